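"""Sliding-window PCA and detection of transient synchronization (TS) events.

A window of ``w`` frames (default 25, i.e. 18 s at TR 0.72 s) slides over the
ROI x time matrix with stride 1. In each window the timecourses are
z-normalized, so the first principal component equals the top eigenvector of
the window correlation matrix and its explained variance the top eigenvalue
divided by the ROI count. TS events are strict local maxima of the explained
variance timecourse; the signed first-PC loading vector at an event is its
temporal synchronization pattern (TSP), with the sign chosen so the PC score
increases toward the event.

The eigenproblem is solved in the small w x w Gram space (w << n_rois), which
makes a full run's worth of windows a few batched matrix operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.sparse.csgraph import shortest_path

from .preprocess import RoiTimeseries, ScrubMask


@dataclass
class VarianceTimecourse:
    """Fraction of window variance explained by the 1st PC, per window."""

    values: np.ndarray         # (n_windows,)
    centers: np.ndarray        # window center frame per value
    window_size: int

    @property
    def n_windows(self) -> int:
        return self.values.size


@dataclass
class TsEvent:
    """One transient synchronization event."""

    center_frame: int
    window_start: int
    window_end: int            # inclusive
    explained_variance: float
    tsp: np.ndarray            # signed unit first-PC loadings over ROIs
    sub_cluster: int = None
    ambiguous: bool = False
    subject_id: str = ""
    run_id: str = ""


@dataclass
class SwpcaResult:
    """Per-window first-PC summaries for one run."""

    variance: VarianceTimecourse
    loadings: np.ndarray       # (n_windows, n_rois), unit norm
    scores: np.ndarray         # (n_windows, w) first-PC score timecourses
    skipped: np.ndarray        # bool per window (all ROIs degenerate)
    starts: np.ndarray
    subject_id: str = ""
    run_id: str = ""


def sliding_windows(n_frames: int, w: int) -> np.ndarray:
    """Stride-1 window bookkeeping: rows of (start, center, end-inclusive).

    ``w`` must be odd so the center is a frame; a run of T usable frames
    yields T - w + 1 windows.
    """
    if w % 2 == 0:
        raise ValueError("window size must be odd so the center is a frame")
    if w > n_frames:
        raise ValueError(f"window size {w} exceeds run length {n_frames}")
    starts = np.arange(n_frames - w + 1)
    half = (w - 1) // 2
    return np.column_stack([starts, starts + half, starts + w - 1])


def _window_stack(data: np.ndarray, w: int):
    """Z-normalized window stack Z of shape (n_windows, n_rois, w)."""
    view = np.lib.stride_tricks.sliding_window_view(data, w, axis=1)
    Z = np.ascontiguousarray(view.transpose(1, 0, 2)).astype(float)
    mean = Z.mean(axis=2, keepdims=True)
    sd = Z.std(axis=2, keepdims=True)
    degenerate = sd == 0.0
    sd = np.where(degenerate, 1.0, sd)
    Z = (Z - mean) / sd
    Z[np.broadcast_to(degenerate, Z.shape)] = 0.0
    n_valid = (~degenerate[:, :, 0]).sum(axis=1)
    return Z, n_valid


def swpca(ts: RoiTimeseries, w: int = 25) -> SwpcaResult:
    """Sliding-window PCA over a run.

    Returns the explained-variance timecourse of the 1st PC plus per-window
    unit-norm loadings and score timecourses. Windows in which every ROI is
    constant are skipped (NaN variance, flagged).
    """
    if w < 3:
        raise ValueError("window size must be at least 3")
    wins = sliding_windows(ts.n_frames, w)
    Z, n_valid = _window_stack(ts.data, w)
    # Gram matrices S = Z^T Z; eigenvalues of S equal those of Z Z^T, and the
    # window correlation matrix is Z Z^T / w with trace = n_valid ROIs.
    S = np.einsum("kni,knj->kij", Z, Z, optimize=True)
    trace = np.einsum("kii->k", S)
    evals, evecs = np.linalg.eigh(S)
    lam = evals[:, -1]
    v = evecs[:, :, -1]
    with np.errstate(invalid="ignore", divide="ignore"):
        ev = np.where(trace > 0, lam / trace, np.nan)
    loadings = np.einsum("knw,kw->kn", Z, v, optimize=True)
    norms = np.linalg.norm(loadings, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    loadings = loadings / norms
    scores = np.einsum("knw,kn->kw", Z, loadings, optimize=True)
    skipped = n_valid == 0
    if skipped.any():
        warnings.warn(f"{int(skipped.sum())} fully degenerate window(s) skipped",
                      stacklevel=2)
    var = VarianceTimecourse(values=ev, centers=wins[:, 1], window_size=w)
    return SwpcaResult(variance=var, loadings=loadings, scores=scores,
                       skipped=skipped, starts=wins[:, 0],
                       subject_id=ts.subject_id, run_id=ts.run_id)


def extract_tsp(loadings: np.ndarray, score_timecourse: np.ndarray):
    """Sign-align first-PC loadings so the score rises toward the TS frame.

    The sign test is the least-squares slope of the score timecourse over the
    window: a negative slope flips the loadings. An exactly zero slope leaves
    the sign unchanged and flags the event as ambiguous.

    Returns (tsp, ambiguous).
    """
    loadings = np.asarray(loadings, dtype=float)
    score = np.asarray(score_timecourse, dtype=float)
    x = np.arange(score.size) - (score.size - 1) / 2.0
    slope = float(x @ score)
    if slope < 0:
        return -loadings, False
    if slope == 0:
        return loadings.copy(), True
    return loadings.copy(), False


def detect_ts(res: SwpcaResult, mask: ScrubMask = None, smooth: int = 0) -> list:
    """TS events at strict local maxima of the explained-variance timecourse.

    A window is an event only if its variance exceeds both neighbours
    (plateaus and endpoints never qualify). Events whose window overlaps any
    scrubbed frame are dropped. ``smooth`` > 1 applies a moving average of
    that width to the variance timecourse before the maxima search, which
    suppresses estimator ripple; the default leaves the timecourse
    untouched.
    """
    v = res.variance.values
    if smooth and smooth > 1:
        v = np.convolve(v, np.ones(smooth) / smooth, mode="same")
    w = res.variance.window_size
    if mask is not None and len(mask) != v.size + w - 1:
        raise ValueError("scrub mask length must match the run's frame count")
    if v.size < 3:
        return []
    with np.errstate(invalid="ignore"):
        is_max = np.zeros(v.size, dtype=bool)
        is_max[1:-1] = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    is_max &= ~res.skipped
    events = []
    masked_cum = None
    if mask is not None:
        masked_cum = np.concatenate([[0], np.cumsum(mask.mask.astype(int))])
    for i in np.flatnonzero(is_max):
        start = int(res.starts[i])
        end = start + w - 1
        if masked_cum is not None and masked_cum[end + 1] - masked_cum[start] > 0:
            continue
        tsp, ambiguous = extract_tsp(res.loadings[i], res.scores[i])
        events.append(TsEvent(center_frame=int(res.variance.centers[i]),
                              window_start=start, window_end=end,
                              explained_variance=float(res.variance.values[i]),
                              tsp=tsp,
                              ambiguous=ambiguous, subject_id=res.subject_id,
                              run_id=res.run_id))
    return events


_ALL_MEASURES = ("frobenius_norm", "phase_sync", "ppa_count",
                 "global_efficiency")


def sync_measures(ts: RoiTimeseries, w: int = 25, ppa_threshold: float = 1.0,
                  measures=_ALL_MEASURES) -> pd.DataFrame:
    """Comparison synchronization measures, one row per window center.

    frobenius_norm : Frobenius norm of the window correlation matrix.
    phase_sync     : Kuramoto order parameter of analytic-signal phases at
                     the window center.
    ppa_count      : number of ROIs whose full-run z-scored timecourse
                     exceeds +``ppa_threshold`` SD at the center frame.
    global_efficiency : mean inverse shortest-path length on the weighted
                     graph with edge length 1 - r (r < 0 set to length 2).
                     O(windows * n_rois^3); select ``measures`` to skip it
                     on large runs.
    """
    wins = sliding_windows(ts.n_frames, w)
    centers = wins[:, 1]
    out = {"frame": centers}
    need_windows = {"frobenius_norm", "global_efficiency"} & set(measures)
    if need_windows:
        Z, _ = _window_stack(ts.data, w)

    if "frobenius_norm" in measures:
        S = np.einsum("kni,knj->kij", Z, Z, optimize=True)
        evals = np.linalg.eigvalsh(S)
        # ||C||_F with C = Z Z^T / w shares nonzero eigenvalues with S / w
        out["frobenius_norm"] = np.sqrt((evals ** 2).sum(axis=1)) / w

    centered = ts.data - ts.data.mean(axis=1, keepdims=True)
    if "phase_sync" in measures:
        phases = np.angle(_signal.hilbert(centered, axis=1))
        kuramoto = np.abs(np.exp(1j * phases).mean(axis=0))
        out["phase_sync"] = kuramoto[centers]

    if "ppa_count" in measures:
        sd = ts.data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out["ppa_count"] = ((centered / sd) > ppa_threshold).sum(axis=0)[centers]

    if "global_efficiency" in measures:
        eff = np.empty(wins.shape[0])
        for k in range(wins.shape[0]):
            C = (Z[k] @ Z[k].T) / w
            length = np.where(C < 0, 2.0, 1.0 - C)
            np.fill_diagonal(length, 0.0)
            length = np.maximum(length, 0.0)
            d = shortest_path(length, method="D", directed=False)
            off = ~np.eye(d.shape[0], dtype=bool)
            with np.errstate(divide="ignore"):
                inv = 1.0 / np.maximum(d[off], 1e-6)
            eff[k] = inv.mean()
        out["global_efficiency"] = eff

    return pd.DataFrame(out).set_index("frame")


def window_size_scan(ts: RoiTimeseries, sizes) -> dict:
    """Explained-variance timecourses for several window sizes.

    Returns ``{"variance": {w: VarianceTimecourse}, "maxima": {w: centers},
    "alignment": DataFrame}`` where the alignment table reports, for each
    size, the offset of each reference-size maximum to its nearest maximum
    (reference = first size in the list).
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("need at least one window size")
    variance, maxima = {}, {}
    for w in sizes:
        res = swpca(ts, w)
        variance[w] = res.variance
        v = res.variance.values
        idx = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1
        maxima[w] = res.variance.centers[idx]
    ref = sizes[0]
    rows = []
    for w in sizes:
        for c in maxima[ref]:
            if maxima[w].size:
                off = int(maxima[w][np.argmin(np.abs(maxima[w] - c))] - c)
            else:
                off = np.nan
            rows.append({"size": w, "ref_center": int(c), "offset": off})
    return {"variance": variance, "maxima": maxima,
            "alignment": pd.DataFrame(rows)}
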
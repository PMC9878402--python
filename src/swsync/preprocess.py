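"""Preprocessing of ROI-level BOLD time series before synchronization detection.

Steps mirror common resting-state practice: temporal band-pass filtering
(default 0.009--0.08 Hz), discarding frames at the run boundaries, per-window
z-normalization, and motion-based scrubbing driven by framewise displacement
(FD) computed from the six rigid-body realignment parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal


@dataclass
class RoiTimeseries:
    """ROI x frame BOLD matrix with acquisition metadata.

    Attributes
    ----------
    data : ndarray, shape (n_rois, n_frames)
        BOLD signal in arbitrary units; no missing values allowed.
    tr : float
        Repetition time in seconds.
    roi_ids : list of str
        One label per ROI row.
    subject_id, run_id : str
        Identity of the run the matrix came from.
    frame_offset : int
        Index of column 0 in the original (untrimmed) acquisition, so event
        frames can always be mapped back to scanner time.
    """

    data: np.ndarray
    tr: float
    roi_ids: list = None
    subject_id: str = ""
    run_id: str = ""
    frame_offset: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (ROI x frame)")
        if self.data.shape[1] < 1:
            raise ValueError("need at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.roi_ids is None:
            self.roi_ids = [f"roi{i}" for i in range(self.data.shape[0])]
        if len(self.roi_ids) != self.data.shape[0]:
            raise ValueError("roi_ids length must match ROI count")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters per frame.

    ``params`` has shape (n_frames, 6): columns 0-2 are translations in mm,
    columns 3-5 rotations in radians.
    """

    params: np.ndarray

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must have shape (n_frames, 6)")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class ScrubMask:
    """Per-frame boolean mask; True marks a frame unusable for TS detection."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 1:
            raise ValueError("mask must be 1-D")

    @property
    def n_frames(self) -> int:
        return self.mask.size

    def __len__(self) -> int:
        return self.mask.size


def bandpass(ts: RoiTimeseries, low_hz: float = 0.009, high_hz: float = 0.08,
             order: int = 4) -> RoiTimeseries:
    """Zero-phase Butterworth band-pass filter applied identically to each ROI.

    The filter is applied forward and backward (``filtfilt``), so the output
    has no phase shift — window centers stay aligned with the input.

    Parameters
    ----------
    low_hz, high_hz : float
        Pass-band edges in Hz; must satisfy 0 < low < high < Nyquist.
    order : int
        Butterworth order per pass (effective order doubles with filtfilt).
    """
    nyq = 0.5 / ts.tr
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyq:.4g}) Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / ts.tr, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    return replace(ts, data=filtered)


def trim_frames(ts: RoiTimeseries, n_head: int = 38, n_tail: int = 38) -> RoiTimeseries:
    """Discard the first ``n_head`` and last ``n_tail`` frames of a run.

    The returned series carries ``frame_offset`` so that a post-trim frame
    index f corresponds to acquisition frame f + frame_offset.
    """
    if n_head < 0 or n_tail < 0:
        raise ValueError("trim counts must be non-negative")
    if n_head + n_tail >= ts.n_frames:
        raise ValueError(
            f"cannot trim {n_head}+{n_tail} frames from a {ts.n_frames}-frame run"
        )
    stop = ts.n_frames - n_tail
    return replace(ts, data=ts.data[:, n_head:stop],
                   frame_offset=ts.frame_offset + n_head)


def framewise_displacement(motion: MotionTrace, head_radius: float = 50.0) -> np.ndarray:
    """Framewise displacement in mm.

    FD(t) = sum |Delta translation_i| + head_radius * sum |Delta rotation_j|,
    with FD(0) = 0. Rotations are converted to arc length on a sphere of
    ``head_radius`` mm (default 50 mm).
    """
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames to compute FD")
    d = np.diff(motion.params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub_mask(fd: np.ndarray, threshold: float = 0.5, n_after: int = 30) -> ScrubMask:
    """Mark frames contaminated by head movement.

    Every frame t with FD(t) > ``threshold`` mm is masked together with the
    ``n_after`` following frames (windows touching the movement and its
    hemodynamic aftermath are unusable for TS detection).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if n_after < 0:
        raise ValueError("n_after must be non-negative")
    fd = np.asarray(fd, dtype=float)
    mask = np.zeros(fd.size, dtype=bool)
    for t in np.flatnonzero(fd > threshold):
        mask[t:t + n_after + 1] = True
    return ScrubMask(mask)


def exclude_low_ts_runs(ts_counts: dict, min_ts: int = 60) -> dict:
    """Flag runs whose TS event count falls below ``min_ts``.

    Returns a dict with ``kept`` and ``excluded`` lists of run keys; a run
    with exactly ``min_ts`` events is kept (boundary convention: keep >=).
    """
    if min_ts < 0:
        raise ValueError("min_ts must be non-negative")
    kept = [k for k, n in ts_counts.items() if n >= min_ts]
    excluded = [k for k, n in ts_counts.items() if n < min_ts]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} run(s) with fewer than {min_ts} TS events",
            stacklevel=2,
        )
    return {"kept": kept, "excluded": excluded}


def window_znorm(window: np.ndarray):
    """Z-normalize each ROI row of a window to mean 0, SD 1 (population SD).

    Zero-variance rows cannot be normalized; they are set to all-zero and
    reported through the returned boolean ``degenerate`` vector.

    Returns
    -------
    normalized : ndarray, same shape as ``window``
    degenerate : ndarray of bool, shape (n_rois,)
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] < 2:
        raise ValueError("window must be ROI x w with w >= 2")
    mean = window.mean(axis=1, keepdims=True)
    sd = window.std(axis=1, keepdims=True)
    degenerate = (sd[:, 0] == 0.0)
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    out = (window - mean) / safe_sd
    out[degenerate] = 0.0
    return out, degenerate
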
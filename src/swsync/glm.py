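"""Event-coded GLM reconstruction of synchronized activation patterns (SAPs).

TS event centers for each sub-cluster are coded as impulse trains, convolved
with the canonical double-gamma HRF, and regressed against voxel (or ROI)
timecourses by ordinary least squares at the run level. Run-level beta maps
are combined across runs (fixed effect: average within subject) and subjects
(random effect: one-sample t across subjects, converted to z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


def canonical_hrf(tr: float) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    gamma(shape 6, scale 1 s) minus gamma(shape 16, scale 1 s)/6, sampled at
    0, tr, 2*tr, ... up to 32 s and normalized to unit peak. The positive
    lobe peaks at (6-1)*1 = 5 s; the undershoot follows.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(int(np.floor(32.0 / tr)) + 1) * tr
    h = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    """Frames x regressors design with event regressors plus intercept.

    ``row_slice`` records which frames of the run the rows correspond to,
    so that the data matrix can be trimmed identically before fitting.
    """

    matrix: np.ndarray
    names: list
    tr: float
    row_slice: slice
    dropped: list

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SapMap:
    """Per-sub-cluster voxel beta maps (run level) or group z maps."""

    betas: np.ndarray          # (n_subclusters, n_voxels)
    subcluster_ids: list
    kind: str = "beta"         # "beta" or "z"
    affine: np.ndarray = None
    shape: tuple = None


def build_design(events, n_frames: int, tr: float, n_subclusters: int = None,
                 glm_trim: int = 50) -> DesignMatrix:
    """Build the event-coded design matrix.

    One unit impulse is placed at each event's center frame in the regressor
    of its sub-cluster; each train is convolved with the canonical HRF and
    truncated to the run length. The first and last ``glm_trim`` frames are
    then discarded from the design (and must be discarded from the data) and
    an intercept column is appended. Sub-clusters with no events yield an
    all-zero regressor, which is dropped with a warning and recorded.

    ``events`` is a sequence of objects with ``center_frame`` and
    ``sub_cluster`` attributes (or (frame, label) pairs).
    """
    pairs = []
    for ev in events:
        if hasattr(ev, "center_frame"):
            frame, label = ev.center_frame, ev.sub_cluster
        else:
            frame, label = ev
        if label is None:
            raise ValueError("every event must carry a sub-cluster label")
        if not (0 <= frame < n_frames):
            raise ValueError(f"event frame {frame} outside run of {n_frames} frames")
        pairs.append((int(frame), int(label)))
    if n_subclusters is None:
        n_subclusters = max(l for _, l in pairs) + 1 if pairs else 0
    if 2 * glm_trim >= n_frames:
        raise ValueError("glm_trim removes the whole run")

    kernel = canonical_hrf(tr)
    cols, names, dropped = [], [], []
    for sc in range(n_subclusters):
        train = np.zeros(n_frames)
        for frame, label in pairs:
            if label == sc:
                train[frame] += 1.0
        if not train.any():
            dropped.append(sc)
            continue
        reg = np.convolve(train, kernel)[:n_frames]
        cols.append(reg)
        names.append(f"subcluster_{sc}")
    if dropped:
        warnings.warn(f"sub-clusters with no events dropped from design: {dropped}",
                      stacklevel=2)
    row_slice = slice(glm_trim, n_frames - glm_trim)
    cols.append(np.ones(n_frames))
    names.append("intercept")
    matrix = np.column_stack(cols)[row_slice]
    return DesignMatrix(matrix=matrix, names=names, tr=tr,
                        row_slice=row_slice, dropped=dropped)


def run_glm(voxel_ts: np.ndarray, design: DesignMatrix):
    """Per-voxel ordinary least squares against the event design.

    ``voxel_ts`` is voxel x frame over the full run; rows of the design's
    ``row_slice`` are used. Returns (betas, residual_variance, dof) where
    betas has shape (n_voxels, n_regressors).
    """
    voxel_ts = np.asarray(voxel_ts, dtype=float)
    y = voxel_ts[:, design.row_slice].T            # frames x voxels
    X = design.matrix
    if y.shape[0] != X.shape[0]:
        raise ValueError("data frames do not match design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify near-collinear columns from the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.names[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    resid_var = (resid ** 2).sum(axis=0) / dof
    return beta.T, resid_var, dof


def group_stats(run_betas, z_cap: float = 40.0):
    """Group-level z maps from per-subject, per-run beta maps.

    ``run_betas`` maps subject id -> list of beta arrays (n_subclusters x
    n_voxels), one per run. Runs are averaged within subject (fixed effect);
    a one-sample t-test across subjects per voxel (random effect) is
    converted to a signed z score. Voxels with zero between-subject variance
    get |z| capped at ``z_cap`` and are counted in the returned report.
    """
    subjects = sorted(run_betas)
    if len(subjects) < 2:
        raise ValueError("group statistics require at least 2 subjects")
    per_subject = np.stack([np.mean(np.stack(run_betas[s]), axis=0) for s in subjects])
    n = per_subject.shape[0]
    mean = per_subject.mean(axis=0)
    sd = per_subject.std(axis=0, ddof=1)
    capped = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # two-sided p mapped back to a signed z
    p_one = stats.t.sf(np.abs(t), df=n - 1)
    z = np.sign(t) * stats.norm.isf(np.clip(p_one, 1e-300, 1.0))
    z[capped] = np.sign(mean[capped]) * z_cap
    z = np.clip(z, -z_cap, z_cap)
    if capped.any():
        warnings.warn(f"{int(capped.sum())} voxel(s) had zero between-subject "
                      "variance; z capped", stacklevel=2)
    return z, {"n_subjects": n, "n_capped": int(capped.sum())}
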
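"""Relating synchronization clusters to static connectivity, task maps, and
subject measures.

Static RSFC is the full-run Pearson correlation between network timecourses;
cluster occurrence features predict RSFC strength by multiple regression.
Spatial consistency between subject-level SAP maps and task activation maps
is quantified as Hedges' g between same-subject and different-subject map
correlations. Brain-behaviour association uses the deconfounded PCA -> CCA
pipeline with subject-permutation family-wise error control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA


@dataclass
class RsfcVector:
    """Upper-triangle network-pair correlations for one run."""

    values: np.ndarray        # (m * (m - 1) / 2,)
    pair_labels: list
    missing: list             # pairs involving a zero-variance network


@dataclass
class CcaResult:
    corrs: np.ndarray         # canonical correlations, non-increasing
    p_fwe: np.ndarray         # permutation FWE p per mode
    sm_weights: np.ndarray    # (n_sms, n_modes) variable-variate correlations
    image_weights: np.ndarray # (n_pixels, n_modes)
    n_pcs: int
    n_perm: int
    seed: int


def static_rsfc(network_ts: np.ndarray, labels=None) -> RsfcVector:
    """All pairwise Pearson correlations over the full run.

    m networks yield m(m-1)/2 values. Pairs involving a zero-variance
    timecourse are set to NaN and reported in ``missing``.
    """
    X = np.asarray(network_ts, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("need >= 2 networks and >= 3 frames")
    m = X.shape[0]
    if labels is None:
        labels = [f"net{i}" for i in range(m)]
    constant = np.ptp(X, axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        C = np.corrcoef(X)
    iu = np.triu_indices(m, k=1)
    values = C[iu]
    pair_labels = [(labels[i], labels[j]) for i, j in zip(*iu)]
    missing = []
    for idx, (i, j) in enumerate(zip(*iu)):
        if constant[i] or constant[j]:
            values[idx] = np.nan
            missing.append(pair_labels[idx])
    if missing:
        warnings.warn(f"zero-variance networks: {len(missing)} pair(s) missing",
                      stacklevel=2)
    return RsfcVector(values=values, pair_labels=pair_labels, missing=missing)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    n = y.size
    Xd = np.column_stack([X, np.ones(n)])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("rank-deficient predictor matrix")
    beta, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid ** 2) / tss) if tss > 0 else np.nan


def regress_rsfc(rsfc_by_subject: np.ndarray, predictors: np.ndarray,
                 per_cluster: bool = False):
    """Predict RSFC strength from cluster features by group-level OLS.

    ``rsfc_by_subject`` is subjects x pairs, ``predictors`` subjects x
    features (e.g. per-cluster occurrence frequency). Returns per-pair R^2;
    with ``per_cluster=True`` a pairs x features matrix of single-feature
    R^2 values is returned instead.
    """
    Y = np.asarray(rsfc_by_subject, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError("subject counts differ")
    if Y.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more subjects than predictors + 1")
    if per_cluster:
        out = np.empty((Y.shape[1], X.shape[1]))
        for j in range(X.shape[1]):
            for p in range(Y.shape[1]):
                out[p, j] = _ols_r2(Y[:, p], X[:, [j]])
        return out
    return np.array([_ols_r2(Y[:, p], X) for p in range(Y.shape[1])])


def hedges_g(x: np.ndarray, y: np.ndarray) -> float:
    """Hedges' g: pooled-SD standardized mean difference, bias-corrected."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    df = nx + ny - 2
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df)
    if pooled == 0:
        return 0.0 if x.mean() == y.mean() else np.inf
    g = (x.mean() - y.mean()) / pooled
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(g * correction)


def map_similarity_g(subject_saps: np.ndarray, subject_taskmaps: np.ndarray) -> float:
    """Spatial-consistency effect size between two per-subject map sets.

    Both inputs are subjects x voxels for one (cluster, contrast) pairing.
    The cross-subject mean map is removed from each set; the matched
    distribution holds same-subject spatial correlations and the null all
    different-subject correlations; the return value is Hedges' g between
    the two distributions.
    """
    A = np.asarray(subject_saps, dtype=float)
    B = np.asarray(subject_taskmaps, dtype=float)
    if A.shape != B.shape or A.shape[0] < 2:
        raise ValueError("need matched subjects x voxels arrays with >= 2 subjects")
    if A.shape[0] < 10:
        warnings.warn("fewer than 10 subjects: effect size is unstable",
                      stacklevel=2)
    A = A - A.mean(axis=0, keepdims=True)
    B = B - B.mean(axis=0, keepdims=True)

    def rows_corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        return a @ b / (na * nb) if na > 0 and nb > 0 else 0.0

    n = A.shape[0]
    matched = np.array([rows_corr(A[i], B[i]) for i in range(n)])
    null = np.array([rows_corr(A[i], B[j])
                     for i in range(n) for j in range(n) if i != j])
    return hedges_g(matched, null)


def inverse_gaussian_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse Gaussian (Van der Waerden) transform.

    Ranks r (ties get mean rank) map to standard-normal quantiles at
    r / (n + 1); affine transformations of the input leave the output
    unchanged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.all(v == v[0]):
        raise ValueError("all values identical: no rank information")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf(ranks / (v.size + 1.0))


def deconfound(values: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize each column of ``values`` on confounds plus intercept."""
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if Y.shape[0] != C.shape[0]:
        raise ValueError("subject counts differ")
    if Y.shape[0] <= C.shape[1] + 1:
        raise ValueError("need more subjects than confounds + 1")
    X = np.column_stack([C, np.ones(C.shape[0])])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient confound matrix")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def _cca_corrs(X: np.ndarray, Y: np.ndarray):
    """Canonical correlations and variates of two column-centered blocks."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Qx, _ = np.linalg.qr(Xc)
    Qy, _ = np.linalg.qr(Yc)
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    n_modes = min(X.shape[1], Y.shape[1])
    corrs = np.clip(s[:n_modes], 0.0, 1.0)
    return corrs, Qx @ U[:, :n_modes], Qy @ Vt.T[:, :n_modes]


def _rank_transform_columns(M: np.ndarray) -> np.ndarray:
    out = np.empty_like(M, dtype=float)
    n = M.shape[0]
    for j in range(M.shape[1]):
        col = M[:, j]
        if np.all(col == col[0]):
            out[:, j] = 0.0
        else:
            out[:, j] = stats.norm.ppf(stats.rankdata(col) / (n + 1.0))
    return out


def cca_pipeline(images: np.ndarray, sms: np.ndarray, confounds: np.ndarray = None,
                 n_pcs: int = 50, n_perm: int = 10000, seed: int = 0) -> CcaResult:
    """Deconfounded PCA -> CCA between image maps and subject measures.

    Image columns are rank-based inverse-Gaussian transformed; subject
    measures are residualized on the confounds (if given); both blocks are
    PCA-reduced to ``n_pcs`` components before CCA. Significance per mode is
    assessed by permuting subject rows on the SM side, with FWE control from
    the per-permutation maximum canonical correlation. Weights are the
    correlations of the original variables with the canonical variates.
    """
    X = np.asarray(images, dtype=float)
    Y = np.asarray(sms, dtype=float)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("images and SMs must have the same subject count")
    if n_pcs >= n:
        raise ValueError("n_pcs must be below the subject count")
    Xr = _rank_transform_columns(X)
    Yd = deconfound(Y, confounds) if confounds is not None else Y - Y.mean(axis=0)
    kx = min(n_pcs, Xr.shape[1])
    ky = min(n_pcs, Yd.shape[1])
    Xp = PCA(n_components=kx, random_state=seed).fit_transform(Xr)
    Yp = PCA(n_components=ky, random_state=seed).fit_transform(Yd)
    corrs, vx, vy = _cca_corrs(Xp, Yp)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null_max[i] = _cca_corrs(Xp, Yp[perm])[0][0]
    p_fwe = np.array([
        max(float(np.mean(null_max >= c)), 1.0 / (n_perm + 1)) for c in corrs
    ])

    def weights(block, variates):
        Bc = block - block.mean(axis=0)
        Vc = variates - variates.mean(axis=0)
        bn = np.linalg.norm(Bc, axis=0)
        vn = np.linalg.norm(Vc, axis=0)
        bn[bn == 0] = 1.0
        vn[vn == 0] = 1.0
        return (Bc / bn).T @ (Vc / vn)

    return CcaResult(corrs=corrs, p_fwe=p_fwe,
                     sm_weights=weights(Y, vy),
                     image_weights=weights(Xr, vx),
                     n_pcs=n_pcs, n_perm=n_perm, seed=seed)
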
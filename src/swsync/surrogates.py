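"""Phase-randomized stationary null data and cluster-validity comparison.

Surrogates add one shared conjugate-symmetric random phase vector to the
Fourier transform of every ROI's timecourse. Sharing the phases across ROIs
preserves the cross-spectra, hence the full auto- and cross-covariance
structure of the run, while destroying any non-stationary event structure —
exactly the null needed to test whether transient synchronization clusters
carry temporal structure beyond linear (stationary Gaussian) dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .cluster import center_unit
from .preprocess import RoiTimeseries


def phase_randomize(ts: RoiTimeseries, seed: int) -> RoiTimeseries:
    """Common-phase randomization of a run.

    Each ROI's DFT is multiplied by exp(i * phi_k) with one shared phase
    vector phi (uniform on [0, 2pi), conjugate-symmetric; DC and Nyquist bins
    untouched). The inverse transform is real-valued, preserves each ROI's
    power spectrum exactly, and preserves every ROI pair's cross-covariance.
    """
    T = ts.n_frames
    if T < 4:
        raise ValueError("need at least 4 frames to phase-randomize")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(ts.data, axis=1)
    n_bins = spec.shape[1]
    phases = np.zeros(n_bins)
    hi = n_bins - 1 if T % 2 == 0 else n_bins  # keep an even run's Nyquist real
    phases[1:hi] = rng.uniform(0.0, 2.0 * np.pi, size=hi - 1)
    rotated = spec * np.exp(1j * phases)[None, :]
    data = np.fft.irfft(rotated, n=T, axis=1)
    return replace(ts, data=data)


def cluster_validity(tsps: np.ndarray, labels) -> float:
    """Within/between correlation-distance ratio (lower = tighter clusters).

    Mean pairwise distance (1 - Pearson r) within clusters divided by the
    mean distance between clusters; clusters with fewer than 2 members are
    skipped from the within term with a warning.
    """
    V = center_unit(tsps)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("validity requires at least 2 represented clusters")
    D = 1.0 - V @ V.T
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within_pairs = same[iu]
    between_pairs = ~within_pairs
    counts = {c: int(np.sum(labels == c)) for c in uniq}
    singletons = [c for c, n in counts.items() if n < 2]
    if singletons:
        warnings.warn(f"clusters with <2 members skipped: {singletons}",
                      stacklevel=2)
    if not within_pairs.any() or not between_pairs.any():
        raise ValueError("need both within- and between-cluster pairs")
    within = D[iu][within_pairs].mean()
    between = D[iu][between_pairs].mean()
    return float(within / between)


def silhouette_validity(tsps: np.ndarray, labels) -> float:
    """Mean silhouette coefficient under correlation distance (companion index)."""
    from sklearn.metrics import silhouette_score

    V = center_unit(tsps)
    D = np.clip(1.0 - V @ V.T, 0.0, None)
    np.fill_diagonal(D, 0.0)
    return float(silhouette_score(D, np.asarray(labels), metric="precomputed"))


def compare_validity(real_index: float, null_indices) -> dict:
    """One-sided empirical test that real clustering is tighter than null.

    p = (1 + #{null <= real}) / (n + 1), so a real index below every null
    attains the 1/(n+1) floor. The effect size is the real index standardized
    against the null mean and SD (negative = tighter than null).
    """
    null_indices = np.asarray(list(null_indices), dtype=float)
    n = null_indices.size
    if n < 20:
        raise ValueError("need at least 20 null indices")
    p = (1.0 + np.sum(null_indices <= real_index)) / (n + 1.0)
    sd = null_indices.std(ddof=1)
    effect = (real_index - null_indices.mean()) / sd if sd > 0 else np.inf
    return {"p": float(p), "effect": float(effect), "n_null": int(n)}
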
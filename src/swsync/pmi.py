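"""Pointwise mutual information (PMI) structure of cluster co-occurrence.

For an ordered cluster pair (a, b) and times (t, t + tau), PMI measures how
much observing cluster a at t raises the probability of observing cluster b
at t + tau, conditional on a TS of any cluster occurring at the frames
involved:

    PMI(t, tau) = log2( Pr(Y_b = 1 at t+tau | X_a = 1 at t) / Pr(Y_b = 1 at t+tau) )

Probabilities come from occurrence timecourses smoothed with a 50-frame
moving average (which keeps the conditioning probability away from zero) and
are estimated by averaging across runs. Each (a, b) surface is decomposed by
multiple linear regression into a lag (tau) effect, a time (t) effect, and a
zero-lag constant; significance is assessed family-wise against
phase-randomized surrogate data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cluster import OccurrenceTimecourse


@dataclass
class PmiSurface:
    """PMI values in bits over a (t, tau) grid for one ordered cluster pair."""

    pair: tuple
    t_values: np.ndarray
    tau_values: np.ndarray
    pmi: np.ndarray            # (n_t, n_tau), NaN where invalid
    valid: np.ndarray          # bool mask, same shape
    n_frames: int


@dataclass
class PmiDecomposition:
    """Regression decomposition of one pair's PMI surface (units: bits)."""

    pair: tuple
    lag_coef: float            # bits per frame of tau
    time_coef: float           # bits per frame of t
    const: float               # zero-lag PMI, bits
    p_lag: float = None
    p_time: float = None
    p_const: float = None


def _as_stack(occ):
    """Stack one or several runs' occurrence timecourses into arrays."""
    occs = [occ] if isinstance(occ, OccurrenceTimecourse) else list(occ)
    T = occs[0].n_frames
    if any(o.n_frames != T for o in occs):
        raise ValueError("all runs must share the frame count")
    probs = np.stack([o.probs for o in occs])       # (R, k, T)
    any_ts = np.stack([o.any_ts for o in occs])     # (R, T)
    return probs, any_ts


def pmi_surface(occ, pair, tau_max: int, t_stride: int = 1,
                tau_stride: int = 1, floor: float = 1e-6,
                form: str = "ratio") -> PmiSurface:
    """PMI(t, tau) for one ordered cluster pair from smoothed occurrences.

    ``occ`` is an OccurrenceTimecourse or a list of them (one per run);
    probabilities are averaged across runs, weighted by the smoothed any-TS
    indicator that encodes the conditioning on "some TS occurred". Cells
    whose conditioning probability (or any-TS denominator) falls below
    ``floor``, or whose joint probability is non-positive, are masked —
    never imputed. ``form='literal'`` computes log2(Pr(Y|X) * Pr(X)) for
    comparison with the non-ratio reading of the definition.
    """
    probs, any_ts = _as_stack(occ)
    a, b = pair
    T = probs.shape[2]
    if tau_max >= T:
        raise ValueError(f"tau_max={tau_max} must be below the run length {T}")
    x = probs[:, a, :]                              # (R, T)
    y = probs[:, b, :]
    t_vals = np.arange(0, T - 1, t_stride)
    tau_vals = np.arange(tau_stride, tau_max + 1, tau_stride)
    idx = t_vals[:, None] + tau_vals[None, :]
    inside = idx < T
    idx_c = np.minimum(idx, T - 1)

    y_sh = y[:, idx_c]                              # (R, n_t, n_tau)
    any_sh = any_ts[:, idx_c]
    x_t = x[:, t_vals]
    any_t = any_ts[:, t_vals]

    joint_num = np.einsum("rt,rtj->tj", x_t, y_sh, optimize=True)
    joint_den = np.einsum("rt,rtj->tj", any_t, any_sh, optimize=True)
    px_num = x_t.sum(axis=0)
    px_den = any_t.sum(axis=0)
    py_num = y_sh.sum(axis=0)
    py_den = any_sh.sum(axis=0)

    valid = inside & (joint_den > floor) & (py_den > floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        px = px_num / px_den
        valid &= (px_den > floor)[:, None] & (px > floor)[:, None]
        pj = joint_num / joint_den
        py = py_num / py_den
        valid &= pj > 0
        if form == "ratio":
            valid &= py > floor
            pmi = np.log2(pj / (px[:, None] * py))
        elif form == "literal":
            pmi = np.log2(pj)
        else:
            raise ValueError("form must be 'ratio' or 'literal'")
    pmi = np.where(valid, pmi, np.nan)
    return PmiSurface(pair=(a, b), t_values=t_vals, tau_values=tau_vals,
                      pmi=pmi, valid=valid, n_frames=T)


def decompose_pmi(surface: PmiSurface, t_trim: int = 100,
                  tau_min: int = 100) -> PmiDecomposition:
    """Regress valid PMI cells on (t, tau, 1).

    Cells with t outside [t_trim, T - t_trim] or tau <= tau_min are excluded
    (early/late scanning periods and short lags are dominated by the
    autocorrelation of the filtered signal).
    """
    T = surface.n_frames
    keep_t = (surface.t_values >= t_trim) & (surface.t_values <= T - 1 - t_trim)
    keep_tau = surface.tau_values > tau_min
    cells = surface.valid & keep_t[:, None] & keep_tau[None, :]
    n_cells = int(cells.sum())
    if n_cells < 9:
        raise ValueError(f"only {n_cells} valid cells; need at least 9 for "
                         "a 3-parameter regression")
    tt, tau = np.meshgrid(surface.t_values, surface.tau_values, indexing="ij")
    X = np.column_stack([tt[cells], tau[cells], np.ones(n_cells)])
    ydat = surface.pmi[cells]
    beta, _, _, _ = np.linalg.lstsq(X, ydat, rcond=None)
    return PmiDecomposition(pair=surface.pair, time_coef=float(beta[0]),
                            lag_coef=float(beta[1]), const=float(beta[2]))


def pmi_decompositions(occ, n_clusters: int, tau_max: int,
                       t_stride: int = 1, tau_stride: int = 1,
                       t_trim: int = 100, tau_min: int = 100,
                       floor: float = 1e-6, form: str = "ratio",
                       on_insufficient: str = "raise") -> dict:
    """Decompositions for all ordered cluster pairs: {(a, b): PmiDecomposition}.

    A pair whose surface has too few valid cells (e.g. a cluster with no
    events in these runs) raises by default; ``on_insufficient='skip'``
    drops the pair with a warning instead.
    """
    out = {}
    for a in range(n_clusters):
        for b in range(n_clusters):
            surf = pmi_surface(occ, (a, b), tau_max, t_stride=t_stride,
                               tau_stride=tau_stride, floor=floor, form=form)
            try:
                out[(a, b)] = decompose_pmi(surf, t_trim=t_trim, tau_min=tau_min)
            except ValueError:
                if on_insufficient != "skip":
                    raise
                warnings.warn(f"pair {(a, b)}: too few valid PMI cells; skipped",
                              stacklevel=2)
    return out


def pmi_significance(real: dict, null: list, alpha: float = 0.05) -> dict:
    """Family-wise permutation p-values for PMI regression coefficients.

    ``real`` maps ordered pairs to PmiDecomposition; ``null`` is a list of
    such dicts, one per surrogate dataset. For each coefficient type the null
    distribution is the per-surrogate maximum |coefficient| across all pairs;
    p_fwe for an observed coefficient is the fraction of surrogate maxima at
    or above its magnitude, floored at 1/(n_surrogates + 1). The p-values are
    written back onto the ``real`` decompositions and returned as
    {coef_type: {pair: p}}.
    """
    n = len(null)
    if n < 1:
        raise ValueError("need at least one surrogate dataset")
    if n < int(np.ceil(1.0 / alpha)) - 1:
        warnings.warn(f"{n} surrogates cannot resolve alpha={alpha}", stacklevel=2)
    null = [s for s in null if s]   # a surrogate with no fittable pair is dropped
    if not null:
        raise ValueError("no usable surrogate decompositions")
    n = len(null)
    fields = {"lag": "lag_coef", "time": "time_coef", "const": "const"}
    pvals = {}
    for name, attr in fields.items():
        null_max = np.array([max(abs(getattr(d, attr)) for d in s.values())
                             for s in null])
        pv = {}
        for pair, dec in real.items():
            obs = abs(getattr(dec, attr))
            p = max(float(np.mean(null_max >= obs)), 1.0 / (n + 1))
            pv[pair] = p
            setattr(dec, "p_" + name, p)
        pvals[name] = pv
    return pvals
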
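"""Synthetic BOLD-like runs with known transient synchronization events.

The generator emulates HCP-style resting-state runs (TR 0.72 s, 1,200 frames,
~264 ROIs): band-limited (0.009--0.08 Hz) Gaussian noise plus brain-wide
co-activation transients. Each transient is a spatial pattern drawn from a
designed set of anti-correlated pattern pairs, amplitude-modulated by a
rise-and-decay temporal kernel whose synchronization moment sits at the
event's logged center frame (a canonical-HRF kernel is available as an
option; see ``transient_kernel``). A partner-pattern event follows each
event one window-length later with configurable probability, reproducing
the paired-transition phenomenology of the analysis. Every run carries its
ground-truth event log.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .glm import canonical_hrf
from .preprocess import MotionTrace, RoiTimeseries


@dataclass
class PatternSet:
    """Designed co-activation patterns over ROIs.

    ``patterns`` has shape (2 * n_pairs, n_rois); every row is a zero-mean
    unit vector. ``pairing`` maps each pattern index to its anti-correlated
    partner (within-pair Pearson r <= -0.8; cross-pair |r| < 0.3).
    """

    patterns: np.ndarray
    pairing: dict
    n_rois: int

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    def correlations(self) -> np.ndarray:
        """Pairwise Pearson correlations between patterns."""
        return np.corrcoef(self.patterns)


@dataclass
class EventLog:
    """Ground-truth events: (true_pattern_id, center_frame, amplitude)."""

    pattern_ids: np.ndarray
    center_frames: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        self.pattern_ids = np.asarray(self.pattern_ids, dtype=int)
        self.center_frames = np.asarray(self.center_frames, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not (len(self.pattern_ids) == len(self.center_frames) == len(self.amplitudes)):
            raise ValueError("event log columns must have equal length")
        if len(self.center_frames) > 1 and not np.all(np.diff(self.center_frames) > 0):
            raise ValueError("event center frames must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.center_frames)


@dataclass
class SyntheticRun:
    """A simulated run together with its generating ground truth."""

    roi_ts: RoiTimeseries
    log: EventLog
    seed: int
    voxel_ts: np.ndarray = None           # voxel x frame, optional
    roi_to_voxel: dict = None
    motion: MotionTrace = None
    noise_sd: float = 0.0                 # realized ROI noise SD
    event_signal: np.ndarray = None       # noise-free event component


def _random_centered_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal(n)
    v -= v.mean()
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise RuntimeError("degenerate random vector")
    return v / nrm


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def make_pattern_set(n_rois: int, n_pairs: int, seed: int,
                     pair_r: float = -0.95, cross_r: float = 0.3,
                     max_tries: int = 500) -> PatternSet:
    """Draw ``2 * n_pairs`` unit patterns forming anti-correlated pairs.

    Each pair's second member is the negated first member plus orthogonal
    jitter tuned so the within-pair correlation is about ``pair_r``. Base
    patterns are redrawn until every cross-pair correlation satisfies
    |r| < ``cross_r``; if that cannot be achieved within ``max_tries`` draws
    per pattern the construction fails explicitly (e.g., too few ROIs).
    """
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    if n_rois < 2 * n_pairs:
        raise ValueError("n_rois must be at least 2 * n_pairs")
    rng = np.random.default_rng(seed)
    patterns = []

    def ok_against_others(v, others):
        return all(abs(_pearson(v, o)) < cross_r for o in others)

    for _ in range(n_pairs):
        for attempt in range(max_tries):
            base = _random_centered_unit(rng, n_rois)
            if not ok_against_others(base, patterns):
                continue
            # partner: -base mixed with orthogonal centered jitter
            mix = abs(pair_r)
            for _ in range(max_tries):
                noise = _random_centered_unit(rng, n_rois)
                noise -= (noise @ base) * base
                nrm = np.linalg.norm(noise)
                if nrm > 1e-12:
                    break
            else:
                raise RuntimeError("could not build orthogonal jitter")
            partner = -mix * base + np.sqrt(max(1.0 - mix ** 2, 0.0)) * noise / nrm
            partner -= partner.mean()
            partner /= np.linalg.norm(partner)
            if _pearson(base, partner) <= -0.8 and ok_against_others(partner, patterns):
                patterns.append(base)
                patterns.append(partner)
                break
        else:
            raise RuntimeError(
                f"could not satisfy pattern decorrelation with n_rois={n_rois}, "
                f"n_pairs={n_pairs} after {max_tries} tries"
            )
    pairing = {}
    for p in range(n_pairs):
        pairing[2 * p] = 2 * p + 1
        pairing[2 * p + 1] = 2 * p
    return PatternSet(patterns=np.array(patterns), pairing=pairing, n_rois=n_rois)


def transient_kernel(window: int = 25, tr: float = 0.72, shape: str = "ramp",
                     decay: float = None):
    """Temporal profile of one synchronization transient.

    ``shape='ramp'`` (default): a half-cosine rise spanning one analysis
    window, centered on the event frame, followed by an exponential decay
    (time constant ``decay`` frames, default one window). The rise makes the
    windowed signal variance peak exactly at the event frame and gives the
    first-PC score a positive slope there, matching how the detector defines
    and sign-aligns a TS event. ``shape='hrf'`` uses the canonical
    double-gamma HRF with its peak at the event frame.

    Returns (kernel, center_index) where ``center_index`` marks the event
    frame within the kernel.
    """
    if shape == "hrf":
        k = canonical_hrf(tr)
        return k, int(np.argmax(k))
    if shape != "ramp":
        raise ValueError("shape must be 'ramp' or 'hrf'")
    if decay is None:
        decay = float(window)
    rise = window - 1  # even for odd windows, so the midpoint is a frame
    n_tail = int(np.ceil(4 * decay))
    i = np.arange(rise + 1 + n_tail, dtype=float)
    k = np.empty_like(i)
    up = i <= rise
    k[up] = (1.0 - np.cos(np.pi * i[up] / rise)) / 2.0
    k[~up] = np.exp(-(i[~up] - rise) / decay)
    return k, rise // 2


def _bandlimited_noise(rng, n_rois, n_frames, tr, band, order=6):
    """Unit-SD Gaussian noise filtered to the requested band per ROI.

    Order 6 keeps >= 95% of the noise power inside the band (the shallower
    order-4 skirt used for *analysis* filtering leaks a few percent).
    """
    white = rng.standard_normal((n_rois, n_frames))
    sos = signal.butter(order, list(band), btype="bandpass", fs=1.0 / tr,
                        output="sos")
    filt = signal.sosfiltfilt(sos, white, axis=1)
    sd = filt.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return filt / sd


def _schedule_events(rng, patterns: PatternSet, n_frames, event_rate, window,
                     pair_prob, min_gap, margin, gap_shape=8.0):
    """Primary events with shifted-gamma gaps; partners follow one window later.

    Gaps are drawn from the most recent event (partner included), so the
    minimum inter-event gap holds globally and the expected total event
    density matches ``event_rate``. Gap lengths are min_gap + a gamma draw
    (shape ``gap_shape``), a fairly regular renewal process that does not
    pile events onto the minimum gap.
    """
    # rate = (1 + pair_prob) events per (mean_gap + pair_prob * window) frames
    mean_gap = (1.0 + pair_prob) / event_rate - pair_prob * window
    if mean_gap <= min_gap + 1:
        raise ValueError(
            f"event_rate {event_rate}/frame cannot respect the minimum gap of "
            f"{min_gap} frames"
        )
    scale = (mean_gap - min_gap) / gap_shape
    events = []  # (frame, pattern_id)
    t = margin
    while True:
        t += min_gap + max(0, int(round(rng.gamma(gap_shape, scale))))
        if t >= n_frames - margin:
            break
        pid = int(rng.integers(patterns.n_patterns))
        events.append((t, pid))
        if rng.random() < pair_prob:
            tp = t + window
            if tp >= n_frames - margin:
                break
            events.append((tp, patterns.pairing[pid]))
            t = tp
    return events


def simulate_run(patterns: PatternSet, n_frames: int = 1200, tr: float = 0.72,
                 event_rate: float = 0.0625, snr: float = 1.0, seed: int = 0,
                 window: int = 25, pair_prob: float = 0.5, min_gap: int = 10,
                 amplitude: float = 1.0, band=(0.009, 0.08),
                 transient: str = "ramp", subject_id: str = "",
                 run_id: str = "") -> SyntheticRun:
    """Simulate one ROI-level run with known synchronization events.

    ``event_rate`` is the expected total number of events per frame
    (partner events included). Each event adds amplitude * pattern * a
    transient (see ``transient_kernel``; 'ramp' rise-and-decay by default,
    'hrf' for the canonical double-gamma) aligned so the synchronization
    moment sits at the event's center frame. Noise is band-limited Gaussian,
    scaled so that the ratio of the event component's temporal SD to the
    noise SD, averaged over ROIs, equals ``snr``. ``snr=np.inf`` produces a
    noise-free run.
    """
    if n_frames < 200:
        raise ValueError("n_frames must be at least 200")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    margin = window
    if event_rate > 0:
        scheduled = _schedule_events(rng, patterns, n_frames, event_rate,
                                     window, pair_prob, min_gap, margin)
    else:
        scheduled = []  # stationary noise-only run
    kernel, peak = transient_kernel(window, tr, shape=transient)
    kernel = kernel * amplitude

    sig = np.zeros((patterns.n_rois, n_frames))
    frames, pids, amps = [], [], []
    for frame, pid in scheduled:
        onset = frame - peak
        k0 = max(0, -onset)
        k1 = min(kernel.size, n_frames - onset)
        sig[:, onset + k0:onset + k1] += np.outer(patterns.patterns[pid],
                                                  kernel[k0:k1])
        frames.append(frame)
        pids.append(pid)
        amps.append(amplitude)

    event_sd = sig.std(axis=1).mean()
    if np.isinf(snr) or event_sd == 0.0:
        noise_sd = 0.0 if np.isinf(snr) else 1.0
    else:
        noise_sd = event_sd / snr
    data = sig.copy()
    if noise_sd > 0:
        data += noise_sd * _bandlimited_noise(rng, patterns.n_rois, n_frames,
                                              tr, band)
    roi_ts = RoiTimeseries(data=data, tr=tr, subject_id=subject_id,
                           run_id=run_id or f"sim{seed}")
    log = EventLog(pattern_ids=pids, center_frames=frames, amplitudes=amps)
    return SyntheticRun(roi_ts=roi_ts, log=log, seed=seed, noise_sd=noise_sd,
                        event_signal=sig)


def expected_event_count(n_frames: int, event_rate: float = 0.0625,
                         window: int = 25) -> float:
    """Expected total events for ``simulate_run``'s scheduling scheme."""
    return (n_frames - 2 * window) * event_rate


def simulate_voxels(run: SyntheticRun, roi_to_voxel: dict, n_voxels: int,
                    noise_sd: float = None, band=(0.009, 0.08)) -> SyntheticRun:
    """Broadcast a run's ROI timecourses into a voxel matrix.

    ``roi_to_voxel`` maps ROI index -> iterable of voxel indices; the sets
    must be disjoint and lie inside [0, n_voxels). Each voxel's timecourse is
    its ROI's timecourse plus independent band-limited noise of SD
    ``noise_sd`` (defaults to the run's ROI noise SD). Uncovered voxels are
    pure noise. The voxel noise stream is seeded deterministically from the
    run seed.
    """
    seen = set()
    for roi, voxels in roi_to_voxel.items():
        vs = set(int(v) for v in voxels)
        if vs & seen:
            raise ValueError("roi_to_voxel voxel sets overlap")
        if any(v < 0 or v >= n_voxels for v in vs):
            raise ValueError("voxel index outside [0, n_voxels)")
        seen |= vs
    if noise_sd is None:
        noise_sd = run.noise_sd
    n_frames = run.roi_ts.n_frames
    voxel_ts = np.zeros((n_voxels, n_frames))
    for roi, voxels in roi_to_voxel.items():
        voxel_ts[list(voxels)] = run.roi_ts.data[roi]
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([run.seed, 7]))
        voxel_ts += noise_sd * _bandlimited_noise(rng, n_voxels, n_frames,
                                                  run.roi_ts.tr, band)
    return replace(run, voxel_ts=voxel_ts, roi_to_voxel=dict(roi_to_voxel))


def voxel_pattern_maps(patterns: PatternSet, roi_to_voxel: dict,
                       n_voxels: int) -> np.ndarray:
    """Ground-truth voxel map per pattern: ROI weights broadcast to voxels."""
    maps = np.zeros((patterns.n_patterns, n_voxels))
    for roi, voxels in roi_to_voxel.items():
        maps[:, list(voxels)] = patterns.patterns[:, [roi]]
    return maps


def simulate_motion(n_frames: int, spike_frames=(), spike_mm: float = 0.6,
                    seed: int = 0, drift_amp: float = 0.05, tr: float = 0.72) -> MotionTrace:
    """Smooth low-amplitude drift plus sustained translation steps.

    Drift is a slow sinusoid (one random frequency and phase per parameter,
    amplitude ``drift_amp`` mm or rad-equivalent) whose frame-to-frame change
    stays far below scrubbing thresholds. Each frame in ``spike_frames`` adds
    a sustained ``spike_mm`` step to the x translation, producing a single FD
    excursion at that frame.
    """
    spike_frames = [int(f) for f in spike_frames]
    if any(f < 0 or f >= n_frames for f in spike_frames):
        raise ValueError("spike frames must lie inside the run")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * tr
    params = np.zeros((n_frames, 6))
    if drift_amp > 0:
        for j in range(6):
            freq = rng.uniform(0.005, 0.015)
            phase = rng.uniform(0, 2 * np.pi)
            amp = drift_amp if j < 3 else drift_amp / 50.0  # rotations stay small
            params[:, j] = amp * np.sin(2 * np.pi * freq * t + phase)
    for f in spike_frames:
        params[f:, 0] += spike_mm
    return MotionTrace(params=params)
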
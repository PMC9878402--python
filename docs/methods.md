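# Methods

## Model and assumptions

The pipeline treats a resting-state run as an ROI × time matrix in which
brain-wide synchronization appears as brief epochs where one spatial mode
dominates the local covariance. Within a sliding window the timecourses are
z-normalized, so the first principal component coincides with the top
eigenvector of the window correlation matrix and the explained variance
with its top eigenvalue divided by the ROI count. A temporal
synchronization (TS) event is a strict local maximum of that
explained-variance timecourse; plateaus and endpoints never qualify,
because on a smooth variance estimate an exact tie indicates degeneracy
rather than an event. The analysis deliberately uses only the first PC:
the sign-alignment rule (below) has no analogue for higher components at
this window length.

Key assumptions: the BOLD signal has been cleaned and band-limited
upstream (only a temporal band-pass, frame trimming and motion scrubbing
are applied here); synchronization episodes are transient at the window
scale (~18 s); and event-locked responses superpose linearly.

## Parameter defaults

| parameter | default | units | role |
|---|---|---|---|
| `tr` | 0.72 | s | sampling interval of the emulated acquisition |
| `window_size` | 25 | frames | sw-PCA window (18 s); odd so the center is a frame |
| `band_low`, `band_high` | 0.009, 0.08 | Hz | zero-phase Butterworth band-pass (order 4 per pass) |
| `trim` | 38 | frames | discarded at each run edge before detection |
| `fd_threshold` | 0.5 | mm | FD above this marks a head movement |
| `scrub_after` | 30 | frames | additionally masked after each movement |
| `head_radius` | 50 | mm | converts rotations to displacement in FD |
| `min_ts` | 60 | events | runs with fewer TS are excluded (kept at exactly 60) |
| `k`, `n_init` | 12, 100 | — | sub-cluster count and k-means restarts |
| `var_smooth` | 0 | frames | optional moving average on the variance timecourse before the maxima search |
| `glm_trim` | 50 | frames | discarded at each edge in the event GLM |
| `pmi_smooth` | 50 | frames | moving average of occurrence timecourses |
| `pmi_t_trim`, `pmi_tau_min` | 100, 100 | frames | PMI regression exclusions |
| `knn_k` | 100 | — | neighbours for task-TSP transfer (5 exposed as an alternative preset) |
| `cca_n_pcs`, `cca_n_perm` | 50, 10,000 | — | PCA dimension and permutations in the CCA pipeline |

Zero-phase filtering matters because window centers index event times; a
causal filter would shift them. The FD convention (sum of absolute
parameter derivatives, rotations at a 50 mm radius) is the standard one.
The run-exclusion rule is directionally ambiguous in its usual phrasing;
it is implemented as a configurable minimum with "keep at exactly the
threshold".

## Synthetic data generator

`synthetic.simulate_run` emulates an HCP-like resting-state run: 1,200
frames at TR 0.72 s over ~264 ROIs, band-limited Gaussian noise plus
transient brain-wide co-activation events with a ground-truth log.

**Patterns.** `make_pattern_set` draws zero-mean unit ROI vectors in
anti-correlated pairs (within-pair r ≈ −0.95; cross-pair |r| < 0.3,
enforced by bounded redraws). Near-mirrored pairs reflect the phenomenology
the pipeline is built around: the two sub-clusters of a cluster are
rising/falling phases of one spatial mode, so their patterns are nearly
sign-flipped copies.

**Event transient.** Each event adds `amplitude × pattern × kernel`, where
the default kernel is a half-cosine rise spanning exactly one analysis
window followed by an exponential decay (time constant one window), with
the event frame at the rise midpoint. This shape was chosen, after
analysis of the detector, so that the ground-truth event frame is also the
detector's expected answer: the windowed variance of a transient peaks
where the window straddles a balanced low→high transition, and a rise
spanning the window puts that point exactly at the logged center while
giving the PC score a positive slope there (satisfying the sign rule). A
canonical double-gamma HRF kernel is available (`transient='hrf'`), but
with a 25-frame window its windowed variance is bimodal — flank maxima
near −7/+9 frames — so every HRF-shaped event produces two variance maxima
and center-aligned recovery is impossible by construction; it is therefore
not the default.

**Scheduling.** Events form a renewal process: inter-event gaps are
`min_gap` (default 10 frames) plus a gamma draw (shape 8) whose scale is
set so the expected total event rate matches `event_rate`; after each
event its anti-correlated partner follows one window later with
probability 0.5 (the paired-transition phenomenology). The near-regular
gamma gap law avoids the pile-up at the minimum gap that an
exponential/geometric law produces — events closer than ~half a window are
unresolvable by any windowed detector, so a memoryless gap law would make
event recovery ill-posed at any density.

**Noise and SNR.** Noise is white Gaussian filtered to 0.009–0.08 Hz with
an order-6 zero-phase Butterworth (order 6 keeps ≥ 95% of the noise power
strictly in band; the analysis filter itself stays at the conventional
order 4). SNR is defined as the ratio of the event component's temporal SD
to the noise SD, averaged over ROIs; a single noise scale is shared by all
ROIs. Voxel-level data broadcast each ROI's timecourse to its voxels plus
independent band-limited voxel noise.

**What the generator does not emulate:** physiological (cardiac or
respiratory) noise, 1/f background, spatial smoothness of voxel noise,
amplitude variability across events, hemodynamic variability across
regions, and any non-event-locked network dynamics. Passing recovery tests
on these simulations therefore shows the pipeline is correct and
well-calibrated under its own generative assumptions — not that those
assumptions hold in real BOLD data.

## Benchmark conditions (the package's own choices)

- **Pair recovery** (the headline check, also in `scripts/acceptance.py`):
  20 runs × 1,200 frames, ~75 events/run, snr 1, detection with the default
  (unsmoothed) variance timecourse, k-means k = 12 with 100 restarts,
  transition pairing; a designed pair counts as recovered when a fitted
  pair's centroids match it one-to-one at r ≥ 0.9.
- **Event recovery**: 50 runs at ~46 events/run (event_rate 0.04), snr 1,
  variance smoothing width 11. At ~75 events/run the pair-transition
  structure forces mean inter-event gaps of ~11 frames, which no 25-frame
  windowed detector can resolve into distinct maxima, so the per-event
  benchmark uses a density at which transients still tile the run but
  remain separable. A detection counts as *recovering* an event when it
  lies within ±3 frames; it counts as *false* only when it is farther than
  half a window (12 frames) from every true event — in between it is a
  mislocalization, penalized through the recovery rate rather than twice.
- **GLM map recovery**: 8 runs × 2,000 voxels (100 ROIs × 20 voxels),
  snr 1, design built from the ground-truth event log, run-level betas
  averaged (the fixed-effect step).
- **PMI calibration**: 20 repetitions of 2 stationary 600-frame 100-ROI
  runs, 100 surrogates each, (t, τ) grid strided by 4. With an exact
  exchangeability-based 5% test, 20 repetitions resolve the false-positive
  rate only to ±(2 × binomial SE) ≈ ±0.10, so calibration is asserted as
  at most 2 of 20 repetitions significant per coefficient family.
- **CCA**: 200 subjects, 400 pixels, 60 measures, one latent factor with
  construction canonical correlation 0.9, PCA-50, 1,000 permutations;
  null calibration over 60 independent repetitions at 500 permutations
  (an independent 200-repetition study puts the empirical family-wise
  false-positive rate of the procedure at 0.050).

## Numerical choices

- **sw-PCA in Gram space.** With w ≪ N the w × w Gram matrix Zᵀ Z shares
  its nonzero eigenvalues with the N × N window correlation matrix (up to
  the 1/w factor), so a full run is three batched operations (normalize,
  einsum, batched `eigh`). Loadings are recovered as Z v / ‖Z v‖. Windows
  where every ROI is constant are flagged and skipped.
- **Sign rule.** "Score increases toward the event" is operationalized as
  the sign of the least-squares slope of the first-PC score over the
  window; an exactly zero slope leaves the sign and flags the event
  ambiguous.
- **Variance-timecourse smoothing.** The maxima search runs on the raw
  estimate by default; an optional moving average (`var_smooth`) is exposed
  because the per-window eigenvalue is a noisy estimator whose ripple
  creates spurious maxima. The event-recovery benchmark uses width 11
  (about half a window).
- **Spherical k-means.** Centroid update = mean of member vectors,
  re-centered and renormalized (with centered unit vectors, correlation is
  a dot product); an emptied cluster is re-seeded from the worst-fit
  point; restart selection minimizes Σ(1 − r) to assigned centroids.
- **Pairing.** Greedy maximum-weight matching on symmetrized transition
  counts, accepting a pair only if the centroid correlation is negative;
  leftovers fall back to the most anti-correlated unmatched partner under
  a warning.
- **PMI estimator.** Probabilities are ratios of run-summed smoothed
  occurrence products to run-summed smoothed any-TS products, which makes
  the "given a TS of any cluster" conditioning explicit; cells whose
  conditioning probability or denominators fall below 1e-6, or whose joint
  probability is non-positive, are masked and never imputed. The published
  definition of the statistic as typeset multiplies Pr(Y|X) by Pr(X),
  which is not a ratio and conflicts with the surrounding description;
  the standard PMI reading log₂(Pr(Y|X)/Pr(Y)) is implemented, with the
  literal form available via `form='literal'` for comparison.
- **Surrogates.** One conjugate-symmetric random phase vector is shared by
  all ROIs (common-phase randomization): independent phases would destroy
  cross-covariance, which the null is required to preserve. DC and (for
  even lengths) Nyquist bins are untouched, so the output is exactly real
  and per-ROI spectra are preserved to machine precision.
- **GLM.** OLS without prewhitening (an AR(1) option can be added at the
  design level via extra regressors; at synthetic scale residual
  autocorrelation biases no spatial comparison). The group model is the
  summary-statistics approximation: run betas averaged within subject,
  one-sample t across subjects mapped to a signed z, capped at ±40 where
  between-subject variance vanishes.
- **CCA.** Classical CCA via QR of both centered blocks and SVD of
  QxᵀQy; permutation of subject rows on the measure side; FWE p per mode
  from the per-permutation maximum canonical correlation, floored at
  1/(n_perm + 1). Weights are correlations of the original variables with
  the canonical variates.
- **Empirical p-values** everywhere use the fraction convention with the
  1/(n + 1) floor.

## Design decisions on open points

- **kNN score threshold.** The rule "scores lower than the 5th percentile
  of random-pattern scores are set to 0" zeroes, by construction, about 5%
  of random queries; it is a junk filter, not a rejection test. The
  implementation follows that rule as stated.
- **Cluster-validity index.** The within/between mean correlation-distance
  ratio is the primary index (lower = tighter); a silhouette coefficient
  under the same distance is computed alongside, since the literature the
  index descends from does not pin one choice.
- **PMI pooling.** Occurrence probabilities are estimated per run and
  pooled inside the PMI estimator (ratio of summed products); per-subject
  decomposition with coefficient averaging is available by calling the
  decomposition per subject.
- **Negative control for SAP maps.** Shuffling event frames does not push
  map–truth correlations to zero: at study densities, transients tile the
  run, so even a shuffled regressor captures event signal, and the
  resulting map is a random direction inside the designed 12-pattern span
  (~6 effective dimensions, since pairs are near-mirrored). A random
  direction there correlates at ~0.2–0.3 with a designated pattern no
  matter how many runs are averaged (correlation is scale-free). The
  control therefore asserts collapse of the matched correlation to below
  0.35 against ≥ 0.9 when the timing is intact.

## Known limitations

- Detection resolution is bounded by the window: events closer than about
  half a window merge into one variance maximum. Localization jitter at
  snr 1 is a few frames even for isolated events.
- The explained-variance timecourse of band-limited noise itself exhibits
  local maxima at the autocorrelation timescale; at realistic densities
  these are absorbed by true events, but on event-free data the detector
  (by design, like the analysis it implements) still reports TS events.
- Permutation schemes ignore family/kinship exchangeability structure; a
  hook for block permutations exists at the call sites but no block logic
  is implemented.
- The GLM omits motion/drift nuisance regressors by default (cleaned input
  assumed); extra columns can be appended to the design before fitting.
- No CIFTI/grayordinate support: voxel data travel as plain NIfTI-1 and
  matrices.
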
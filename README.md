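# swsync

Transient whole-brain synchronization analysis for resting-state BOLD time
series: sliding-window PCA event detection, synchronization-pattern
clustering, event-coded GLM activation maps, and temporal-structure
statistics with surrogate testing.

## The problem

Resting-state fMRI is usually summarized by time-averaged functional
connectivity, but much of the interesting structure is transient: moments at
which signals across the whole brain briefly synchronize. `swsync`
implements an event-based analysis of such moments for ROI × time BOLD
matrices (e.g. HCP-style runs: TR 0.72 s, 1,200 frames, ~264 ROIs), together
with a fully specified synthetic-data generator so every stage can be
validated against known ground truth.

It is intended for methods researchers in dynamic functional connectivity
who want a tested, reproducible reference pipeline, and for simulation
studies of event-detection behaviour.

## The method

1. **Detection (sw-PCA).** A window of *w* = 25 frames (18 s) slides over
   the band-passed (0.009–0.08 Hz), trimmed ROI matrix with stride 1. In
   each window the timecourses are z-normalized, so the first principal
   component is the top eigenvector of the window correlation matrix **C**
   and its explained variance is λ₁(**C**)/N. **Temporal synchronization
   (TS)** events are strict local maxima of the explained-variance
   timecourse; windows overlapping motion-scrubbed frames (FD > 0.5 mm,
   plus 30 frames after) are discarded.
2. **TSPs.** The unit first-PC loading vector at an event is its **temporal
   synchronization pattern (TSP)**, sign-aligned so the PC score increases
   toward the event.
3. **Clustering.** TSPs pooled over runs are clustered by k-means with
   correlation distance (1 − *r*, *k* = 12, 100 restarts). Sub-clusters are
   paired into clusters by maximum-weight matching on the symmetrized
   transition-count matrix, gated on anti-correlated centroids — mutually
   transiting, spatially opposite pattern pairs.
4. **SAP maps.** Event trains per sub-cluster, convolved with the canonical
   double-gamma HRF, are regressed against voxel timecourses (OLS per run;
   runs averaged within subject; one-sample t → z across subjects), giving
   **synchronized activation patterns (SAPs)**.
5. **Temporal structure (PMI).** Cluster-occurrence timecourses (50-frame
   moving average) enter the pointwise mutual information
   PMI(t, τ) = log₂ Pr(Y_b = 1 at t+τ | X_a = 1 at t) / Pr(Y_b = 1 at t+τ),
   decomposed by linear regression into lag (τ), time (t) and zero-lag
   effects, with family-wise significance from common-phase-randomized
   surrogates (which preserve all auto- and cross-covariance).
6. **Associations.** Static RSFC regression on cluster occurrence, spatial
   consistency with task maps (Hedges' *g*), and a deconfounded
   rank-transform → PCA → CCA pipeline with subject-permutation FWE.

## Worked example

Simulate four runs built from six anti-correlated spatial pattern pairs at
snr 1, detect TS events, cluster and pair the TSPs, and compare the
recovered centroids with the generating patterns:

```python
import swsync

patterns = swsync.make_pattern_set(n_rois=264, n_pairs=6, seed=1)
config = swsync.PipelineConfig()

events_per_run = []
for seed in range(1, 5):
    run = swsync.simulate_run(patterns, n_frames=1200, tr=0.72,
                              event_rate=0.0625, snr=1.0, seed=seed)
    events, _ = swsync.detect_run(run.roi_ts, config)
    events_per_run.append(events)
    print(f"run {seed}: {run.log.n_events} true events, {len(events)} TS detected")

model, transitions = swsync.cluster_runs(events_per_run, config)
n_pairs, details = swsync.recovered_pairs(model, patterns, r_thresh=0.9)
print(f"recovered {n_pairs} of 6 designed pattern pairs")
for d in details[:2]:
    print(f"cluster {d['cluster']}: sub-clusters {d['subclusters']} -> "
          f"patterns {d['patterns']}, r = ({d['r'][0]:.3f}, {d['r'][1]:.3f})")
```

Output:

```
run 1: 73 true events, 75 TS detected
run 2: 74 true events, 76 TS detected
run 3: 74 true events, 74 TS detected
run 4: 74 true events, 77 TS detected
recovered 5 of 6 designed pattern pairs
cluster 0: sub-clusters (4, 5) -> patterns (8, 9), r = (0.945, 0.944)
cluster 1: sub-clusters (0, 9) -> patterns (4, 5), r = (0.930, 0.917)
```

Each run of ~74 events yields about as many detected TS windows. With only
four runs, one pair's centroids fall just short of the r ≥ 0.9 bar; pooling
20 runs (as `scripts/acceptance.py` does) recovers all six pairs with
centroid correlations around 0.97.

A command-line interface mirrors the library
(`swsync simulate|preprocess|detect|cluster|sap|pmi|surrogate|associate|run-all`).

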
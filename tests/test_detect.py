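import numpy as np
import pytest

import swsync
from swsync.detect import (detect_ts, extract_tsp, sliding_windows, swpca,
                           sync_measures, window_size_scan)
from swsync.preprocess import RoiTimeseries, ScrubMask, window_znorm


def _ts(data, tr=0.72):
    return RoiTimeseries(data=np.asarray(data, dtype=float), tr=tr)


class TestSlidingWindows:
    @pytest.mark.parametrize("n_frames,w,n_windows", [
        (1124, 25, 1100),    # the study-scale bookkeeping
        (25, 25, 1),
        (100, 5, 96),
    ])
    def test_window_counts(self, n_frames, w, n_windows):
        wins = sliding_windows(n_frames, w)
        assert wins.shape[0] == n_windows
        assert np.all(wins[:, 1] - wins[:, 0] == (w - 1) // 2)
        assert np.all(wins[:, 2] - wins[:, 0] == w - 1)

    def test_window_longer_than_run_fails(self):
        with pytest.raises(ValueError):
            sliding_windows(24, 25)

    def test_even_window_fails(self):
        with pytest.raises(ValueError):
            sliding_windows(100, 24)


class TestSwpca:
    def test_rank_one_window_explains_everything(self):
        t = np.linspace(0, 2 * np.pi, 31)
        data = np.outer([1.0, -2.0, 0.5, 3.0], np.sin(t))
        res = swpca(_ts(data), 31)
        assert res.variance.values[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_bruteforce_eigendecomposition(self, rng):
        data = rng.standard_normal((12, 60))
        w = 9
        res = swpca(_ts(data), w)
        for k in (0, 7, 33, 51):
            win, _ = window_znorm(data[:, k:k + w])
            corr = win @ win.T / w
            evals, evecs = np.linalg.eigh(corr)
            assert res.variance.values[k] == pytest.approx(
                evals[-1] / np.trace(corr), abs=1e-8)
            top = evecs[:, -1]
            assert abs(abs(top @ res.loadings[k]) - 1) < 1e-8

    def test_iid_noise_variance_low_and_stable(self):
        # white noise: the 1st PC explains little and fluctuates mildly
        sds, means = [], []
        for seed in range(10):
            data = np.random.default_rng(seed).standard_normal((264, 200))
            res = swpca(_ts(data), 25)
            means.append(res.variance.values.mean())
            sds.append(res.variance.values.std())
        assert np.mean(means) < 0.2
        assert max(sds) < 0.05

    def test_scale_invariance(self, small_run):
        res1 = swpca(small_run.roi_ts, 25)
        scaled = _ts(small_run.roi_ts.data * 37.5)
        res2 = swpca(scaled, 25)
        assert np.allclose(res1.variance.values, res2.variance.values, atol=1e-10)
        assert np.allclose(np.abs(res1.loadings), np.abs(res2.loadings), atol=1e-8)

    def test_roi_permutation_equivariance(self, small_run):
        perm = np.random.default_rng(1).permutation(small_run.roi_ts.n_rois)
        res1 = swpca(small_run.roi_ts, 25)
        res2 = swpca(_ts(small_run.roi_ts.data[perm]), 25)
        assert np.allclose(res1.variance.values, res2.variance.values, atol=1e-10)
        k = 40
        assert np.allclose(res1.loadings[k][perm], res2.loadings[k], atol=1e-8) or \
            np.allclose(res1.loadings[k][perm], -res2.loadings[k], atol=1e-8)


class TestExtractTsp:
    def test_increasing_score_keeps_sign(self):
        load = np.array([0.6, -0.8])
        tsp, amb = extract_tsp(load, np.arange(9, dtype=float))
        assert np.array_equal(tsp, load) and not amb

    def test_decreasing_score_flips_sign(self):
        load = np.array([0.6, -0.8])
        tsp, amb = extract_tsp(load, np.arange(9, 0, -1, dtype=float))
        assert np.array_equal(tsp, -load) and not amb

    def test_flat_score_is_ambiguous(self):
        tsp, amb = extract_tsp(np.array([1.0, 0.0]), np.ones(9))
        assert amb

    def test_tsp_positively_correlates_with_generating_pattern(self, small_patterns):
        run = swsync.simulate_run(small_patterns, n_frames=1200, seed=21,
                                  snr=2.0, event_rate=0.03)
        events, _ = swsync.detect_run(run.roi_ts, swsync.PipelineConfig())
        true = np.array(run.log.center_frames)
        rs = []
        for ev in events:
            i = np.argmin(np.abs(true - ev.center_frame))
            if abs(true[i] - ev.center_frame) <= 3:
                p = small_patterns.patterns[run.log.pattern_ids[i]]
                rs.append(np.corrcoef(ev.tsp, p)[0, 1])
        assert len(rs) > 10
        assert np.mean(rs) > 0.5           # signed: recovered, not inverted
        assert np.mean(np.array(rs) > 0) > 0.9


class TestDetectTs:
    def test_single_bump_single_event(self):
        """A unimodal variance timecourse yields exactly one event at its peak."""
        res = swpca(_ts(np.random.default_rng(0).standard_normal((6, 125))), 25)
        centers = res.variance.centers
        res.variance.values = np.exp(-0.5 * ((centers - 60) / 10.0) ** 2)
        events = detect_ts(res)
        assert len(events) == 1
        assert events[0].center_frame == 60

    def test_monotone_variance_no_events(self):
        class Fake:
            pass
        res = swpca(_ts(np.random.default_rng(1).standard_normal((5, 60))), 25)
        res.variance.values = np.linspace(0.2, 0.8, res.variance.values.size)
        assert detect_ts(res) == []

    def test_scrubbed_interval_drops_events(self, small_run):
        res = swpca(small_run.roi_ts, 25)
        all_events = detect_ts(res)
        assert all_events
        mask = ScrubMask(np.ones(small_run.roi_ts.n_frames, dtype=bool))
        assert detect_ts(res, mask) == []
        # masking one event's window removes exactly the overlapping events
        target = all_events[0]
        m = np.zeros(small_run.roi_ts.n_frames, dtype=bool)
        m[target.center_frame] = True
        kept = detect_ts(res, ScrubMask(m))
        assert all(e.center_frame != target.center_frame for e in kept)


class TestSyncMeasures:
    def test_identical_timecourses_frobenius_is_roi_count(self):
        t = np.sin(np.linspace(0, 8 * np.pi, 200))
        data = np.tile(t, (6, 1)) + 1e-9 * np.random.default_rng(0).standard_normal((6, 200))
        out = sync_measures(_ts(data), 25)
        assert out["frobenius_norm"].iloc[100] == pytest.approx(6.0, rel=1e-3)

    def test_synchronized_sinusoids_phase_sync_one(self):
        t = np.sin(np.linspace(0, 8 * np.pi, 200))
        data = np.vstack([t * a for a in (1.0, 2.0, 0.5)])
        out = sync_measures(_ts(data), 25)
        mid = out["phase_sync"].iloc[50:150]
        assert np.all(mid > 1 - 1e-6)

    def test_independent_signals_low_phase_sync(self):
        hits = 0
        for seed in range(20):
            data = np.random.default_rng(seed).standard_normal((264, 300))
            out = sync_measures(_ts(data), 25, measures=("phase_sync",))
            hits += out["phase_sync"].iloc[150] < 0.15
        assert hits >= 19    # ~N^(-1/2) = 0.06 for 264 independent phases

    def test_ppa_counts_threshold_crossings(self):
        data = np.zeros((4, 100))
        data[:, :] = np.random.default_rng(2).standard_normal((4, 100)) * 0.1
        data[:3, 50] = 10.0
        out = sync_measures(_ts(data), 25)
        assert out["ppa_count"].loc[50] == 3


class TestWindowSizeScan:
    def test_single_size_matches_swpca(self, small_run):
        scan = window_size_scan(small_run.roi_ts, [25])
        direct = swpca(small_run.roi_ts, 25)
        assert np.allclose(scan["variance"][25].values, direct.variance.values)

    def test_empty_size_list_fails(self, small_run):
        with pytest.raises(ValueError):
            window_size_scan(small_run.roi_ts, [])

    def test_maxima_consistent_across_sizes_for_sparse_events(self, small_patterns):
        """Well-separated events yield nearly size-independent maxima.

        Positions are compared on a mildly smoothed variance timecourse;
        the 35-frame window trails the 25-frame reference by a few frames
        because it out-spans the transient, so the tolerance is +-3.
        """
        run = swsync.simulate_run(small_patterns, n_frames=900, seed=13,
                                  snr=2.0, event_rate=0.008, pair_prob=0.0)
        assert run.log.n_events >= 3
        true = np.array(run.log.center_frames)
        positions = {}
        for w in (15, 25, 35):
            res = swpca(run.roi_ts, w)
            v = np.convolve(res.variance.values, np.ones(11) / 11, mode="same")
            idx = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1
            maxima = res.variance.centers[idx]
            positions[w] = np.array([maxima[np.argmin(np.abs(maxima - c))]
                                     for c in true])
        for w in (15, 35):
            assert np.abs(positions[w] - positions[25]).max() <= 3
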
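import dataclasses

import numpy as np
import pytest

import swsync


@pytest.fixture(scope="session")
def small_patterns():
    """Three anti-correlated pattern pairs over 40 ROIs."""
    return swsync.make_pattern_set(n_rois=40, n_pairs=3, seed=7)


@pytest.fixture(scope="session")
def small_run(small_patterns):
    """One 400-frame run at snr 2 with a handful of events."""
    return swsync.simulate_run(small_patterns, n_frames=400, seed=11, snr=2.0,
                               event_rate=0.04)


@pytest.fixture()
def config():
    return swsync.PipelineConfig()


@pytest.fixture()
def smooth_config():
    """Detection configuration used for event-recovery benchmarks."""
    return dataclasses.replace(swsync.PipelineConfig(), var_smooth=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
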
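import numpy as np
import pytest

from seizstate import SynthConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 4-state cohort used across recovery tests (ground truth retained)."""
    cfg = SynthConfig(
        n_channels=5,
        n_seizures=80,
        recording_days=60,
        state_library_size=4,
        window_noise_sd=0.05,
        seed=3,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = SynthConfig(
        n_channels=4,
        n_seizures=40,
        recording_days=45,
        state_library_size=3,
        window_noise_sd=0.0,
        spike_noise_sd=0.0,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
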
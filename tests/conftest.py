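import numpy as np
import pytest

from hfodet.simkit import SimulationConfig, make_gold_standard


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but learnable simulation: 40+40 segments, 4 patients."""
    return SimulationConfig(n_hfo=40, n_nc=40, n_patients=4, n_channels=8, seed=11)


@pytest.fixture(scope="session")
def small_gold(small_config):
    return make_gold_standard(small_config)


@pytest.fixture(scope="session")
def trainable_gold():
    """200 clearly separable segments (high burst SNR) for training sanity checks."""
    cfg = SimulationConfig(n_hfo=100, n_nc=100, n_patients=4, seed=5, burst_snr_db=20.0)
    return cfg, make_gold_standard(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
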
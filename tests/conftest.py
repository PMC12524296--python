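import numpy as np
import pytest

import glycospec as gs


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def benchmark():
    """169-band selector benchmark: 10 independently informative bands."""
    X, y, idx = gs.make_band_recovery_benchmark(seed=3)
    return X, y, idx


@pytest.fixture(scope="session")
def small_dataset():
    """30-sample synthetic study dataset (fast path for model tests)."""
    config = gs.SyntheticConfig(n_per_day=10, seed=7)
    dataset, truth = gs.generate_dataset(config)
    return dataset, truth, config


@pytest.fixture(scope="session")
def noiseless_config():
    return gs.SyntheticConfig(
        scatter_sd=0.0, baseline_slope_sd=0.0, noise_sd=0.0,
        image=gs.ImageConfig(pixel_gain_jitter_sd=0.0),
    )
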
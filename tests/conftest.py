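import numpy as np
import pytest

import eegtwin as et


@pytest.fixture(scope="session")
def small_subject():
    """One deterministic synthetic subject with a strong mu-band class effect."""
    cfg = et.SimulationConfig(
        n_trials_per_class=50, n_channels=8, erd_depth=0.8,
        band_jitter=0.0, seed=11,
    )
    return et.generate_subject(cfg, 0)


@pytest.fixture(scope="session")
def small_bank():
    """Compact five-band bank covering mu and beta."""
    return et.FilterBankSpec(bands=[(4, 8), (8, 12), (12, 16), (16, 24), (24, 32)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def separable_blobs(rng, n_per_class=40, d=2, sep=6.0):
    """Two well-separated Gaussian blobs with labels in {+1, -1}."""
    a = rng.standard_normal((n_per_class, d)) + sep / 2
    b = rng.standard_normal((n_per_class, d)) - sep / 2
    X = np.vstack([a, b])
    y = np.r_[np.ones(n_per_class), -np.ones(n_per_class)]
    return X, y
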
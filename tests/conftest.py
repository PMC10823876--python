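import numpy as np
import pytest

from emgvdi import (
    GESTURES,
    SampleMatrix,
    SimConfig,
    default_activation_profile,
    simulate_window,
)


@pytest.fixture(scope="session")
def profile():
    return default_activation_profile()


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=0, n_windows_per_gesture=3)


@pytest.fixture(scope="session")
def fist_window(profile, sim_cfg):
    """One default 200 x 4 simulated window for the fist gesture."""
    return simulate_window(GESTURES[3], profile, sim_cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_window():
    """Tiny handmade 4 x 2 window for exact-arithmetic checks."""
    return SampleMatrix(
        np.array([[1.0, -2.0], [0.0, 3.0], [2.0, 1.0], [-1.0, 0.0]]),
        fs=1000.0,
    )
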
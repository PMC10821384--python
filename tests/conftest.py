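import numpy as np
import pytest

from radonmetry import (
    DeviceCountData,
    RadonSeries,
    YlcmSimConfig,
    simulate_ylcm,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def constant_series():
    """A full 3-h YLCM pinned at 120 Bq/m3."""
    return RadonSeries(values=np.full(2920, 120.0), step_hours=3.0)


@pytest.fixture
def tiny_series():
    """Four samples at 6-h step (not a full year; for transform arithmetic)."""
    return np.array([1.0, 2.0, 3.0, 4.0])


@pytest.fixture(scope="session")
def sim_room():
    """One simulated YLCM room at the default study conditions."""
    return simulate_ylcm(YlcmSimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_ensemble_matrix():
    """Ten simulated rooms stacked as a (10, 2920) matrix."""
    rows = [simulate_ylcm(YlcmSimConfig(seed=s)).values for s in range(1, 11)]
    return np.vstack(rows)


@pytest.fixture
def example_device():
    """The counting-device worked example: C = 100 Bq/m3, U_D ~ 0.124."""
    return DeviceCountData(
        n_g=1000.0, t=1e4, n_0=100.0, t_0=1e4,
        epsilon=9e-4, u_rel_epsilon=0.05, k=2.0,
    )
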
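import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vhitdrift as vd

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """One 57-impulse dataset at the default (clinic-emulating) settings."""
    cfg = vd.SimulationConfig(seed=1)
    return vd.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_features(default_dataset):
    windows, _, _ = default_dataset
    return vd.feature_table(windows)


@pytest.fixture(scope="session")
def constructed_windows():
    """Noiseless dataset exactly correctable by a known theta."""
    cfg = vd.constructed_solution_config(seed=0)
    windows, _, _ = vd.simulate_dataset(cfg)
    return windows


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
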
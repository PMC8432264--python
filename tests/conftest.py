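import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import cordmotion as cm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg():
    return cm.default_config()


@pytest.fixture(scope="session")
def small_cfg():
    """A single-group cohort small enough for fast unit tests."""
    cfg = cm.default_config()
    cfg.group_sizes = {"C5/C6": 8}
    return cfg


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return cm.generate_cohort(small_cfg, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
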
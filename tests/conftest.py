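import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mieeg import GeneratorConfig, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def small_trialset(default_config):
    """30 trials/class with the default ERD/ERS structure (seed 7)."""
    return generate_dataset(default_config, 30)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
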
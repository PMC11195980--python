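import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cvdpm.synthetic import SyntheticConfig, generate_calibration

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig(seed=7, population_size=10_000)


@pytest.fixture(scope="session")
def bundle(config):
    """One shared synthetic calibration bundle (small population)."""
    return generate_calibration(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
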
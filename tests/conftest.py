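import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iodinedna import GeneratorConfig, generate_events

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    """The package's stated synthetic world, fixed seed."""
    return GeneratorConfig(seed=20260918)


@pytest.fixture(scope="session")
def small_dataset(default_config):
    """4k decays: cheap, enough for structural/oracle checks."""
    return generate_events(default_config, 4000)


@pytest.fixture(scope="session")
def medium_dataset():
    """20k decays on an independent seed, for Monte Carlo comparisons."""
    return generate_events(GeneratorConfig(seed=777), 20000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
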
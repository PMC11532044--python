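import pytest
from hypothesis import settings

from fiscalfood import GeneratorConfig, calibration_bundle, generate_bundle

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cal_bundle():
    """Fixed calibration bundle (back-solved elasticities), shared by tests."""
    return calibration_bundle(n_households=100)


@pytest.fixture(scope="session")
def small_bundle():
    """Small random bundle for generator-agnostic integration tests."""
    return generate_bundle(GeneratorConfig(seed=7, n_households=120, population_size=100_000))
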
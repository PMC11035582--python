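import pytest
from hypothesis import HealthCheck, settings

from alleesense import AlgorithmParameters

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def params() -> AlgorithmParameters:
    """Literature-derived default parameter set used throughout."""
    return AlgorithmParameters()
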
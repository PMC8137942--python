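import pytest
from hypothesis import HealthCheck, settings

from copdscreen import default_parameters, run_arms

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def base_results(params):
    """Discounted per-patient results for the three arms at base case."""
    return run_arms(params)
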
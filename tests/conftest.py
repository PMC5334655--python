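import pytest
from hypothesis import HealthCheck, settings

from avhyd import CohortParams, force_curve, population_mean_subject

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params():
    return CohortParams()


@pytest.fixture(scope="session")
def mean_subject(default_params):
    """Noise-free subject built from the population landmarks."""
    return population_mean_subject(default_params)


@pytest.fixture(scope="session")
def mean_force_curve(mean_subject):
    return force_curve(mean_subject)
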
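import pytest
from hypothesis import HealthCheck, settings

import ptewater as pw

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def defaults():
    return pw.load_defaults()


@pytest.fixture(scope="session")
def cohorts(defaults):
    return {"adult": defaults.adult, "child": defaults.child}


@pytest.fixture(scope="session")
def samples53():
    """A study-shaped synthetic table: 53 samples, eight-element preset."""
    return pw.generate_samples(53, seed=20240629)
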
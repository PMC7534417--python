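import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sweepscan.simulate import make_fixtures

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures():
    """Hard-coded toy datasets shared across modules."""
    return make_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def write_text(path, text):
    path.write_text(text)
    return str(path)
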
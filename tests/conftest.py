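import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rnaforge.backends import ToyBackend

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_backend():
    """One shared toy backend; the fold cache is an implementation detail
    that must never change results, so sharing it across tests is safe."""
    return ToyBackend()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
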
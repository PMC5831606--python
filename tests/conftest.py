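import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def core_model():
    from acetogas.metabolic_model import core_acetogen_model

    return core_acetogen_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
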
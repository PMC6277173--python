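import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "cdrloop",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cdrloop")

from cdrloop import make_loop_system, make_template_set  # noqa: E402


@pytest.fixture(scope="session")
def loop_system():
    return make_loop_system(seed=11)


@pytest.fixture(scope="session")
def templates(loop_system):
    return make_template_set(loop_system, 3, separation=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
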
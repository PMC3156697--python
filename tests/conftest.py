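import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from molsock import make_synthetic_model, toy_score  # noqa: E402


@pytest.fixture
def helix10():
    return make_synthetic_model(10, seed=7, name="helix10")


@pytest.fixture
def helix100():
    return make_synthetic_model(100, seed=3, name="helix100")


@pytest.fixture
def helix10_energies(helix10):
    return toy_score(helix10)
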
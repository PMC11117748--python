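import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def t1_model():
    from nadflux.fixtures import make_t1_model

    return make_t1_model()


@pytest.fixture
def toy_model():
    from nadflux.fixtures import ToyModelSpec, make_toy_model

    return make_toy_model(ToyModelSpec(seed=0))


@pytest.fixture
def toy_km(toy_model):
    from nadflux.fixtures import make_toy_km_table

    return make_toy_km_table(toy_model, seed=0)


@pytest.fixture
def concentrations():
    from nadflux.fixtures import toy_concentrations

    return toy_concentrations()
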
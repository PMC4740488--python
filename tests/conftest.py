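import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wakeupcea as w

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params():
    return w.default_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mrs_dist():
    return w.placeholder_mrs_distribution()


@pytest.fixture(scope="session")
def life_table():
    return w.synthesize_life_table()


@pytest.fixture(scope="session")
def zero_mortality_table():
    return w.synthesize_life_table(makeham_a=1e-12, makeham_b=1e-12, max_age=200.0)
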
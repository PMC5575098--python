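import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dnacyclize.params_io import DNASequence
from dnacyclize.synthetic import random_sequence, straight_step_table


@pytest.fixture(scope="session")
def straight_table():
    return straight_step_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_seq():
    return DNASequence("short", "ACGTACGTAC")


@pytest.fixture(scope="session")
def seq63():
    return random_sequence(63, 0.5, np.random.default_rng(63), id="seq63")
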
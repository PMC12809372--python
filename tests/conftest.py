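import pytest
from hypothesis import HealthCheck, settings

import nhobs

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def figure1():
    return nhobs.make_fixture("figure1_schematic")


@pytest.fixture
def small_cohort():
    from tests.oracles import small_params

    return nhobs.generate_cohort(small_params(7))
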
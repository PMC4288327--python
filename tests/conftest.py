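import pytest
from hypothesis import settings

from bpapk import DoseSchedule, load_parameter_set, simulate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rat_adult():
    return load_parameter_set("rat", "adult")


@pytest.fixture(scope="session")
def monkey_adult():
    return load_parameter_set("monkey", "adult")


@pytest.fixture(scope="session")
def human_adult():
    return load_parameter_set("human", "adult")


@pytest.fixture(scope="session")
def rat_iv_96h(rat_adult):
    """Adult rat, i.v. bolus 100 μg/kg, 96 h — the reference i.v. scenario."""
    return simulate(rat_adult, DoseSchedule.single("iv", 100.0), 96.0)


@pytest.fixture(scope="session")
def monkey_iv_96h(monkey_adult):
    return simulate(monkey_adult, DoseSchedule.single("iv", 100.0), 96.0)
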
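import numpy as np
import pytest

from paccsim import (
    DrugSchedule,
    Interval,
    ModelParameters,
    make_schedule,
    make_scenario,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def schedule_same():
    return make_schedule(same_drug=True)


@pytest.fixture(scope="session")
def schedule_different():
    return make_schedule(same_drug=False)


@pytest.fixture(scope="session")
def drug_free_schedule():
    """A therapy-free window, for mean-field and equilibrium checks."""
    return DrugSchedule(intervals=(Interval(0.0, 50.0),))


@pytest.fixture(scope="session")
def all_scenarios():
    return [
        make_scenario("single_state", m=0.5),
        make_scenario("pacc_no_R", sigma2=0.05),
        make_scenario("pacc_memory"),
        make_scenario("innate_resistance"),
        make_scenario("temporary_innate_resistance"),
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.RandomState(20240917)
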
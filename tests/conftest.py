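import numpy as np
import pytest

from headmap.respondent import Respondent
from headmap.simulate import CohortSpec, simulate_cohort
from headmap.tariffs import Tariff, sf6d_tariff, uk_eq5d3l_tariff


@pytest.fixture(scope="session")
def eq_tariff():
    return uk_eq5d3l_tariff()


@pytest.fixture(scope="session")
def sf_tariff():
    return sf6d_tariff()


@pytest.fixture(scope="session")
def cohort_349():
    """Default synthetic cohort at the test-sample size."""
    return simulate_cohort(CohortSpec(n=349, seed=0))


@pytest.fixture(scope="session")
def cohort_5000():
    return simulate_cohort(CohortSpec(n=5000, seed=0))


@pytest.fixture
def valid_respondent():
    return Respondent(
        id="r1", hit6=60, chq_rr=50.0, chq_rp=60.0, chq_ef=55.0,
        age=45, sex="female", eq5d_utility=0.7, sf6d_utility=0.6,
    )


@pytest.fixture
def toy_tariff():
    """Two-dimension additive tariff with both extra-term predicates."""
    return Tariff(
        name="toy",
        constant=1.0,
        decrements={("A", 2): 0.1, ("A", 3): 0.3, ("B", 2): 0.2},
        extra_terms={"any_beyond_level1": 0.05, "any_at_worst": 0.07},
        dimensions=("A", "B"),
        levels=(3, 2),
    )
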
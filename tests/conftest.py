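import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dabipkpd as dp

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pop():
    return dp.default_population()


@pytest.fixture(scope="session")
def study_times():
    return np.asarray(dp.population.STUDY_TIMES)


@pytest.fixture(scope="session")
def small_cohort(pop):
    """Five-sheep paper-design cohort used by several modules' tests."""
    return dp.generate_cohort(pop, dp.paper_design(n_subjects=5, seed=11))


@pytest.fixture(scope="session")
def noise_free_cohort(pop):
    """Deterministic cohort: no BSV, no residual error."""
    quiet = pop.with_values(
        omega={k: 0.0 for k in pop.omega},
        sigmas={"prop_conc": 0.0, "add_conc": 0.0, "prop_r": 0.0, "add_r": 0.0})
    return dp.generate_cohort(quiet, dp.paper_design(n_subjects=3, seed=5)), quiet
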
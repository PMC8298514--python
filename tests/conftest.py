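import logging

import pytest

from enhdiff.synthetic import CohortConfig, simulate_cohort

logging.getLogger("enhdiff").setLevel(logging.ERROR)


SMALL_COHORT_KWARGS = dict(
    n_elements=800,
    n_gained_ec=10,
    n_gained_lnc=10,
    n_common_gained=20,
    n_lost_ec=10,
    n_lost_lnc=10,
    n_common_lost=20,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured paired cohort (800 elements, 80 planted)."""
    return simulate_cohort(CohortConfig(seed=11, **SMALL_COHORT_KWARGS))


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 5000 elements, 400 planted, noise 0.3."""
    return simulate_cohort(CohortConfig(seed=1))
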
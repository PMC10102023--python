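import pytest
from hypothesis import settings

from horamortis import CohortConfig, add_ratios, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_10k():
    """Default-configuration synthetic cohort, n = 10,000, fixed seed."""
    return generate_cohort(CohortConfig(n_cases=10_000, seed=0))


@pytest.fixture(scope="session")
def ratios_10k(cohort_10k):
    annotated, excluded = add_ratios(cohort_10k)
    assert len(excluded) == 0
    return annotated
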
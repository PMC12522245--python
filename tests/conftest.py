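import numpy as np
import pytest

from pasenorm.cohort import DEFAULT_SPEC, apply_exclusions, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 6,000-subject synthetic cohort shared across tests."""
    return generate_cohort(DEFAULT_SPEC.replace(n=6000), seed=11)


@pytest.fixture(scope="session")
def included_males(small_cohort):
    inc, _, _ = apply_exclusions(small_cohort)
    return inc[inc["sex"] == "male"]


@pytest.fixture
def rng():
    return np.random.default_rng(7)
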
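import numpy as np
import pytest

from motorage.cohort import CohortSpec, EffectModel, simulate_cohort_signals
from motorage.features import extract_feature_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down cohort (4 per group, 6 s trials) for fast end-to-end tests."""
    return CohortSpec(group_sizes=(4,) * 8, seed=7, trial_duration=6.0)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort_signals(small_spec, EffectModel())


@pytest.fixture(scope="session")
def small_extraction(small_cohort):
    return extract_feature_matrix(small_cohort)
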
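import numpy as np
import pytest

from proxiscale import CohortConfig, generate_cohort
from proxiscale.pipeline import cohort_feature_table


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (144 observations, 3 raters), seed 7."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return cohort_feature_table(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
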
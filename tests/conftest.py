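import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ehrcsa.synthetic_ehr import Cohort, CohortConfig, InformativeFeature, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_cohort() -> Cohort:
    """48 patients, 10 features, 2 strongly planted + 8 background."""
    cfg = CohortConfig(
        n_cases=23,
        n_controls=25,
        n_features=10,
        informative_features=(
            InformativeFeature("aa_planted_strong", 0.9, 0.1),
            InformativeFeature("bb_planted_mild", 0.6, 0.2),
        ),
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture
def separable_cohort() -> Cohort:
    """One feature equal to the label vector among noise."""
    cfg = CohortConfig(
        n_cases=12,
        n_controls=12,
        n_features=5,
        informative_features=(InformativeFeature("oracle_item", 1.0, 0.0),),
        seed=3,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
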
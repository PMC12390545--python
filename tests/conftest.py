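import numpy as np
import pytest

from gaitsense.features import FeatureTable, build_feature_table
from gaitsense.synthetic_gait import default_profiles, generate_cohort


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 3 conditions x 2 reps of 45 s — desk-scale cohort."""
    return generate_cohort(n_subjects=6, reps=2, duration_s=45.0, seed=11)


@pytest.fixture(scope="session")
def small_table(small_cohort) -> FeatureTable:
    return build_feature_table(small_cohort, subset="accel_only")


@pytest.fixture(scope="session")
def small_trait_map(small_cohort) -> dict:
    return {t.meta.subject_id: t.meta.trait_ei for t, _ in small_cohort}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
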
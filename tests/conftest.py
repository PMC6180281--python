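import numpy as np
import pytest

from eegcomplex import CohortSpec, SampEnParams, extract_feature_table, generate_cohort


@pytest.fixture(scope="session")
def hc_ad3_cohort():
    """Small two-group cohort with the default planted contrast."""
    spec = CohortSpec(
        group_sizes={"HC": 6, "AD3": 6}, duration_s=5.0, seed=11
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def hc_ad3_features(hc_ad3_cohort):
    recordings, _ = hc_ad3_cohort
    return extract_feature_table(recordings, SampEnParams())


@pytest.fixture(scope="session")
def four_group_cohort():
    """One-session-per-subject cohort across all four groups (for CCA)."""
    spec = CohortSpec(
        group_sizes={"HC": 5, "AD1": 5, "AD2": 5, "AD3": 5},
        sessions_per_subject=1,
        duration_s=4.0,
        seed=5,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def four_group_features(four_group_cohort):
    recordings, _ = four_group_cohort
    return extract_feature_table(recordings, SampEnParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
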
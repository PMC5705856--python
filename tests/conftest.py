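import numpy as np
import pytest

from carealert.config import CohortConfig


@pytest.fixture(scope="session")
def neutral_config():
    """Both arms generatively identical: no bias, no alert effect."""
    return CohortConfig(
        n_dyads_per_arm=5,
        study_days=84,
        improvement_prob_given_alert=None,
        improvement_prob_control=None,
        attrition_hazard_per_checkin=0.0,
        bias_report_prob=1.0,
        bias_rating_shift=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(neutral_config):
    from carealert.cohort import generate_cohort

    return generate_cohort(neutral_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
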
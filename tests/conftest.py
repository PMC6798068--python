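import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_effect_config():
    """A small cohort with the standard effect set (runs in seconds)."""
    from bistable_eeg.synth import SimConfig, standard_components

    return SimConfig(
        n_fd=3, n_fi=3, n_fn=0, n_training_trials=0, n_blocks=1,
        trials_per_block=20, p_press1=1.0, p_reversal_fd=0.8,
        p_reversal_fi=0.9, erp_components=standard_components(), seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_effect_config):
    from bistable_eeg.synth import generate_cohort

    return generate_cohort(small_effect_config)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    from bistable_eeg.pipeline import cohort_feature_table

    return cohort_feature_table(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
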
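import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_model():
    """The shipped base-case model (built once; tests must not mutate it)."""
    from migraine_cea.inputs import default_model

    return default_model()


@pytest.fixture(scope="session")
def base_result(base_model):
    return base_model.evaluate()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_panel():
    """A reproducible synthetic panel, 400 patients, both arms, 2 cycles."""
    from migraine_cea.cohort import default_trial_profiles, generate_cohort
    from migraine_cea.inputs import default_transition_matrices

    return generate_cohort(
        default_trial_profiles(), 400, default_transition_matrices(),
        n_cycles=2, seed=42,
    )
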
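import numpy as np
import pytest

from fcbrainage.synthetic import (
    make_aging_covariance_pair,
    simulate_cohort_t0,
    simulate_followup,
)


@pytest.fixture(scope="session")
def small_model():
    """16-node aging covariance pair shared across tests."""
    return make_aging_covariance_pair(
        n_nodes=16, n_factors=4, similarity=0.4, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_model):
    """30-subject baseline cohort with short runs (kept small for speed)."""
    return simulate_cohort_t0(
        n_subjects=30,
        model=small_model,
        frames_per_run=120,
        brain_age_noise_sd=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def longitudinal_cohort(small_cohort):
    return simulate_followup(small_cohort, residual_sd=1.5, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
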
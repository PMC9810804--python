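import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bddkit as bk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 6-patient, 5-session cohort with default noise."""
    return bk.generate_cohort(
        bk.CohortSpec(n_patients=6, n_sessions=5, frames_per_session=80, seed=11)
    )


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Same shape with σ = 0: scale totals exactly affine in latent BDD."""
    return bk.generate_cohort(
        bk.CohortSpec(
            n_patients=6, n_sessions=5, frames_per_session=80, seed=11,
            scale_noise_sd=0.0,
        )
    )
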
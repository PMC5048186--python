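import numpy as np
import pytest

from dietval import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_config():
    """Cohort with every noise source off: reported EI == true TEE and the
    DLW round trip is exact by construction."""
    return CohortConfig(
        seed=7,
        n_subjects=40,
        n_dlw_subjects=40,
        accuracy_mean_by_instrument={"record": 1.0, "ffq": 1.0},
        accuracy_sd_by_instrument={"record": 0.0, "ffq": 0.0},
        cv_within_ei=0.0,
        cv_within_ei_ffq=0.0,
        enrichment_noise_sd=0.0,
    )


@pytest.fixture
def small_config():
    """Small noisy cohort for fast pipeline-level tests."""
    return CohortConfig(seed=11, n_subjects=60, n_dlw_subjects=20)
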
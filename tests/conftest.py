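import numpy as np
import pytest

from spikeseiz import CohortSpec, generate_background, generate_cohort


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Short cohort, cheap enough for session-wide reuse."""
    return CohortSpec(n_patients=4, records_per_patient=1, record_duration_s=120.0,
                      seizure_prevalence=0.1, min_seizure_s=10.0, n_channels=4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_spec):
    return generate_cohort(small_cohort_spec)


@pytest.fixture(scope="session")
def background_record():
    return generate_background(C=3, duration_s=30, fs=256, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
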
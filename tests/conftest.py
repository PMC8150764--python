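import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wristpa.features import extract_cohort_features
from wristpa.synthetic import SyntheticCohortConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

logging.getLogger("wristpa").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-participant cohort (2 per age group), 30 Hz, one window/activity."""
    config = SyntheticCohortConfig(
        n_young=2, n_middle=2, n_old=2, rate_hz=30, duration_s=60.0, seed=42
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return extract_cohort_features(small_cohort.recordings, small_cohort.intervals)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
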
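import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emgspecvar import CohortParams, SpectralVariability, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def small_params(**kwargs) -> CohortParams:
    """Reduced-scale cohort parameters for fast unit tests."""
    defaults = dict(n_participants=2, n_repetitions=3, burst_duration_s=2.0,
                    rest_duration_s=1.0, seed=42)
    defaults.update(kwargs)
    return CohortParams(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_params())


@pytest.fixture(scope="session")
def default_recording():
    """One default-protocol recording (10 x 5 s bursts) plus ground truth."""
    cohort = generate_cohort(CohortParams(n_participants=1, seed=1))
    rec = cohort.recordings[0]
    return rec, cohort.ground_truths[(rec.participant_id, rec.task)]


@pytest.fixture(scope="session")
def small_results():
    """Fitted results on a 6-participant reduced cohort (both norms, all
    orders), shared across tests that inspect the result tables."""
    model = SpectralVariability.from_synthetic(
        small_params(n_participants=6, n_repetitions=4, seed=5))
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
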
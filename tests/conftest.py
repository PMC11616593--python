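import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def moments():
    from ohlra.cohort import default_moments

    return default_moments()


@pytest.fixture(scope="session")
def small_raw_cohort():
    """20 synthetic raw worker records (deterministic fixture)."""
    from ohlra.cohort import generate_raw_records

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_raw_records(20, seed=11)


@pytest.fixture(scope="session")
def continuous_cohort(moments):
    from ohlra.cohort import generate_cohort

    return generate_cohort(moments, n=10_000, seed=5, mode="continuous")


def spd_matrix(rng: np.random.Generator, p: int) -> np.ndarray:
    """Random symmetric positive-definite matrix (test helper)."""
    a = rng.standard_normal((p, p))
    return a @ a.T + p * np.eye(p)
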
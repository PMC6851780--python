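import numpy as np
import pytest

from spirosim import (
    RoundingMode,
    SimulationConfig,
    SubjectProfile,
    derive_sigmas,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_subject():
    return SubjectProfile()


@pytest.fixture(scope="session")
def default_variability(default_subject):
    return derive_sigmas(default_subject, cv_t=0.03, cv_m=0.06)


@pytest.fixture(scope="session")
def default_cohort(default_subject, default_variability):
    """Full-size default cohort (20,902 x 8), shared across tests."""
    config = SimulationConfig(default_subject, default_variability, seed=12345)
    return simulate_cohort(config)


@pytest.fixture()
def small_cohort(default_subject, default_variability):
    config = SimulationConfig(
        default_subject, default_variability, n_tests=500, n_maneuvers=8, seed=99
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
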
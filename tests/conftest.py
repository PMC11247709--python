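import numpy as np
import pytest

from crmsm import SimulationConfig, generate_cohort
from crmsm.panel import Cohort, StateObservation, Subject


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    cohort, record = generate_cohort(SimulationConfig(n=250, seed=42))
    return cohort, record


@pytest.fixture
def toy_subject():
    return Subject(
        id="s1",
        observations=[StateObservation(0.0, 1), StateObservation(6.0, 2),
                      StateObservation(9.0, 4, exact=True)],
        covariates={"cr": 1.0, "age_c": 0.0, "female": 1.0},
    )


@pytest.fixture
def toy_cohort(toy_subject):
    other = Subject(
        id="s2",
        observations=[StateObservation(0.0, 1), StateObservation(6.0, 1)],
        covariates={"cr": -0.5, "age_c": 6.0, "female": 0.0},
    )
    return Cohort([toy_subject, other], ["cr", "age_c", "female"])


def random_generator(rng, scale=0.3):
    """A random valid 4-state generator with absorbing state 4."""
    Q = rng.uniform(0.01, scale, size=(4, 4))
    Q[3, :] = 0.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q
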
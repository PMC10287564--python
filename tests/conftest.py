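import numpy as np
import pytest

from alcophewas.config import EndpointEffect, SimulationConfig
from alcophewas.exposure import derive_exposure
from alcophewas.simulate import simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(n_participants=20_000, seed=7)


@pytest.fixture(scope="session")
def cohort(default_config):
    """A mid-sized cohort shared across tests (read-only)."""
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def exposure_table(cohort):
    return derive_exposure(cohort.participants)


@pytest.fixture(scope="session")
def null_config():
    """All endpoint effects null; a single moderately common endpoint."""
    return SimulationConfig(
        n_participants=20_000, seed=11,
        endpoint_effects=[EndpointEffect("R10", "R10", "XVIII", False, 0.0, 3e-3)])


def random_tiny_survival(rng, n_max=8):
    """A random tiny one-stratum survival dataset with one binary covariate."""
    n = rng.integers(4, n_max + 1)
    entry = np.round(rng.uniform(0, 2, n), 2)
    exit_ = np.round(entry + rng.uniform(0.5, 5, n), 2)
    event = rng.random(n) < 0.7
    if not event.any():
        event[0] = True
    x = (rng.random(n) < 0.5).astype(float)
    if x.std() == 0:
        x[0] = 1 - x[0]
    return entry, exit_, event, x
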
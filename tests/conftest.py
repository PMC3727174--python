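"""Shared fixtures: fixture models and one long cascade realization reused
by the estimator-agreement and population-geometry suites."""

import numpy as np
import pytest

import gtas

#: base seed for every stochastic test (publication date of the model)
BASE_SEED = 20130717


@pytest.fixture(scope="session")
def models():
    return gtas.fixture_models()


@pytest.fixture(scope="session")
def cascade_sim(models):
    """One long exponential-cascade realization (10^4 time units)."""
    rng = np.random.default_rng(BASE_SEED)
    return gtas.simulate_thinning(models["cascade_exp_n6"], (0.0, 10_000.0), rng)


@pytest.fixture(scope="session")
def cascade_binned(cascade_sim):
    return gtas.bin_counts(cascade_sim, 0.2)
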
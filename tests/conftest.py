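import numpy as np
import pytest

from feroxmr.encounters import load_rannoch_table, reconstruct_histories
from feroxmr.mcmc import McmcSettings, run_mcmc
from feroxmr.model import ModelConfig


@pytest.fixture(scope="session")
def rannoch_table():
    return load_rannoch_table()


@pytest.fixture(scope="session")
def rannoch_matrix(rannoch_table):
    return reconstruct_histories(rannoch_table, 7)


@pytest.fixture(scope="session")
def rannoch_config():
    return ModelConfig(T=16, M=1000)


@pytest.fixture(scope="session")
def short_rannoch_sample(rannoch_matrix, rannoch_config):
    """A short but converging fit of the packaged data, shared across tests."""
    settings = McmcSettings(n_chains=3, n_iterations=6000, rng_seed=42, min_retained=3000)
    return run_mcmc(rannoch_matrix, rannoch_config, settings)
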
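import pytest

from anthrotrend.growth_reference import ReferenceTable
from anthrotrend.hiermix_model import MCMCSettings, fit
from anthrotrend.synthetic_data import SimulationConfig, generate_surveys, generate_truth


@pytest.fixture(scope="session")
def who_table():
    return ReferenceTable.packaged("WHO2006")


@pytest.fixture(scope="session")
def nchs_table():
    return ReferenceTable.packaged("NCHS1977")


@pytest.fixture(scope="session")
def tiny_sim():
    """A small simulated dataset: 2 regions x 2 countries, default conditions."""
    cfg = SimulationConfig(n_regions=2, countries_per_region=2)
    truth = generate_truth(cfg, 42)
    sources = generate_surveys(truth, cfg, 43)
    return cfg, truth, sources


@pytest.fixture(scope="session")
def tiny_fit(tiny_sim):
    """A short MCMC fit of the tiny dataset, shared across tests."""
    cfg, truth, sources = tiny_sim
    settings = MCMCSettings(chains=2, iterations=400, burnin=100, thin=2, seed=7)
    return fit(sources, truth.meta, cfg.model_spec(), settings)
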
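import pytest

from gsempath.effects import load_reported_system
from gsempath.glm_engine import fit_system
from gsempath.model_spec import default_model
from gsempath.synthetic_data import default_scenario, generate_population


@pytest.fixture(scope="session")
def diagram():
    return default_model()


@pytest.fixture(scope="session")
def reported_system():
    """Published path-coefficient set as a SystemFit (diagonal covariance)."""
    return load_reported_system()


@pytest.fixture(scope="session")
def population_20k(diagram):
    """One survey-calibrated synthetic population, n = 20,000."""
    scenario = default_scenario(n=20_000, seed=11)
    return scenario, generate_population(scenario, diagram)


@pytest.fixture(scope="session")
def system_fit_20k(diagram, population_20k):
    _, records = population_20k
    return fit_system(diagram, records)
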
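import numpy as np
import pytest

from exacmsm import parametric as pm
from exacmsm import synth


@pytest.fixture(scope="session")
def default_config():
    return synth.GeneratorConfig(n=2000, seed=7)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One moderately sized simulated cohort shared across tests."""
    return synth.simulate_trajectories(default_config)


@pytest.fixture(scope="session")
def dataset(default_config):
    return synth.simulate_dataset(default_config)


@pytest.fixture(scope="session")
def weibull_fit(dataset):
    return pm.fit(dataset, "weibull")


@pytest.fixture(scope="session")
def exponential_fit(dataset):
    return pm.fit(dataset, "exponential")
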
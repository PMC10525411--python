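import numpy as np
import pytest

from sdmshift import grids, niche, synth


@pytest.fixture(scope="session")
def world():
    """Default synthetic world: 5 bioclim-like layers on a 50x50 grid."""
    return synth.make_climate_stack(seed=101)


@pytest.fixture(scope="session")
def species(world):
    return synth.default_virtual_species(world, n_presence=300, seed=101)


@pytest.fixture(scope="session")
def suitability(world, species):
    return synth.make_true_suitability(world, species)


@pytest.fixture(scope="session")
def presences(suitability, species):
    return synth.sample_presences(suitability, species)


@pytest.fixture(scope="session")
def training_data(world, presences):
    """(presence covariates, background covariates, names) for SDM tests."""
    X, ok = grids.extract_at_points(world, presences)
    _, bg = niche.sample_background(world, n=1000, seed=202)
    return X[ok], bg, world.names


@pytest.fixture
def rng():
    return np.random.default_rng(7)
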
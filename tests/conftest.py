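import numpy as np
import pytest

import gridpop as gp


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def lattice3():
    return gp.build_lattice(3, 3, 2.0)


@pytest.fixture
def small_landscape():
    """A 10x10 synthetic landscape with covariates, rivers, units, mask."""
    return gp.make_landscape(10, 10, seed=42)


@pytest.fixture
def tiny_dataset():
    """A small simulated landscape + survey dataset at the reference ψ."""
    land = gp.make_landscape(8, 8, seed=11)
    psi = gp.default_psi()
    states, data = gp.simulate_dataset(land, psi, years=6, seed=111)
    return land, psi, states, data


def one_cell_model(area=4.0, lam=None):
    """A single-cell landscape for exact-enumeration oracles."""
    land = gp.build_lattice(1, 1, 2.0)
    land.area[:] = area
    return land
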
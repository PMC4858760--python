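import numpy as np
import pytest

import mossgrad as mg


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def grid10():
    """All-land 10x10 lattice spanning 40-52 degrees latitude."""
    return mg.LatticeGrid.regular(10, 10, pixel_size=100.0,
                                  lat_range=(40.0, 52.0))


@pytest.fixture
def grid4():
    return mg.LatticeGrid.regular(4, 4, pixel_size=100.0,
                                  lat_range=(42.0, 50.0))


@pytest.fixture
def env12():
    """Small deterministic landscape shared across tests."""
    return mg.make_landscape(12, 12, seed=5)


def random_species_grid(grid, n_species, rng, p=0.4):
    occ = rng.random((grid.n_land, n_species)) < p
    ids = [f"sp{k:02d}" for k in range(n_species)]
    return mg.SpeciesGrid(grid, ids, occ)
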
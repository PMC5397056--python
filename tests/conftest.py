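import numpy as np
import pytest

from steadypm.fields import CellFields, SynthesisParams, synthesize_archive
from steadypm.grid import GridConfig, RasterPopulation, build_static_grid


def uniform_grid(nx=4, ny=4, cell=1000.0, layer_tops=(50.0,), divisors=(2,),
                 cap=1500.0):
    """Single-resolution grid: nx x ny base cells x len(layer_tops) layers."""
    cfg = GridConfig(domain_bounds=(0.0, 0.0, nx * cell, ny * cell),
                     base_size=cell, divisors=divisors, pop_threshold=1e30,
                     layer_tops=tuple(layer_tops), high_res_cap_height=cap)
    pop = RasterPopulation(np.zeros((ny, nx)), 0.0, 0.0, cell)
    return build_static_grid(pop, cfg)


def calm_fields(grid) -> CellFields:
    """All-zero dynamics; ground resistances set to benign values."""
    cf = CellFields.zeros(grid.n_cells)
    cf.ra = np.full(grid.n_cells, 100.0)
    cf.rb = np.full(grid.n_cells, 50.0)
    cf.rc_gas = np.full(grid.n_cells, 50.0)
    cf.rc_particle = np.full(grid.n_cells, 50.0)
    return cf


@pytest.fixture
def grid_4x4():
    return uniform_grid(4, 4, 1000.0)


@pytest.fixture
def grid_two_cells():
    return uniform_grid(2, 1, 1000.0)


@pytest.fixture
def column_grid():
    """One footprint cell, five vertical layers."""
    return uniform_grid(1, 1, 2000.0, layer_tops=(50.0, 150.0, 350.0, 700.0, 1200.0))


@pytest.fixture
def var_grid():
    """Variable-resolution grid: one refined base cell, three layers.

    The cap height of 100 m puts the two elevated layers on the coarse
    footprint, exercising mixed coarse/fine vertical interfaces.
    """
    cfg = GridConfig(domain_bounds=(0.0, 0.0, 8000.0, 8000.0),
                     base_size=2000.0, divisors=(2,), pop_threshold=100.0,
                     layer_tops=(50.0, 150.0, 400.0), high_res_cap_height=100.0)
    vals = np.zeros((8, 8))
    vals[4, 2] = 1000.0   # populate one 1 km pixel -> split its base cell
    pop = RasterPopulation(vals, 0.0, 0.0, 1000.0)
    return build_static_grid(pop, cfg)


@pytest.fixture
def var_grid_fields(var_grid):
    return synthesize_archive(var_grid, seed=7, params=SynthesisParams(n_hours=240))


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    from steadypm.run import make_demo
    out = tmp_path_factory.mktemp("demo")
    make_demo(1, out)
    return out
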
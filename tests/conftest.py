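import numpy as np
import pytest

from urbansat import GridSpec, RasterLayer, default_truth, simulate_study


def make_fine_grid(n_rows=30, n_cols=30, cell=0.001):
    return GridSpec(
        origin_x=10.0, origin_y=50.0, cell_w=cell, cell_h=cell,
        n_rows=n_rows, n_cols=n_cols,
    )


def make_coarse_grid(fine, factor=10):
    return GridSpec(
        origin_x=fine.origin_x, origin_y=fine.origin_y,
        cell_w=fine.cell_w * factor, cell_h=fine.cell_h * factor,
        n_rows=fine.n_rows // factor, n_cols=fine.n_cols // factor,
        crs=fine.crs,
    )


def random_continuous(grid, rng, nodata_frac=0.0):
    vals = rng.normal(5.0, 2.0, size=grid.shape)
    if nodata_frac:
        vals[rng.random(grid.shape) < nodata_frac] = np.nan
    return RasterLayer(grid, vals, kind="continuous")


def random_categorical(grid, rng, codes=(30, 40, 50, 80, 111), nodata_frac=0.0):
    vals = rng.choice(codes, size=grid.shape)
    if nodata_frac:
        vals = np.where(rng.random(grid.shape) < nodata_frac, -1, vals)
    return RasterLayer(grid, vals, nodata=-1, kind="categorical")


@pytest.fixture(scope="session")
def small_study():
    """One default synthetic world, shared by read-only tests."""
    return simulate_study(n_subjects=300, seed=11)


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=5)
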
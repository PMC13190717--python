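"""Shared fixtures: small grids, smooth fields, and reusable Moran bases."""

import numpy as np
import pytest

from tremornet.simulate import (
    default_analysis_mask,
    make_template_network,
    smooth_noise_field,
)
from tremornet.spatialnull import build_weights, moran_eigenbasis
from tremornet.volumes import BrainMap, VolumeGrid

#: hub layout that fits inside the small test grids
SMALL_HUBS = (
    ((-16.0, -10.0, 14.0), 8.0, +1, 1.0),
    ((16.0, -10.0, 14.0), 8.0, +1, 1.0),
    ((-10.0, -22.0, -14.0), 7.0, +1, 1.0),
    ((10.0, -22.0, -14.0), 7.0, +1, 1.0),
    ((-12.0, 18.0, 8.0), 7.0, -1, 1.0),
    ((12.0, 18.0, 8.0), 7.0, -1, 1.0),
)


@pytest.fixture(scope="session")
def small_grid():
    return VolumeGrid.centered((16, 18, 16), 4.0)


@pytest.fixture(scope="session")
def small_mask(small_grid):
    return default_analysis_mask(small_grid)


@pytest.fixture(scope="session")
def small_template(small_grid, small_mask):
    return make_template_network(small_grid, SMALL_HUBS, mask=small_mask)


@pytest.fixture(scope="session")
def tiny_grid():
    """~500-voxel mask: cheap enough for dense eigendecompositions."""
    return VolumeGrid.centered((10, 10, 10), 6.0)


@pytest.fixture(scope="session")
def tiny_mask(tiny_grid):
    return default_analysis_mask(tiny_grid)


@pytest.fixture(scope="session")
def tiny_basis(tiny_grid, tiny_mask):
    weights = build_weights(tiny_grid, tiny_mask)
    return weights, moran_eigenbasis(weights)


def smooth_field(grid, mask, rng, fwhm=8.0, sd=1.0) -> BrainMap:
    return smooth_noise_field(grid, mask, fwhm, sd, rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
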
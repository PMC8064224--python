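import numpy as np
import pytest

import retnorm as rn
from retnorm import geometry as geom


@pytest.fixture(scope="session")
def wt_db():
    return rn.load_packaged("wt")


@pytest.fixture(scope="session")
def ad_db():
    return rn.load_packaged("ad")


@pytest.fixture
def flat_config():
    """Noise-free, gradient-free full-size volume: every layer constant."""
    return rn.SimConfig(noise_sd_um=0.0, nasal_temporal_slope_um=0.0,
                        disc_distance_slope_um=0.0)


def constant_map(value: float, layer: str = "TRT",
                 orientation: str = "standardized",
                 shape=(geom.GRID_SIZE, geom.GRID_SIZE),
                 **meta) -> rn.ThicknessMap:
    return rn.ThicknessMap(layer=layer,
                           values=np.full(shape, float(value)),
                           validity=np.ones(shape, dtype=bool),
                           orientation=orientation, **meta)


@pytest.fixture
def make_constant_map():
    return constant_map


def grid_from_means(means, layer="INL", subject="eye", counts=None, **meta):
    """BlockGrid built directly from a 3x3 array of block means."""
    means = np.asarray(means, dtype=float)
    valid = ~np.isnan(means)
    if counts is None:
        counts = np.where(valid, geom.BLOCK_PIXELS, 0)
    return rn.BlockGrid(block_means=means, valid_counts=counts,
                        block_valid=valid, layer=layer, subject=subject, **meta)


@pytest.fixture
def make_block_grid():
    return grid_from_means
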
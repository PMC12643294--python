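import numpy as np
import pytest

from defauna.raster import EnvStack, RasterGrid
from defauna.synth import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A quick little world for integration-style unit tests."""
    cfg = WorldConfig(
        nrows=40,
        ncols=40,
        n_env_layers=5,
        n_species=10,
        n_sites=20,
        n_sites_strict=5,
        n_sites_sustainable=3,
        n_occurrences=40,
        site_richness_floor=5,
        seed=7,
    )
    return generate_world(cfg)


@pytest.fixture
def unit_template():
    """10x10 raster, origin (0, 10), unit cells."""
    return RasterGrid(np.zeros((10, 10)), origin_x=0.0, origin_y=10.0, cell_size=1.0)


def make_raster(values, cell_size=1.0, origin=(0.0, None), nodata=-9999.0, crs="local"):
    values = np.asarray(values, dtype=float)
    oy = origin[1] if origin[1] is not None else values.shape[0] * cell_size
    return RasterGrid(
        values, origin_x=origin[0], origin_y=oy, cell_size=cell_size,
        nodata=nodata, crs_label=crs,
    )


def make_env(layers: dict, **kwargs) -> EnvStack:
    return EnvStack({name: make_raster(vals, **kwargs) for name, vals in layers.items()})
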
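import numpy as np
import pytest
from shapely.geometry import box

from rnahsi.grid import Grid, GridSpec
from rnahsi.synthetic import SceneParams, generate_scene
from rnahsi.vectors import Zone, ZoneSet

CRS = "EPSG:32650"


@pytest.fixture
def small_spec():
    """A 10x10 grid of 100 m cells."""
    return GridSpec((10, 10), (0.0, 1000.0), 100.0, CRS)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def ramp_grid(small_spec):
    """Planar surface v = 2 + 0.003 x + 0.001 y (exact under bilinear)."""
    X, Y = small_spec.center_mesh()
    return Grid(2.0 + 0.003 * X + 0.001 * Y, small_spec)


@pytest.fixture
def quad_zones():
    """Four quadrant zones tiling the 10x10/100 m grid."""
    zones = [
        Zone("a", box(0, 500, 500, 1000), 100),
        Zone("b", box(500, 500, 1000, 1000), 200),
        Zone("c", box(0, 0, 500, 500), 300),
        Zone("d", box(500, 0, 1000, 500), 400),
    ]
    return ZoneSet(zones, crs=CRS)


@pytest.fixture(scope="session")
def default_scene():
    """The default synthetic city (200x200 cells, 74 zones)."""
    return generate_scene(SceneParams(seed=7))


def scaled_scene_params(seed: int) -> SceneParams:
    """A quarter-size city used where many scenes are needed."""
    base = SceneParams()
    return SceneParams(
        grid=GridSpec((100, 100), base.grid.origin, 100.0, base.grid.crs),
        n_zones=36,
        roads_per_class=40,
        n_evi_layers=8,
        centre_scale=1500.0,
        density_smoothing_bandwidth=1000.0,
        total_population=500_000.0,
        seed=seed,
    )
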
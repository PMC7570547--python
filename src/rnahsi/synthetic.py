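"""Seeded synthetic-city generator for end-to-end testing.

A scene carries every input the mapping workflow consumes — nighttime
light DN, a stack of vegetation-index layers, a classified road network
and census zones — built so the statistical structure the method relies
on holds by construction:

* road segments cluster around a handful of urban centres, so road
  density is a smooth multi-centre surface;
* the true population density is a power law of the smoothed
  road-length density (density = a * S**b_true), so the zone-level
  RND-density calibration is recoverable;
* nighttime DN is a monotone transform of density, degraded with a
  Gaussian blur (sensor "blooming") and multiplicative noise;
* the vegetation composite is anti-correlated with density, with
  seasonal modulation and jitter across the per-period layers;
* zone census counts are the integrals of the true density surface
  (largest-remainder rounding, so totals match exactly).

All randomness flows from one integer seed through per-layer
sub-streams, so adding a layer never perturbs the others and the same
seed always reproduces the scene bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, box

from .grid import Grid, GridSpec
from .gtiff import write_geotiff
from .kde import line_kde
from .vectors import (
    ROAD_CLASSES,
    RoadFeature,
    RoadNetwork,
    Zone,
    ZoneSet,
    write_census_csv,
    write_roads_geojson,
    write_zones_geojson,
)

__all__ = ["SceneParams", "SyntheticScene", "generate_scene", "scene_to_files"]

#: typical segment length range per class, metres
_CLASS_SEGMENT_LENGTH = {
    "expressway": (3000.0, 6000.0),
    "trunk": (2000.0, 4000.0),
    "secondary_trunk": (1500.0, 3000.0),
    "branch": (1000.0, 2000.0),
    "railway": (3000.0, 6000.0),
    "other": (500.0, 1500.0),
}


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the synthetic city.

    Defaults describe a 20 x 20 km city on the 100 m analysis grid with
    5 urban centres and 74 census zones (the order of a large Chinese
    city's township count), a power-law exponent of 1.2322 linking
    density to road density, moderate nighttime-light blooming (300 m
    blur) and 15% multiplicative radiance noise.
    """

    grid: GridSpec = GridSpec((200, 200), (500000.0, 2500000.0), 100.0, "EPSG:32650")
    n_centres: int = 5
    centre_scale: float = 3000.0  # metres; urban-centre kernel width
    road_classes: tuple[str, ...] = ROAD_CLASSES
    roads_per_class: int = 120
    b_true: float = 1.2322
    ntl_blur_sigma: float = 300.0  # metres
    noise_sd: float = 0.15        # relative, multiplicative
    n_zones: int = 74
    n_evi_layers: int = 23
    total_population: float = 2_000_000.0
    density_smoothing_bandwidth: float = 3000.0  # metres; defines S
    ntl_underground_deficit: float = 0.5  # activity invisible to the sensor
    density_floor_frac: float = 0.001     # background density, fraction of mean S
    evi_saturation: float = 0.15  # density fraction at which vegetation is gone
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_centres < 1 or self.roads_per_class < 1 or self.n_zones < 1:
            raise ValueError("counts must be >= 1")
        if not self.b_true > 0:
            raise ValueError("b_true must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rows, cols = self.grid.shape
        if rows * cols < 4 * self.n_zones or min(rows, cols) < 8:
            raise ValueError(
                f"grid {self.grid.shape} too small for {self.n_zones} zones"
            )


@dataclass
class SyntheticScene:
    params: SceneParams
    true_density: Grid   # persons/km²
    ntl_dn: Grid         # sensor DN
    evi_stack: list[Grid]
    roads: RoadNetwork
    zones: ZoneSet


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(seed)) % (2**31), stream])


def _centre_field(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Mixture of radially decaying kernels around random centres."""
    spec = params.grid
    X, Y = spec.center_mesh()
    xmin, ymin, xmax, ymax = spec.bounds()
    mx, my = 0.1 * (xmax - xmin), 0.1 * (ymax - ymin)
    field = np.full(spec.shape, 0.02)
    for _ in range(params.n_centres):
        cx = rng.uniform(xmin + mx, xmax - mx)
        cy = rng.uniform(ymin + my, ymax - my)
        amp = rng.uniform(0.5, 1.0)
        s = params.centre_scale * rng.uniform(0.7, 1.3)
        field += amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * s * s))
    return field


def _sample_locations(
    intensity: np.ndarray, spec: GridSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n points with cell probability ~ intensity, jittered in-cell."""
    p = intensity.ravel() / intensity.sum()
    cells = rng.choice(p.size, size=n, p=p)
    r, c = np.unravel_index(cells, spec.shape)
    x0, y0 = spec.origin
    cs = spec.cell_size
    xs = x0 + (c + rng.uniform(0, 1, n)) * cs
    ys = y0 - (r + rng.uniform(0, 1, n)) * cs
    return np.column_stack([xs, ys])


def _make_roads(
    params: SceneParams, intensity: np.ndarray, rng: np.random.Generator
) -> RoadNetwork:
    """Lay bent segments per class, midpoints drawn from intensity^(1/b).

    Sampling with intensity^(1/b_true) makes the smoothed road-length
    density track the centre field raised to 1/b, so raising it back by
    b recovers a multi-centre density surface.
    """
    spec = params.grid
    xmin, ymin, xmax, ymax = spec.bounds()
    inset = spec.cell_size
    weight = np.power(intensity, 1.0 / params.b_true)
    feats: list[RoadFeature] = []
    for cls in params.road_classes:
        mids = _sample_locations(weight, spec, params.roads_per_class, rng)
        lo, hi = _CLASS_SEGMENT_LENGTH[cls]
        for mx, my in mids:
            length = rng.uniform(lo, hi)
            theta = rng.uniform(0, 2 * np.pi)
            d = np.array([np.cos(theta), np.sin(theta)])
            perp = np.array([-d[1], d[0]]) * rng.normal(0, 0.05) * length
            pts = np.array(
                [
                    [mx, my] - d * length / 2,
                    [mx, my] + perp,
                    [mx, my] + d * length / 2,
                ]
            )
            pts[:, 0] = np.clip(pts[:, 0], xmin + inset, xmax - inset)
            pts[:, 1] = np.clip(pts[:, 1], ymin + inset, ymax - inset)
            line = LineString(pts)
            if line.length > 0:
                feats.append(RoadFeature(line, cls))
    return RoadNetwork(feats, crs=spec.crs)


def _apportion(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing to ``total``
    (largest-remainder; ties broken by index)."""
    floors = np.floor(values).astype(int)
    short = total - int(floors.sum())
    if short < 0:  # total below the floor sum; trim smallest remainders
        order = np.lexsort((np.arange(len(values)), values - floors))
        out = floors.copy()
        for i in order[: -short]:
            out[i] = max(out[i] - 1, 0)
        return out
    frac = values - floors
    order = np.lexsort((np.arange(len(values)), -frac))
    out = floors.copy()
    out[order[:short]] += 1
    return out


def _make_zones(params: SceneParams, density: np.ndarray) -> ZoneSet:
    """Rectangular partition of the grid into n_zones census polygons."""
    spec = params.grid
    rows, cols = spec.shape
    n = params.n_zones
    nrows = max(1, int(round(np.sqrt(n))))
    base, extra = divmod(n, nrows)
    per_row = [base + (1 if i < extra else 0) for i in range(nrows)]
    row_edges = np.linspace(0, rows, nrows + 1).round().astype(int)
    x0, y0 = spec.origin
    cs = spec.cell_size
    cell_km2 = spec.cell_area_m2 / 1e6
    geoms, integrals = [], []
    for i, ncols_i in enumerate(per_row):
        r0, r1 = row_edges[i], row_edges[i + 1]
        col_edges = np.linspace(0, cols, ncols_i + 1).round().astype(int)
        for j in range(ncols_i):
            c0, c1 = col_edges[j], col_edges[j + 1]
            geoms.append(
                box(x0 + c0 * cs, y0 - r1 * cs, x0 + c1 * cs, y0 - r0 * cs)
            )
            integrals.append(density[r0:r1, c0:c1].sum() * cell_km2)
    integrals = np.asarray(integrals)
    total = int(round(integrals.sum()))
    pops = _apportion(integrals, total)
    width = len(str(len(geoms)))
    zones = [
        Zone(f"z{i:0{width}d}", g, int(p))
        for i, (g, p) in enumerate(zip(geoms, pops))
    ]
    return ZoneSet(zones, crs=spec.crs)


def generate_scene(params: SceneParams | None = None, **overrides) -> SyntheticScene:
    """Build a complete synthetic scene from seeded sub-streams."""
    if params is None:
        params = SceneParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    spec = params.grid
    centres = _centre_field(params, _rng(params.seed, 1))
    roads = _make_roads(params, centres, _rng(params.seed, 2))

    # true density: power law of the smoothed road-length density
    s_grid = line_kde(
        roads, None, params.density_smoothing_bandwidth, spec, method="fft"
    )
    S = s_grid.values + params.density_floor_frac * s_grid.values.mean()
    shape_field = np.power(S, params.b_true)
    cell_km2 = spec.cell_area_m2 / 1e6
    scale = params.total_population / (shape_field.sum() * cell_km2)
    density = scale * shape_field  # persons/km²
    true_density = Grid(density, spec, units="persons/km2")

    zones = _make_zones(params, density)

    # nighttime light: radiance tracks the *visible* activity — in
    # road-dense cores a fraction of activity (underground commerce and
    # transit) emits no light, the deficit the road adjustment corrects
    rng_ntl = _rng(params.seed, 3)
    l_max = 1e-3  # W/(m² sr µm) at the densest cell
    visible = density * (
        1.0 - params.ntl_underground_deficit * S / S.max()
    )
    radiance = l_max * visible / visible.max()
    dn = np.power(radiance * 1e10, 2.0 / 3.0)
    if params.ntl_blur_sigma > 0:
        dn = gaussian_filter(dn, sigma=params.ntl_blur_sigma / spec.cell_size)
    if params.noise_sd > 0:
        dn = dn * rng_ntl.lognormal(0.0, params.noise_sd, size=dn.shape)
    ntl_dn = Grid(dn, spec, units="DN")

    # vegetation index stack: anti-correlated with density, saturating —
    # vegetation is gone in any built-up cell, so EVI separates urban
    # from rural but cannot grade density within the urban core
    rng_evi = _rng(params.seed, 4)
    dens_norm = density / density.max()
    built = np.minimum(dens_norm / params.evi_saturation, 1.0)
    evi_base = 0.15 + 0.6 * (1.0 - built)
    evi_stack = []
    for t in range(params.n_evi_layers):
        season = 0.6 + 0.4 * np.sin(np.pi * t / max(params.n_evi_layers - 1, 1))
        layer = evi_base * season
        if params.noise_sd > 0:
            layer = layer + rng_evi.normal(0.0, 0.2 * params.noise_sd, layer.shape)
        evi_stack.append(Grid(np.clip(layer, -0.2, 1.0), spec, units="EVI"))

    return SyntheticScene(
        params=params,
        true_density=true_density,
        ntl_dn=ntl_dn,
        evi_stack=evi_stack,
        roads=roads,
        zones=zones,
    )


def scene_to_files(scene: SyntheticScene, directory: str | Path) -> dict[str, Path]:
    """Write the scene in the exact formats the pipeline consumes.

    GeoTIFFs for the rasters (float32), GeoJSON for roads and zones, a
    zone_id/population CSV for the census.  Returns the path map.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    write_geotiff(scene.ntl_dn, d / "ntl_dn.tif")
    paths["ntl"] = d / "ntl_dn.tif"
    write_geotiff(scene.true_density, d / "true_density.tif")
    paths["true_density"] = d / "true_density.tif"
    evi_paths = []
    for i, layer in enumerate(scene.evi_stack, start=1):
        p = d / f"evi_{i:02d}.tif"
        write_geotiff(layer, p)
        evi_paths.append(p)
    paths["evi"] = evi_paths
    write_roads_geojson(scene.roads, d / "roads.geojson")
    paths["roads"] = d / "roads.geojson"
    write_zones_geojson(scene.zones, d / "zones.geojson")
    paths["zones"] = d / "zones.geojson"
    write_census_csv(scene.zones, d / "census.csv")
    paths["census"] = d / "census.csv"
    return paths
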
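"""Classified road networks, census zones, and their GeoJSON/CSV I/O.

Roads are polylines in a projected CRS tagged with one of six functional
classes (the OSM-derived taxonomy used for the density layers); zones are
census polygons with integer population counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPolygon, Polygon, mapping, shape

from .grid import GridSpec, check_projected

__all__ = [
    "ROAD_CLASSES",
    "DEFAULT_OSM_CLASS_MAP",
    "RoadFeature",
    "RoadNetwork",
    "Zone",
    "ZoneSet",
    "read_roads_geojson",
    "write_roads_geojson",
    "read_zones_geojson",
    "write_zones_geojson",
    "read_census_csv",
    "write_census_csv",
]

ROAD_CLASSES = (
    "expressway",
    "trunk",
    "secondary_trunk",
    "branch",
    "railway",
    "other",
)

# Mapping from OSM highway/railway tag values to the six-class taxonomy.
DEFAULT_OSM_CLASS_MAP: Mapping[str, str] = {
    "motorway": "expressway",
    "motorway_link": "expressway",
    "trunk": "trunk",
    "trunk_link": "trunk",
    "primary": "trunk",
    "primary_link": "trunk",
    "secondary": "secondary_trunk",
    "secondary_link": "secondary_trunk",
    "tertiary": "branch",
    "tertiary_link": "branch",
    "unclassified": "branch",
    "rail": "railway",
    "subway": "railway",
    "light_rail": "railway",
    "residential": "other",
    "living_street": "other",
    "pedestrian": "other",
    "footway": "other",
    "cycleway": "other",
    "path": "other",
    "service": "other",
}


@dataclass(frozen=True)
class RoadFeature:
    geometry: LineString
    road_class: str

    def __post_init__(self) -> None:
        if self.road_class not in ROAD_CLASSES:
            raise ValueError(
                f"unknown road class {self.road_class!r}; expected one of {ROAD_CLASSES}"
            )
        coords = np.asarray(self.geometry.coords)
        if len(coords) < 2:
            raise ValueError("road polyline needs at least 2 vertices")
        if not np.isfinite(coords).all():
            raise ValueError("road polyline has non-finite coordinates")
        if not self.geometry.length > 0:
            raise ValueError("road polyline has zero length")

    @property
    def length(self) -> float:
        return self.geometry.length


@dataclass
class RoadNetwork:
    """Classified polylines in a projected CRS."""

    features: list[RoadFeature]
    crs: str = "EPSG:32650"

    def __post_init__(self) -> None:
        check_projected(self.crs)

    def by_class(self, road_class: str) -> "RoadNetwork":
        return RoadNetwork(
            [f for f in self.features if f.road_class == road_class], crs=self.crs
        )

    def classes_present(self) -> list[str]:
        present = {f.road_class for f in self.features}
        return [c for c in ROAD_CLASSES if c in present]

    def total_length(self, road_class: str | None = None) -> float:
        return sum(
            f.length
            for f in self.features
            if road_class is None or f.road_class == road_class
        )

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class Zone:
    zone_id: str
    geometry: Polygon | MultiPolygon
    population: int

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"zone {self.zone_id}: population must be >= 0")
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise ValueError(f"zone {self.zone_id}: invalid or empty polygon")
        if not self.geometry.area > 0:
            raise ValueError(f"zone {self.zone_id}: zero area")

    @property
    def area_km2(self) -> float:
        return self.geometry.area / 1e6


@dataclass
class ZoneSet:
    """Census polygons with population counts, ordered by zone_id."""

    zones: list[Zone]
    crs: str = "EPSG:32650"

    def __post_init__(self) -> None:
        check_projected(self.crs)
        ids = [z.zone_id for z in self.zones]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate zone ids: {dup}")
        self.zones = sorted(self.zones, key=lambda z: z.zone_id)

    @property
    def zone_ids(self) -> list[str]:
        return [z.zone_id for z in self.zones]

    @property
    def populations(self) -> np.ndarray:
        return np.array([z.population for z in self.zones], dtype=float)

    @property
    def areas_km2(self) -> np.ndarray:
        return np.array([z.area_km2 for z in self.zones])

    def total_population(self) -> int:
        return int(sum(z.population for z in self.zones))

    def __len__(self) -> int:
        return len(self.zones)

    def label_grid(self, spec: GridSpec) -> np.ndarray:
        """Assign every cell centre to a zone index, -1 outside all zones.

        Containment is by cell centre; a centre lying exactly on a shared
        boundary goes to the first zone in id order (deterministic
        tie-break).
        """
        if spec.crs != self.crs:
            raise ValueError(f"CRS mismatch: grid {spec.crs!r} vs zones {self.crs!r}")
        X, Y = spec.center_mesh()
        labels = np.full(spec.shape, -1, dtype=np.int32)
        xs = X.ravel()
        ys = Y.ravel()
        flat = labels.ravel()
        for idx, z in enumerate(self.zones):
            todo = flat < 0
            if not todo.any():
                break
            hit = shapely.intersects_xy(z.geometry, xs[todo], ys[todo])
            sel = np.flatnonzero(todo)[hit]
            flat[sel] = idx
        return flat.reshape(spec.shape)

    def mask_grid(self, spec: GridSpec) -> np.ndarray:
        """Boolean study-area mask: cell centres inside any zone."""
        return self.label_grid(spec) >= 0


# ---------------------------------------------------------------- I/O

def _read_geojson(path: str | Path) -> dict:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return gj


def _gj_crs(gj: dict, default: str) -> str:
    crs = gj.get("crs")
    if isinstance(crs, dict):
        name = crs.get("properties", {}).get("name", "")
        # accept "EPSG:32650" and OGC urn forms
        if "EPSG" in name.upper():
            code = name.rsplit(":", 1)[-1].rstrip("'\"")
            return f"EPSG:{code}"
    return default


def read_roads_geojson(
    path: str | Path,
    class_attr: str = "road_class",
    class_map: Mapping[str, str] | None = None,
    crs: str = "EPSG:32650",
) -> RoadNetwork:
    """Load classified polylines from GeoJSON.

    ``class_attr`` names the property holding the class; raw OSM
    highway/railway tag values are translated through ``class_map``
    (default :data:`DEFAULT_OSM_CLASS_MAP`) when they are not already one
    of the six canonical classes.  Dual carriageways are assumed merged
    to centre lines upstream.
    """
    gj = _read_geojson(path)
    crs = _gj_crs(gj, crs)
    cmap = dict(DEFAULT_OSM_CLASS_MAP if class_map is None else class_map)
    feats: list[RoadFeature] = []
    for i, f in enumerate(gj.get("features", [])):
        geom = shape(f["geometry"])
        raw = f.get("properties", {}).get(class_attr)
        if raw is None:
            raise ValueError(f"{path}: feature {i} missing {class_attr!r} property")
        cls = raw if raw in ROAD_CLASSES else cmap.get(raw)
        if cls is None:
            raise ValueError(
                f"{path}: feature {i} class {raw!r} not in taxonomy or class map"
            )
        lines = geom.geoms if geom.geom_type == "MultiLineString" else [geom]
        for line in lines:
            feats.append(RoadFeature(LineString(line), cls))
    return RoadNetwork(feats, crs=crs)


def write_roads_geojson(network: RoadNetwork, path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": network.crs}},
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": {"road_class": f.road_class},
            }
            for f in network.features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_zones_geojson(
    path: str | Path,
    id_attr: str = "zone_id",
    population_attr: str = "population",
    census: Mapping[str, int] | None = None,
    crs: str = "EPSG:32650",
) -> ZoneSet:
    """Load census polygons; counts come from a property or a census table."""
    gj = _read_geojson(path)
    crs = _gj_crs(gj, crs)
    zones: list[Zone] = []
    for i, f in enumerate(gj.get("features", [])):
        props = f.get("properties", {})
        zid = props.get(id_attr)
        if zid is None:
            raise ValueError(f"{path}: feature {i} missing {id_attr!r} property")
        zid = str(zid)
        if census is not None:
            if zid not in census:
                raise ValueError(f"{path}: zone {zid!r} missing from census table")
            pop = int(census[zid])
        else:
            if population_attr not in props:
                raise ValueError(
                    f"{path}: zone {zid!r} has no {population_attr!r} and no census table given"
                )
            pop = int(props[population_attr])
        zones.append(Zone(zid, shape(f["geometry"]), pop))
    return ZoneSet(zones, crs=crs)


def write_zones_geojson(zones: ZoneSet, path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": zones.crs}},
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(z.geometry),
                "properties": {"zone_id": z.zone_id, "population": z.population},
            }
            for z in zones.zones
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_census_csv(path: str | Path) -> dict[str, int]:
    """Read a zone_id,population table."""
    df = pd.read_csv(path, dtype={"zone_id": str})
    for col in ("zone_id", "population"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return dict(zip(df["zone_id"], df["population"].astype(int)))


def write_census_csv(zones: ZoneSet, path: str | Path) -> None:
    pd.DataFrame(
        {"zone_id": zones.zone_ids, "population": [z.population for z in zones.zones]}
    ).to_csv(path, index=False)
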
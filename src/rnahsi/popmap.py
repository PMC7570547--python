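"""Dasymetric population mapping: calibration against census and
disaggregation of zone counts onto the analysis grid.

Zone-level sums of the weighting index are regressed on census counts;
pixel predictions are then rescaled so the study-area (or per-zone)
total matches the census exactly.  The ratio of actual to estimated
total population — the correction factor — removes the model's overall
bias before the rescale in regression mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .grid import Grid
from .vectors import ZoneSet

__all__ = [
    "zonal_sum",
    "fit_linear_calibration",
    "correction_factor",
    "disaggregate",
    "to_density",
    "LinearFit",
]

log = logging.getLogger(__name__)

DisaggregationMode = Literal["regression", "proportional", "proportional_by_zone"]


def zonal_sum(
    grid: Grid, zones: ZoneSet, labels: np.ndarray | None = None
) -> pd.Series:
    """Sum of non-nodata grid values per zone (cell-centre containment).

    Cells outside all zones are excluded.  A zone capturing no cell
    centre gets sum 0 with a warning.
    """
    if grid.crs != zones.crs:
        raise ValueError(f"CRS mismatch: grid {grid.crs!r} vs zones {zones.crs!r}")
    if labels is None:
        labels = zones.label_grid(grid.spec)
    flat = np.nan_to_num(grid.values, nan=0.0).ravel()
    lab = labels.ravel()
    sums = np.bincount(lab[lab >= 0], weights=flat[lab >= 0], minlength=len(zones))
    counts = np.bincount(lab[lab >= 0], minlength=len(zones))
    for zid, n in zip(zones.zone_ids, counts):
        if n == 0:
            log.warning("zone %s contains no cell centres; sum set to 0", zid)
    return pd.Series(sums, index=zones.zone_ids, name="zonal_sum")


@dataclass(frozen=True)
class LinearFit:
    """OLS line population = slope * index_sum + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0,1]: {self.r_squared}")


def fit_linear_calibration(
    zonal_index_sums: np.ndarray, populations: np.ndarray
) -> LinearFit:
    """OLS of census population on per-zone index sums."""
    x = np.asarray(zonal_index_sums, dtype=float)
    y = np.asarray(populations, dtype=float)
    if x.shape != y.shape:
        raise ValueError("sums and populations must have equal length")
    if len(x) < 3:
        raise ValueError(f"need >= 3 zones, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all zonal index sums are equal")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - float((resid**2).sum()) / sst
    return LinearFit(float(slope), float(intercept), min(max(r2, 0.0), 1.0))


def correction_factor(estimated_total: float, actual_total: float) -> float:
    """Ratio actual/estimated applied to remove overall model bias."""
    if not estimated_total > 0:
        raise ValueError(f"estimated total must be positive, got {estimated_total}")
    return actual_total / estimated_total


def disaggregate(
    rnahsi: Grid,
    zones: ZoneSet,
    fit: LinearFit | None = None,
    mode: DisaggregationMode = "regression",
    labels: np.ndarray | None = None,
) -> Grid:
    """Distribute census population onto the grid weighted by the index.

    Modes
    -----
    regression
        Pixel estimate = slope * index + intercept / n_cells (the
        intercept is spread uniformly over in-area cells), negatives
        clipped to 0, then the whole surface is scaled by the correction
        factor so the study-area total equals the census total.
    proportional
        Pixel = census_total * index / sum(index) over the study area.
    proportional_by_zone
        Same, per zone with that zone's count — exact per-zone
        conservation.  A zone whose index is all zero gets a uniform
        spread with a warning.

    Pixels outside all zones are 0.  All modes conserve the study-area
    total exactly.
    """
    if labels is None:
        labels = zones.label_grid(rnahsi.spec)
    inside = labels >= 0
    idx = np.nan_to_num(rnahsi.values, nan=0.0)
    if (idx[inside] < 0).any():
        raise ValueError("index grid has negative values inside the study area")
    total_census = float(zones.total_population())
    pop = np.zeros(rnahsi.shape)

    if mode == "regression":
        if fit is None:
            raise ValueError("regression mode requires a LinearFit")
        n_cells = int(inside.sum())
        raw = fit.slope * idx + fit.intercept / n_cells
        raw = np.where(inside, np.maximum(raw, 0.0), 0.0)
        est_total = float(raw.sum())
        factor = correction_factor(est_total, total_census)
        log.info("correction factor (actual/estimated): %.4f", factor)
        pop = raw * factor
    elif mode == "proportional":
        w = np.where(inside, idx, 0.0)
        s = float(w.sum())
        if s <= 0:
            raise ValueError("index is zero everywhere inside the study area")
        pop = total_census * w / s
    elif mode == "proportional_by_zone":
        flat_idx = idx.ravel()
        flat_lab = labels.ravel()
        flat_pop = pop.ravel()
        for zi, zone in enumerate(zones.zones):
            cells = np.flatnonzero(flat_lab == zi)
            if cells.size == 0:
                continue
            w = flat_idx[cells]
            s = float(w.sum())
            if s <= 0:
                if zone.population > 0:
                    log.warning(
                        "zone %s: all-zero index with positive census; "
                        "spreading uniformly", zone.zone_id,
                    )
                flat_pop[cells] = zone.population / cells.size
            else:
                flat_pop[cells] = zone.population * w / s
        pop = flat_pop.reshape(rnahsi.shape)
    else:
        raise ValueError(
            f"unknown mode {mode!r}; valid modes: regression, proportional, "
            "proportional_by_zone"
        )
    return rnahsi.with_values(pop, units="persons/cell")


def to_density(pop: Grid, per_km2: float = 0.01) -> Grid:
    """Persons per cell -> persons per ``per_km2`` km² (default 0.01 km²,
    the identity for a 100 m grid)."""
    cell_km2 = pop.spec.cell_area_m2 / 1e6
    return pop.with_values(
        pop.values / (cell_km2 / per_km2), units=f"persons/{per_km2} km2"
    )
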
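"""Settlement-index algebra: HSI, the RND power-law calibration, RNAHSI.

The human settlement index combines normalized nighttime radiance
(LJ_nor) and the annual maximum vegetation composite (EVI_max):

    HSI = (1 - EVI_max + LJ_nor)
          / ((1 - LJ_nor) + EVI_max + LJ_nor * EVI_max)

high where lights are bright and vegetation sparse.  The road-network
adjusted index multiplies in the composite road density raised to a
census-calibrated exponent:

    RNAHSI = HSI * RND ** b

where b is the slope of a log-log regression of zone-mean population
density on zone-mean RND (the observed relation is a power law).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import Grid

__all__ = ["compute_hsi", "fit_power_law", "compute_rnahsi", "PowerLawFit"]

log = logging.getLogger(__name__)

#: guard added to the HSI denominator, which vanishes at
#: (LJ_nor, EVI_max) = (1, 0)
HSI_EPS = 1e-9


def compute_hsi(evi_max: Grid, lj_nor: Grid, eps: float = HSI_EPS) -> Grid:
    """Human settlement index from EVI_max and normalized radiance.

    Both inputs must be aligned and in [0, 1] (EVI is clamped to [0, 1]
    upstream — negative EVI marks water/bare surfaces).  The denominator
    vanishes only at the corner (LJ_nor=1, EVI_max=0); values below
    ``eps`` are floored to it there, so that corner yields a large
    finite value rather than a division error while every regular cell
    is computed exactly.
    """
    if not evi_max.aligned_with(lj_nor):
        raise ValueError("evi_max and lj_nor grids are not aligned")
    for name, g in (("evi_max", evi_max), ("lj_nor", lj_nor)):
        v = g.values[g.valid_mask()]
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError(
                f"{name} outside [0, 1]: range [{v.min()}, {v.max()}]"
            )
    e = evi_max.values
    l = lj_nor.values
    num = 1.0 - e + l
    den = (1.0 - l) + e + l * e
    den = np.where(den < eps, eps, den)
    return evi_max.with_values(num / den, units="")


@dataclass(frozen=True)
class PowerLawFit:
    """Zone-level power law density = a * RND**b, fitted in log space."""

    coefficient: float  # a, density units per RND**b
    exponent: float     # b, dimensionless
    r_squared: float
    n_zones: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError(f"coefficient must be positive, got {self.coefficient}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0,1]: {self.r_squared}")
        if self.n_zones < 3:
            raise ValueError(f"need >= 3 zones, got {self.n_zones}")

    def predict(self, rnd: np.ndarray) -> np.ndarray:
        return self.coefficient * np.power(rnd, self.exponent)


def fit_power_law(mean_rnd: np.ndarray, mean_density: np.ndarray) -> PowerLawFit:
    """OLS of ln(density) on ln(RND) across zones.

    ``mean_rnd`` is the zone mean of the composite RND grid and
    ``mean_density`` the zone population density (persons/km²).  Zones
    with non-positive RND or density are excluded (log undefined), with
    the dropped count logged and recorded.  The exponent is
    unit-invariant; the coefficient is tied to the RND units used here
    and is recomputed rather than reused across unit systems.
    """
    x = np.asarray(mean_rnd, dtype=float)
    y = np.asarray(mean_density, dtype=float)
    if x.shape != y.shape:
        raise ValueError("mean_rnd and mean_density must have equal length")
    ok = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    dropped = int((~ok).sum())
    if dropped:
        log.info("power fit: dropped %d zone(s) with non-positive RND or density", dropped)
    if ok.sum() < 3:
        raise ValueError(
            f"need >= 3 zones with positive RND and density, have {int(ok.sum())}"
        )
    lx, ly = np.log(x[ok]), np.log(y[ok])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    sst = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - float((resid**2).sum()) / sst
    return PowerLawFit(
        coefficient=float(np.exp(intercept)),
        exponent=float(slope),
        r_squared=min(max(r2, 0.0), 1.0),
        n_zones=int(ok.sum()),
        n_dropped=dropped,
    )


def compute_rnahsi(hsi: Grid, rnd: Grid, exponent: float) -> Grid:
    """Road-network adjusted settlement index: HSI * RND**b per cell.

    Requires b > 0 (the method presumes density increases with road
    density); RND = 0 therefore maps to RNAHSI = 0.
    """
    if not exponent > 0:
        raise ValueError(f"exponent must be positive, got {exponent}")
    if not hsi.aligned_with(rnd):
        raise ValueError("hsi and rnd grids are not aligned")
    r = rnd.values
    neg = np.nan_to_num(r, nan=0.0) < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(f"negative RND {r[i, j]} at cell (row={i}, col={j})")
    return hsi.with_values(hsi.values * np.power(r, exponent), units="")
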
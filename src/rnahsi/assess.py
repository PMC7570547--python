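"""Zone-level accuracy metrics for estimated population surfaces.

Estimates PE_i are compared with census counts P_i per zone:

    MRE   = 100/n * sum |PE_i - P_i| / P_i
    %RMSE = 100 * sqrt(sum (PE_i - P_i)^2 / n) / mean(P)

plus R² between estimates and census.  Two R² variants are computed:
the squared Pearson correlation (primary — the scatter-fit reading) and
1 - SSE/SST of identity-line residuals (secondary).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import Grid
from .popmap import zonal_sum
from .vectors import ZoneSet

__all__ = ["mre", "pct_rmse", "r_squared", "residual_report", "AccuracyReport"]


def _check_pair(pe, p) -> tuple[np.ndarray, np.ndarray]:
    pe = np.asarray(pe, dtype=float)
    p = np.asarray(p, dtype=float)
    if pe.shape != p.shape or pe.ndim != 1 or pe.size < 1:
        raise ValueError("estimates and actuals must be equal-length 1-D, n >= 1")
    return pe, p


def mre(estimates, actuals, zone_ids=None) -> float:
    """Mean relative error in percent: mean of |PE_i - P_i| / P_i."""
    pe, p = _check_pair(estimates, actuals)
    zero = p <= 0
    if zero.any():
        i = int(np.argmax(zero))
        zid = zone_ids[i] if zone_ids is not None else i
        raise ValueError(f"zone {zid!r} has population {p[i]}; MRE needs P_i > 0")
    return float(100.0 * np.mean(np.abs(pe - p) / p))


def pct_rmse(estimates, actuals) -> float:
    """RMSE of zonal estimates as a percentage of the mean zone count."""
    pe, p = _check_pair(estimates, actuals)
    m = p.mean()
    if not m > 0:
        raise ValueError("mean population must be positive")
    return float(100.0 * np.sqrt(np.mean((pe - p) ** 2)) / m)


def r_squared(estimates, actuals, kind: str = "pearson") -> float:
    """Coefficient of determination between estimates and census.

    ``kind="pearson"`` (default) is the squared Pearson correlation —
    what a scatter-plot trend-line fit reports; ``kind="identity"`` is
    1 - SSE/SST with residuals taken about the identity line PE = P.
    Returns NaN when a variable has zero variance (undefined).
    """
    pe, p = _check_pair(estimates, actuals)
    if pe.size < 3:
        raise ValueError("need >= 3 zones for R²")
    if np.std(pe) == 0 or np.std(p) == 0:
        return float("nan")
    if kind == "pearson":
        return float(np.corrcoef(pe, p)[0, 1] ** 2)
    if kind == "identity":
        sst = float(((p - p.mean()) ** 2).sum())
        return 1.0 - float(((pe - p) ** 2).sum()) / sst
    raise ValueError(f"unknown kind {kind!r}")


@dataclass
class AccuracyReport:
    """Per-zone residuals plus MRE, %RMSE and R² summaries."""

    residuals: pd.DataFrame  # zone_id, estimated, census, residual
    mre: float
    pct_rmse: float
    r_squared: float            # squared Pearson correlation (primary)
    r_squared_identity: float   # 1 - SSE/SST about the identity line

    def __post_init__(self) -> None:
        if self.mre < 0 or self.pct_rmse < 0:
            raise ValueError("MRE and %RMSE must be non-negative")
        ids = self.residuals["zone_id"]
        if ids.duplicated().any():
            raise ValueError("residual table must cover each zone exactly once")

    def summary(self) -> dict:
        return {
            "n_zones": int(len(self.residuals)),
            "mre_pct": self.mre,
            "pct_rmse": self.pct_rmse,
            "r_squared": self.r_squared,
            "r_squared_identity": self.r_squared_identity,
        }

    def to_csv(self, path) -> None:
        self.residuals.to_csv(path, index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2, sort_keys=True))


def residual_report(
    pop_grid: Grid, zones: ZoneSet, labels: np.ndarray | None = None
) -> AccuracyReport:
    """Aggregate an estimated-population grid to zones and score it.

    Residual = estimated - census per zone; summary metrics as above.
    Accepts any population raster aligned in CRS with the zones, so an
    external gridded product can be scored the same way as the package's
    own maps.
    """
    est = zonal_sum(pop_grid, zones, labels=labels)
    p = zones.populations
    pe = est.to_numpy()
    table = pd.DataFrame(
        {
            "zone_id": zones.zone_ids,
            "estimated": pe,
            "census": p,
            "residual": pe - p,
        }
    )
    few = len(p) < 3  # R² undefined for under three zones
    return AccuracyReport(
        residuals=table,
        mre=mre(pe, p, zone_ids=zones.zone_ids),
        pct_rmse=pct_rmse(pe, p),
        r_squared=float("nan") if few else r_squared(pe, p, kind="pearson"),
        r_squared_identity=float("nan") if few else r_squared(pe, p, kind="identity"),
    )
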
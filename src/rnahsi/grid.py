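"""Single-band raster data model and preprocessing operators.

The :class:`Grid` is the carrier for every raster layer in the workflow:
raw nighttime-light digital numbers (DN), calibrated radiance, vegetation
index composites, settlement indices and the final population surfaces.
Grids live on a projected CRS in metres, with square north-up cells; the
cell value is the sample at the cell centre and the grid origin is the
upper-left corner of the upper-left cell.

Nodata is carried as NaN internally; an optional sentinel (``nodata``)
is honoured on construction and on file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Grid",
    "GridSpec",
    "dn_to_radiance",
    "minmax_normalize",
    "max_composite",
    "resample_bilinear",
    "align_stack",
]

# EPSG ranges that are geographic (lat/lon degrees) — the method requires
# metric coordinates, so these are rejected at construction.
_GEOGRAPHIC_EPSG = frozenset({4326, 4269, 4267, 4258, 4490, 4610, 4171})


def _epsg_code(crs: str) -> int | None:
    if isinstance(crs, str) and crs.upper().startswith("EPSG:"):
        try:
            return int(crs.split(":", 1)[1])
        except ValueError:
            return None
    return None


def check_projected(crs: str) -> None:
    """Reject geographic CRS: all distances here are CRS metres."""
    code = _epsg_code(crs)
    if code is not None and code in _GEOGRAPHIC_EPSG:
        raise ValueError(
            f"CRS {crs!r} is geographic (degrees); reproject to a projected "
            "CRS in metres (e.g. the UTM zone of the study area) first."
        )


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an analysis grid: shape, placement and CRS.

    Parameters
    ----------
    shape : (rows, cols)
    origin : (x0, y0) — CRS coordinates of the upper-left corner of the
        upper-left cell.
    cell_size : square cell edge in CRS metres.
    crs : projected CRS identifier, e.g. ``"EPSG:32650"``.
    """

    shape: tuple[int, int]
    origin: tuple[float, float]
    cell_size: float
    crs: str = "EPSG:32650"

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 1 or cols < 1:
            raise ValueError(f"grid shape must be >= 1x1, got {self.shape}")
        if not (self.cell_size > 0):
            raise ValueError(f"cell size must be positive, got {self.cell_size}")
        check_projected(self.crs)

    @property
    def rows(self) -> int:
        return self.shape[0]

    @property
    def cols(self) -> int:
        return self.shape[1]

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) 1-D arrays of column-centre x and row-centre y."""
        x0, y0 = self.origin
        c = self.cell_size
        xs = x0 + (np.arange(self.cols) + 0.5) * c
        ys = y0 - (np.arange(self.rows) + 0.5) * c
        return xs, ys

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) 2-D arrays of cell-centre coordinates."""
        xs, ys = self.cell_centers()
        return np.meshgrid(xs, ys)

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) outer edges of the grid."""
        x0, y0 = self.origin
        return (x0, y0 - self.rows * self.cell_size, x0 + self.cols * self.cell_size, y0)


@dataclass
class Grid:
    """A single-band raster: values + :class:`GridSpec` geometry.

    ``values`` are stored float64 with NaN marking nodata.  A sentinel
    passed as ``nodata`` is converted to NaN on construction and restored
    when writing to file.
    """

    values: np.ndarray
    spec: GridSpec
    nodata: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got ndim={v.ndim}")
        if v.shape != self.spec.shape:
            raise ValueError(
                f"values shape {v.shape} does not match spec shape {self.spec.shape}"
            )
        if self.nodata is not None and not np.isnan(self.nodata):
            v = np.where(v == self.nodata, np.nan, v)
        if np.isinf(v).any():
            raise ValueError("grid contains non-finite (inf) values")
        self.values = v

    # -- convenience -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.spec.shape

    @property
    def crs(self) -> str:
        return self.spec.crs

    @property
    def cell_size(self) -> float:
        return self.spec.cell_size

    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def aligned_with(self, other: "Grid | GridSpec") -> bool:
        spec = other.spec if isinstance(other, Grid) else other
        return self.spec == spec

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Grid":
        return Grid(values, self.spec, nodata=None,
                    units=self.units if units is None else units)


def _require_aligned(grids: Sequence[Grid]) -> None:
    ref = grids[0].spec
    for i, g in enumerate(grids[1:], start=1):
        if g.spec.shape != ref.shape:
            raise ValueError(f"grid {i} shape {g.spec.shape} != {ref.shape}")
        if g.spec.crs != ref.crs:
            raise ValueError(f"grid {i} crs {g.spec.crs!r} != {ref.crs!r}")
        if (g.spec.origin != ref.origin) or (g.spec.cell_size != ref.cell_size):
            raise ValueError(
                f"grid {i} transform (origin={g.spec.origin}, cell={g.spec.cell_size})"
                f" != (origin={ref.origin}, cell={ref.cell_size})"
            )


def dn_to_radiance(dn_grid: Grid, exponent: float = 1.5) -> Grid:
    """Convert raw nighttime-light digital numbers to radiance.

    Applies the LJ 1-01 absolute radiometric calibration
    ``L = 1e-10 * DN**exponent`` per cell, yielding radiant brightness in
    W/(m² sr µm).  The 3/2 exponent is the published calibration
    convention for this sensor.

    Raises
    ------
    ValueError
        If any non-nodata DN is negative (first offending cell named).
    """
    v = dn_grid.values
    neg = np.nan_to_num(v, nan=0.0) < 0
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise ValueError(
            f"negative DN {v[r, c]} at cell (row={r}, col={c}); DN must be >= 0"
        )
    out = 1e-10 * np.power(v, exponent)
    return dn_grid.with_values(out, units="W/(m2 sr um)")


def minmax_normalize(grid: Grid, mask: np.ndarray | None = None) -> Grid:
    """Min–max rescale to [0, 1] over in-mask, non-nodata cells.

    ``mask`` is a boolean array (True = inside the study area) or a
    ZoneSet whose polygons define it — typically the census zones; cells
    outside keep their rescaled value but the min/max are taken in-mask
    only, matching a normalization computed over the study-area extent.
    """
    if mask is not None and hasattr(mask, "mask_grid"):
        mask = mask.mask_grid(grid.spec)
    valid = grid.valid_mask()
    sel = valid if mask is None else (valid & np.asarray(mask, dtype=bool))
    if sel.sum() < 2:
        raise ValueError("need at least two non-nodata cells to normalize")
    vmin = float(grid.values[sel].min())
    vmax = float(grid.values[sel].max())
    if vmax == vmin:
        raise ValueError(
            f"degenerate normalization: grid is constant ({vmin}) over the mask"
        )
    out = (grid.values - vmin) / (vmax - vmin)
    return grid.with_values(out, units="")


def max_composite(grids: Sequence[Grid]) -> Grid:
    """Per-cell maximum over aligned grids, ignoring nodata.

    A cell is nodata in the output only if it is nodata in every input.
    Used to build the annual maximum vegetation-index composite from the
    per-period EVI layers, suppressing cloud-contaminated lows.
    """
    grids = list(grids)
    if not grids:
        raise ValueError("max_composite needs at least one grid")
    _require_aligned(grids)
    stack = np.stack([g.values for g in grids])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        out = np.nanmax(stack, axis=0)
    return grids[0].with_values(out)


def resample_bilinear(grid: Grid, target: GridSpec) -> Grid:
    """Bilinear resampling of a grid onto a target grid geometry.

    Values are interpolated at target cell centres from the four
    surrounding source cell centres.  Target cells whose 2x2 support
    touches a nodata source cell, or that fall outside the convex hull of
    source centres, become nodata.  Exact on affine surfaces.
    """
    if grid.crs != target.crs:
        raise ValueError(f"CRS mismatch: {grid.crs!r} vs {target.crs!r}")
    ratio = target.cell_size / grid.cell_size
    if not (0.1 <= ratio <= 10.0):
        raise ValueError(
            f"target cell size {target.cell_size} outside [1/10, 10]x source"
        )
    if grid.spec == target:
        return Grid(grid.values.copy(), target, units=grid.units)

    sx0, sy0 = grid.spec.origin
    c = grid.cell_size
    txs, tys = target.cell_centers()
    # fractional source indices of target centres (0 == first centre)
    fc = (txs - sx0) / c - 0.5
    fr = (sy0 - tys) / c - 0.5

    rows, cols = grid.shape
    inside_r = (fr >= 0) & (fr <= rows - 1)
    inside_c = (fc >= 0) & (fc <= cols - 1)
    # clamp the lower index so a target centre on the last source centre
    # interpolates within the final cell pair; weights recomputed after
    r0c = np.clip(np.floor(fr).astype(int), 0, max(rows - 2, 0))
    c0c = np.clip(np.floor(fc).astype(int), 0, max(cols - 2, 0))
    wr = fr - r0c
    wc = fc - c0c
    r1 = np.clip(r0c + 1, 0, rows - 1)
    c1 = np.clip(c0c + 1, 0, cols - 1)

    V = grid.values
    R0, C0 = np.meshgrid(r0c, c0c, indexing="ij")
    R1, C1 = np.meshgrid(r1, c1, indexing="ij")
    WR, WC = np.meshgrid(wr, wc, indexing="ij")
    out = (
        V[R0, C0] * (1 - WR) * (1 - WC)
        + V[R0, C1] * (1 - WR) * WC
        + V[R1, C0] * WR * (1 - WC)
        + V[R1, C1] * WR * WC
    )
    IN = np.outer(inside_r, inside_c)
    out = np.where(IN, out, np.nan)
    return Grid(out, target, units=grid.units)


def align_stack(grids: Iterable[Grid], target: GridSpec) -> list[Grid]:
    """Resample every grid onto the common analysis grid (bilinear)."""
    return [resample_bilinear(g, target) for g in grids]
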
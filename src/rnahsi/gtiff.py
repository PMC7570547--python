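"""Single-band GeoTIFF read/write.

Built directly on ``tifffile`` with the standard GeoTIFF tags:
ModelPixelScale (33550), ModelTiepoint (33922), GeoKeyDirectory (34735)
carrying the projected EPSG code, and the GDAL nodata tag (42113).
North-up square-cell rasters only, matching the :class:`~rnahsi.grid.Grid`
model; CRS must be projected in metres.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .grid import Grid, GridSpec, check_projected, _epsg_code

__all__ = ["read_geotiff", "write_geotiff"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_GT_MODEL_TYPE = 1024       # 1 = projected
_GT_RASTER_TYPE = 1025      # 1 = PixelIsArea
_PROJECTED_CS_TYPE = 3072   # EPSG code of the projected CRS


def write_geotiff(grid: Grid, path: str | Path, dtype: str = "float32") -> None:
    """Write a grid as a single-band GeoTIFF (float32 by default)."""
    code = _epsg_code(grid.crs)
    if code is None:
        raise ValueError(f"cannot encode CRS {grid.crs!r}; need an EPSG:<code> string")
    x0, y0 = grid.spec.origin
    c = grid.spec.cell_size
    values = grid.values.astype(dtype)
    nodata = grid.nodata if grid.nodata is not None else float("nan")
    if not np.isnan(nodata):
        values = np.where(np.isnan(values), np.array(nodata, dtype=dtype), values)
    geokeys = [
        1, 1, 0, 3,
        _GT_MODEL_TYPE, 0, 1, 1,
        _GT_RASTER_TYPE, 0, 1, 1,
        _PROJECTED_CS_TYPE, 0, 1, code,
    ]
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (c, c, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(geokeys), tuple(geokeys)),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]
    tifffile.imwrite(Path(path), values, extratags=extratags)


def read_geotiff(path: str | Path) -> Grid:
    """Read a single-band GeoTIFF into a :class:`Grid`.

    Rejects geographic CRS with guidance to reproject first.
    """
    with tifffile.TiffFile(Path(path)) as tf:
        page = tf.pages[0]
        values = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {values.shape}")
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
    if not np.isclose(sx, sy):
        raise ValueError(f"{path}: non-square cells ({sx} x {sy}) are not supported")
    tie = tags[_TAG_TIEPOINT]
    # tiepoint maps raster (i, j, k) -> model (x, y, z)
    x0 = tie[3] - tie[0] * sx
    y0 = tie[4] + tie[1] * sy
    crs = "EPSG:32650"
    if _TAG_GEO_KEYS in tags:
        keys = tags[_TAG_GEO_KEYS]
        for k in range(4, len(keys), 4):
            if keys[k] == _PROJECTED_CS_TYPE:
                crs = f"EPSG:{keys[k + 3]}"
            elif keys[k] == _GT_MODEL_TYPE and keys[k + 3] == 2:
                raise ValueError(
                    f"{path}: raster is in a geographic CRS; reproject to a "
                    "projected CRS in metres (e.g. UTM) before use"
                )
    check_projected(crs)
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA]).strip().strip("\x00"))
        except ValueError:
            nodata = None
    spec = GridSpec(values.shape, (float(x0), float(y0)), float(sx), crs=crs)
    return Grid(np.asarray(values, dtype=float), spec, nodata=nodata)
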
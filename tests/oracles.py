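"""Independent brute-force oracles used across the test suite.

Deliberately naive implementations — fine quadrature, explicit loops,
closed forms — kept free of any code path they are used to check.
"""

from __future__ import annotations

import numpy as np


def line_kde_quadrature(
    segments: list[np.ndarray],
    bandwidth: float,
    cell_size: float,
    origin: tuple[float, float],
    shape: tuple[int, int],
    step_frac: float = 1e-4,
) -> np.ndarray:
    """Quartic-kernel line density by midpoint quadrature along segments.

    Each polyline is integrated with a quadrature step of
    ``bandwidth * step_frac``; contributions are summed cell by cell
    from exact distances.  O(cells x quadrature points), chunked.
    """
    h = bandwidth
    rows, cols = shape
    x0, y0 = origin
    cx = x0 + (np.arange(cols) + 0.5) * cell_size
    cy = y0 - (np.arange(rows) + 0.5) * cell_size
    X = np.repeat(cx[None, :], rows, axis=0).ravel()
    Y = np.repeat(cy[:, None], cols, axis=1).ravel()
    density = np.zeros(rows * cols)
    coef = 3.0 / (np.pi * h * h)
    step = h * step_frac
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        for a, b in zip(seg[:-1], seg[1:]):
            L = float(np.hypot(*(b - a)))
            if L == 0:
                continue
            # only cells within h of the segment's bounding box can see it
            near = (
                (X >= min(a[0], b[0]) - h)
                & (X <= max(a[0], b[0]) + h)
                & (Y >= min(a[1], b[1]) - h)
                & (Y <= max(a[1], b[1]) + h)
            )
            idx = np.flatnonzero(near)
            n = max(1, int(np.ceil(L / step)))
            t = (np.arange(n) + 0.5) / n
            px = a[0] + t * (b[0] - a[0])
            py = a[1] + t * (b[1] - a[1])
            w = L / n
            Xn, Yn = X[idx], Y[idx]
            for lo in range(0, n, 8000):
                qx = px[lo : lo + 8000]
                qy = py[lo : lo + 8000]
                u2 = ((Xn[:, None] - qx[None, :]) ** 2 + (Yn[:, None] - qy[None, :]) ** 2) / (h * h)
                k = np.where(u2 < 1.0, (1.0 - u2) ** 2, 0.0)
                density[idx] += coef * w * k.sum(axis=1)
    return density.reshape(rows, cols)


def pearson_r(x, y) -> float:
    """Textbook Pearson correlation from raw sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x**2).sum() - sx**2) * np.sqrt(n * (y**2).sum() - sy**2)
    return float(num / den)


def ols_normal_equations(x, y) -> tuple[float, float]:
    """(slope, intercept) from the closed-form normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x**2).sum() - x.sum() ** 2)
    intercept = (y.sum() - slope * x.sum()) / n
    return float(slope), float(intercept)


def pca_weights_eig(X: np.ndarray) -> np.ndarray:
    """Variance-weighted |loading| class weights via a separate
    eigensolver route (covariance of standardized columns, scipy)."""
    import scipy.linalg

    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    C = np.cov(Z, rowvar=False, ddof=1)
    vals, vecs = scipy.linalg.eig(C)
    vals = vals.real
    vecs = vecs.real
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals >= 1.0 - 1e-12
    if not keep.any():
        keep[0] = True
    ve = vals[keep] / X.shape[1]
    load = vecs[:, keep] * np.sqrt(vals[keep])[None, :]
    raw = (np.abs(load) * ve[None, :]).sum(axis=1)
    return raw / raw.sum()


def zonal_sums_point_in_polygon(values, spec, zones) -> np.ndarray:
    """Per-zone sums via an exhaustive per-cell containment loop
    (matplotlib path test, first-zone-wins on boundaries)."""
    from matplotlib.path import Path as MplPath

    rows, cols = spec.shape
    x0, y0 = spec.origin
    c = spec.cell_size
    paths = []
    for z in zones.zones:
        geoms = getattr(z.geometry, "geoms", [z.geometry])
        paths.append([MplPath(np.asarray(g.exterior.coords)) for g in geoms])
    sums = np.zeros(len(zones.zones))
    for i in range(rows):
        for j in range(cols):
            pt = (x0 + (j + 0.5) * c, y0 - (i + 0.5) * c)
            for zi, plist in enumerate(paths):
                if any(p.contains_point(pt, radius=1e-9) for p in plist):
                    v = values[i, j]
                    if not np.isnan(v):
                        sums[zi] += v
                    break
    return sums
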
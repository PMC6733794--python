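"""Stineman (1980) rational interpolation.

The interpolant passes through every data point with a slope at each
point equal to the tangent of the circle through the point and its two
neighbours.  Between points it deviates from the secant line by at most
``min(|d1|, |d2|)`` where ``d1``/``d2`` are the deviations of the two
endpoint tangent lines from the secant, which is what suppresses the
overshoots that cubic splines produce on sharp level changes.
"""
from __future__ import annotations

import numpy as np


def _circle_tangent_slope(p1, p2, p3, at) -> float:
    """Slope of the circle through three points, at one of them.

    Falls back to the secant slope when the points are (nearly)
    collinear or the tangent is (nearly) vertical.
    """
    (x1, y1), (x2, y2), (x3, y3) = p1, p2, p3
    a11, a12 = 2.0 * (x2 - x1), 2.0 * (y2 - y1)
    a21, a22 = 2.0 * (x3 - x2), 2.0 * (y3 - y2)
    det = a11 * a22 - a12 * a21
    scale = max(abs(a11), abs(a12), abs(a21), abs(a22), 1e-300)
    secant = (y3 - y1) / (x3 - x1)
    if abs(det) <= 1e-12 * scale * scale:
        return secant
    b1 = x2**2 - x1**2 + y2**2 - y1**2
    b2 = x3**2 - x2**2 + y3**2 - y2**2
    cx = (b1 * a22 - a12 * b2) / det
    cy = (a11 * b2 - b1 * a21) / det
    x0, y0 = at
    if abs(y0 - cy) <= 1e-12 * (abs(x0 - cx) + abs(y0 - cy) + 1e-300):
        return secant
    return -(x0 - cx) / (y0 - cy)


def stineman_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-point slopes for Stineman interpolation.

    Interior points use the circle through the point and its two
    neighbours; endpoints use the circle through the first/last three
    points, evaluated at the endpoint.  Two points give the secant
    slope at both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    npts = x.size
    if npts < 2:
        raise ValueError("need at least two points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    dx = np.diff(x)
    dy = np.diff(y)
    yp = np.empty(npts)
    if npts == 2:
        yp[:] = dy[0] / dx[0]
        return yp
    # interior: algebraic form of the circle tangent
    sm2 = dx[:-1] ** 2 + dy[:-1] ** 2
    sp2 = dx[1:] ** 2 + dy[1:] ** 2
    denom = dx[:-1] * sp2 + dx[1:] * sm2
    with np.errstate(divide="ignore", invalid="ignore"):
        interior = (dy[:-1] * sp2 + dy[1:] * sm2) / denom
    # degenerate geometry -> average secant
    bad = ~np.isfinite(interior)
    if np.any(bad):
        interior[bad] = ((dy[:-1] + dy[1:]) / (dx[:-1] + dx[1:]))[bad]
    yp[1:-1] = interior
    pts = list(zip(x, y))
    yp[0] = _circle_tangent_slope(pts[0], pts[1], pts[2], pts[0])
    yp[-1] = _circle_tangent_slope(pts[-3], pts[-2], pts[-1], pts[-1])
    return yp


def stineman_interpolate(
    x: np.ndarray,
    y: np.ndarray,
    xq: np.ndarray,
    slopes: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate the Stineman interpolant of ``(x, y)`` at ``xq``.

    Queries outside ``[x[0], x[-1]]`` are clamped to the boundary
    values (nearest-observed extension; no extrapolation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xq = np.atleast_1d(np.asarray(xq, dtype=float))
    if x.size == 1:
        return np.full(xq.shape, y[0])
    yp = stineman_slopes(x, y) if slopes is None else np.asarray(slopes, float)

    xc = np.clip(xq, x[0], x[-1])
    idx = np.clip(np.searchsorted(x, xc, side="right") - 1, 0, x.size - 2)
    x1, x2 = x[idx], x[idx + 1]
    y1, y2 = y[idx], y[idx + 1]
    s = (y2 - y1) / (x2 - x1)
    y0 = y1 + s * (xc - x1)
    d1 = (yp[idx] - s) * (xc - x1)
    d2 = (yp[idx + 1] - s) * (xc - x2)
    prod = d1 * d2
    out = y0.copy()
    pos = prod > 0
    neg = prod < 0
    out[pos] = y0[pos] + prod[pos] / (d1[pos] + d2[pos])
    out[neg] = y0[neg] + prod[neg] * (2.0 * xc[neg] - x1[neg] - x2[neg]) / (
        (d1[neg] - d2[neg]) * (x2[neg] - x1[neg])
    )
    return out
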
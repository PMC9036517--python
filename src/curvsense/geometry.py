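"""Exact circle/annulus - rectangle intersection areas.

The RDF normalization divides per-annulus counts by the annulus area clipped
to the simulation box.  Without clipping, a uniformly distributed species
would fall below RDF = 1 wherever an annulus extends past the box edges, so
the clipping is done with the exact (closed-form) circle-rectangle
intersection area rather than by sampling.
"""
from __future__ import annotations

import numpy as np


def _sqrt_integral(x: np.ndarray | float, r: float) -> np.ndarray | float:
    """Antiderivative of sqrt(r^2 - X^2) on [-r, r]."""
    x = np.clip(x, -r, r)
    return 0.5 * (x * np.sqrt(np.maximum(r * r - x * x, 0.0))
                  + r * r * np.arcsin(np.clip(x / r, -1.0, 1.0)))


def circle_rect_area(center: tuple[float, float], radius: float,
                     rect: tuple[float, float, float, float]) -> float:
    """Area of a disc intersected with an axis-aligned rectangle.

    Parameters
    ----------
    center : (cx, cy) disc centre
    radius : disc radius (>= 0)
    rect : (xmin, xmax, ymin, ymax)

    The integrand ``min(y2, s(X)) - max(y1, -s(X))`` with
    ``s(X) = sqrt(r^2 - X^2)`` is piecewise analytic; the integral is taken
    in closed form on each sub-interval between branch crossings.
    """
    r = float(radius)
    if r <= 0.0:
        return 0.0
    cx, cy = center
    x1, x2 = rect[0] - cx, rect[1] - cx
    y1, y2 = rect[2] - cy, rect[3] - cy
    lo, hi = max(x1, -r), min(x2, r)
    if lo >= hi or y1 >= y2 or y1 >= r or y2 <= -r:
        return 0.0

    # Breakpoints where s(X) crosses |y1| or |y2| (both signs of X).
    pts = {lo, hi}
    for y in (y1, y2):
        if abs(y) < r:
            xc = np.sqrt(r * r - y * y)
            for p in (-xc, xc):
                if lo < p < hi:
                    pts.add(p)
    pts = sorted(pts)

    area = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        mid = 0.5 * (a + b)
        s_mid = np.sqrt(max(r * r - mid * mid, 0.0))
        upper_is_flat = s_mid > y2
        lower_is_flat = -s_mid < y1
        width = 0.0
        # Upper bound contribution.
        if upper_is_flat:
            upper = y2 * (b - a)
        else:
            upper = _sqrt_integral(b, r) - _sqrt_integral(a, r)
        # Lower bound contribution.
        if lower_is_flat:
            lower = y1 * (b - a)
        else:
            lower = -(_sqrt_integral(b, r) - _sqrt_integral(a, r))
        seg = upper - lower
        if min(y2, s_mid) > max(y1, -s_mid):
            width = seg
        area += max(width, 0.0)
    return float(area)


def annulus_rect_areas(center: tuple[float, float], edges: np.ndarray,
                       rect: tuple[float, float, float, float]) -> np.ndarray:
    """Clipped areas of the annuli defined by radial bin ``edges``."""
    edges = np.asarray(edges, dtype=float)
    discs = np.array([circle_rect_area(center, r, rect) for r in edges])
    return np.diff(discs)


def box_rect(box: tuple[float, ...]) -> tuple[float, float, float, float]:
    """The xy-plane rectangle (0, Lx, 0, Ly) of a simulation box."""
    return (0.0, float(box[0]), 0.0, float(box[1]))
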
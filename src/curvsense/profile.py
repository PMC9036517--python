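"""Radially averaged membrane height profile, sigmoid fit and curvature.

The membrane height over the central pore is modelled with a generalized
logistic ("sigmoid-like") function of radial distance r,

    h(r) = a + (c - a) / (1 + exp(b (r - x0)))**d

with fitting parameters (a, b, c, d, x0): ``c`` is the inner (pore-side)
plateau, ``a`` the outer plateau, ``x0`` the transition radius, ``b`` an
inverse transition width and ``d`` a shape exponent (d = 0 collapses to the
flat membrane h = c; d = 1 is the symmetric logistic).

From the fit, the planar curvature of the height profile is

    K(r) = f''(r) / (1 + f'(r)^2)^(3/2),      RoC(r) = 1 / |K(r)|,

with f' and f'' generated symbolically from the model expression (sympy)
rather than transcribed by hand, so the derivative code cannot drift from
the function it differentiates.

Sign convention, used everywhere in the package: K > 0 where the membrane
curves toward the solvent-exposed side, i.e. the band that is *concave* as
seen by a protein above the membrane; K < 0 is convex.  With the default
geometry the concave band sits near r = 6 nm and the convex band near
r = 11 nm.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import curve_fit

from .errors import EmptySelectionError, FitFailureError, InvalidConfigError
from .frames import BeadFrame

#: RoC value reported where the profile is flat (K == 0).
ROC_INFINITE = np.inf


@lru_cache(maxsize=1)
def _symbolic_model():
    """Sigmoid expression and its first two derivatives, lambdified once."""
    import sympy as sp

    r, a, b, c, d, x0 = sp.symbols("r a b c d x0", real=True)
    expr = a + (c - a) / (1 + sp.exp(b * (r - x0))) ** d
    d1 = sp.diff(expr, r)
    d2 = sp.diff(expr, r, 2)
    args = (r, a, b, c, d, x0)
    return (sp.lambdify(args, expr, "numpy"),
            sp.lambdify(args, d1, "numpy"),
            sp.lambdify(args, d2, "numpy"))


def _check_params(params) -> tuple[float, ...]:
    params = tuple(float(p) for p in params)
    if len(params) != 5:
        raise InvalidConfigError("profile params must be (a, b, c, d, x0)")
    if not np.all(np.isfinite(params)):
        raise InvalidConfigError("profile params must be finite")
    return params


def surface_height(r, params):
    """Membrane height h(r) of the sigmoid model, in nm.

    ``params`` is the 5-tuple (a, b, c, d, x0).  Vectorized over ``r``.
    """
    a, b, c, d, x0 = _check_params(params)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidConfigError("radial distance must be non-negative")
    f, _, _ = _symbolic_model()
    with np.errstate(over="ignore"):
        out = f(r, a, b, c, d, x0)
    return out if out.shape else float(out)


def surface_derivatives(r, params):
    """Analytic (f', f'') of the sigmoid model at ``r``."""
    a, b, c, d, x0 = _check_params(params)
    r = np.asarray(r, dtype=float)
    _, f1, f2 = _symbolic_model()
    with np.errstate(over="ignore"):
        d1 = np.broadcast_to(np.asarray(f1(r, a, b, c, d, x0), dtype=float), r.shape).copy()
        d2 = np.broadcast_to(np.asarray(f2(r, a, b, c, d, x0), dtype=float), r.shape).copy()
    # exp overflow far outside the transition means the true derivative
    # underflows to zero there
    d1[~np.isfinite(d1)] = 0.0
    d2[~np.isfinite(d2)] = 0.0
    return d1, d2


@dataclass
class SigmoidFit:
    """Fitted sigmoid parameters plus diagnostics."""

    a: float
    b: float
    c: float
    d: float
    x0: float
    covariance: np.ndarray
    rss: float
    n_points: int
    converged: bool = True

    @property
    def params(self) -> tuple[float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.x0)

    def __call__(self, r):
        return surface_height(r, self.params)

    def derivatives(self, r):
        return surface_derivatives(r, self.params)


@dataclass
class HeightProfile:
    """Per-annulus mean height of top-leaflet PC headgroups."""

    r: np.ndarray           # annulus mid-radii, nm
    height: np.ndarray      # mean z, nm (NaN in empty annuli)
    counts: np.ndarray      # beads per annulus

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0


def radial_height_profile(frames, center, bin_width: float = 0.5,
                          r_max: float | None = None) -> HeightProfile:
    """Radially averaged vertical position of top-leaflet PC headgroups.

    Beads from all frames are pooled into annuli of width ``bin_width``
    around ``center``; empty annuli are flagged (NaN height), never
    interpolated.
    """
    if bin_width <= 0:
        raise InvalidConfigError("bin_width must be positive")
    frames = list(frames)
    xc, yc = center
    rs, zs = [], []
    for fr in frames:
        sel = (fr.species == "PC_head") & (fr.leaflet == "top")
        pos = fr.positions[sel]
        if len(pos):
            rs.append(np.hypot(pos[:, 0] - xc, pos[:, 1] - yc))
            zs.append(pos[:, 2])
    if not rs:
        raise EmptySelectionError("no top-leaflet PC_head beads in any frame")
    r = np.concatenate(rs)
    z = np.concatenate(zs)
    if r_max is None:
        r_max = float(np.ceil(r.max() / bin_width) * bin_width)
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    idx = np.digitize(r, edges) - 1
    nbins = len(edges) - 1
    keep = (idx >= 0) & (idx < nbins)
    counts = np.bincount(idx[keep], minlength=nbins)
    sums = np.bincount(idx[keep], weights=z[keep], minlength=nbins)
    with np.errstate(invalid="ignore"):
        height = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mid = 0.5 * (edges[:-1] + edges[1:])
    return HeightProfile(r=mid, height=height, counts=counts)


def _initial_guess(r: np.ndarray, h: np.ndarray) -> tuple[float, ...]:
    """Deterministic starting point: plateaus -> a, c; the mid-gap crossing
    radius -> x0; the 25-75% transition width -> b; d starts symmetric (1).

    The profile is lightly smoothed first so shot noise in sparse outer
    annuli cannot hijack the transition estimate.
    """
    win = max(3, len(h) // 10) | 1
    kernel = np.ones(win) / win
    hs = np.convolve(np.pad(h, win // 2, mode="edge"), kernel, mode="valid")
    k = max(1, len(r) // 5)
    c0 = float(np.mean(hs[:k]))          # inner plateau
    a0 = float(np.mean(hs[-k:]))         # outer plateau
    gap = a0 - c0
    if abs(gap) < 1e-12:
        return (a0, 1.0, c0, 1.0, float(np.mean(r)))
    mid = c0 + 0.5 * gap
    x00 = float(r[np.argmin(np.abs(hs - mid))])
    # 25-75% crossing width; for the symmetric logistic it equals 2 ln(3)/b
    frac = np.clip((hs - c0) / gap, 0.0, 1.0)
    lo = r[np.argmin(np.abs(frac - 0.25))]
    hi = r[np.argmin(np.abs(frac - 0.75))]
    width = abs(float(hi) - float(lo))
    b0 = 2.0 * np.log(3.0) / width if width > 1e-9 else 1.0
    b0 = float(np.clip(b0, 1e-3, 50.0))
    return (a0, b0, c0, 1.0, x00)


def _model(r, a, b, c, d, x0):
    f, _, _ = _symbolic_model()
    with np.errstate(over="ignore"):
        return f(r, a, b, c, d, x0)


def fit_sigmoid(profile: HeightProfile, initial_guess=None,
                max_iter: int = 20000) -> SigmoidFit:
    """Nonlinear least-squares fit of the sigmoid height model.

    The contract is on the fitted *curve*, not on parameter uniqueness
    (the model is over-parametrized in its flat limits).  The returned fit
    never has larger residual sum of squares than the initial guess.
    """
    ok = profile.nonempty & np.isfinite(profile.height)
    r, h = profile.r[ok], profile.height[ok]
    if len(r) < 5:
        raise FitFailureError(
            f"need >= 5 non-empty profile points, got {len(r)}",
            {"n_points": int(len(r))},
        )
    if np.ptp(h) < 1e-9:
        # Degenerate flat profile: the flat limit is exact, the optimizer
        # has nothing to do (and its Jacobian would be singular).
        mean = float(np.mean(h))
        return SigmoidFit(a=mean, b=1.0, c=mean, d=1.0, x0=float(np.mean(r)),
                          covariance=np.full((5, 5), np.nan),
                          rss=float(np.sum((h - mean) ** 2)),
                          n_points=len(r), converged=True)

    heuristic = _initial_guess(r, h)
    if initial_guess is not None:
        starts = [tuple(initial_guess)]
    else:
        # multi-start: the heuristic, plus a mild generic sigmoid across the
        # r-range, protects against the heuristic landing in a bad basin
        starts = [heuristic,
                  (heuristic[0], 0.5, heuristic[2], 1.0, float(np.median(r)))]
    rss0 = float(np.sum((_model(r, *starts[0]) - h) ** 2))
    bounds = ([-np.inf, -50.0, -np.inf, 0.0, -np.inf],
              [np.inf, 50.0, np.inf, 20.0, np.inf])
    best = None
    last_exc = None
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            popt, pcov = curve_fit(_model, r, h, p0=p0, bounds=bounds,
                                   maxfev=max_iter)
        except RuntimeError as exc:
            last_exc = exc
            continue
        rss = float(np.sum((_model(r, *popt) - h) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitFailureError(
            f"sigmoid fit did not converge: {last_exc}",
            {"initial_guess": tuple(starts[0]), "n_points": int(len(r))},
        ) from last_exc
    popt, pcov, rss = best
    if rss > rss0:            # optimizer wandered; keep the better point
        popt, pcov, rss = np.asarray(starts[0], dtype=float), np.full((5, 5), np.nan), rss0
    return SigmoidFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                      d=float(popt[3]), x0=float(popt[4]),
                      covariance=np.asarray(pcov), rss=rss,
                      n_points=len(r), converged=True)


@dataclass
class CurvatureProfile:
    """Height, derivatives, curvature and region labels on a radial grid."""

    r_grid: np.ndarray
    height: np.ndarray
    f_prime: np.ndarray
    f_double_prime: np.ndarray
    K: np.ndarray               # nm^-1, K > 0 = concave (toward solvent)
    RoC: np.ndarray             # nm, unsigned; inf where K == 0
    region: np.ndarray          # {"concave", "convex", "flat"}
    flat_threshold: float

    def region_at(self, r: float) -> str:
        """Region label of the grid point nearest to ``r``."""
        return str(self.region[int(np.argmin(np.abs(self.r_grid - r)))])

    def to_table(self):
        import pandas as pd

        return pd.DataFrame({
            "r": self.r_grid, "height": self.height, "f_prime": self.f_prime,
            "f_double_prime": self.f_double_prime, "K": self.K,
            "RoC": self.RoC, "region": self.region,
        })


def curvature_and_roc(fit: SigmoidFit | tuple, r_grid,
                      flat_threshold: float = 0.01) -> CurvatureProfile:
    """Curvature K = f''/(1 + f'^2)^(3/2) and RoC = 1/|K| from the fit.

    Derivatives come from the analytic expressions, not finite differences.
    """
    params = fit.params if isinstance(fit, SigmoidFit) else _check_params(fit)
    r_grid = np.asarray(r_grid, dtype=float)
    h = surface_height(r_grid, params)
    d1, d2 = surface_derivatives(r_grid, params)
    K = d2 / (1.0 + d1 ** 2) ** 1.5
    with np.errstate(divide="ignore"):
        roc = np.where(K != 0.0, 1.0 / np.abs(K), ROC_INFINITE)
    region = classify_k(K, flat_threshold)
    return CurvatureProfile(r_grid=r_grid, height=np.broadcast_to(h, r_grid.shape).copy(),
                            f_prime=d1, f_double_prime=d2, K=K, RoC=roc,
                            region=region, flat_threshold=flat_threshold)


def classify_k(K: np.ndarray, flat_threshold: float) -> np.ndarray:
    """Per-point region labels from the curvature sign convention."""
    region = np.full(K.shape, "flat", dtype=object)
    region[K > flat_threshold] = "concave"
    region[K < -flat_threshold] = "convex"
    return region


@dataclass
class RegionBands:
    """Contiguous concave/convex/flat bands of a curvature profile."""

    bands: list[tuple[str, float, float]]   # (label, r_start, r_end)
    most_concave_r: float | None
    most_convex_r: float | None


def classify_regions(profile: CurvatureProfile,
                     flat_threshold: float | None = None) -> RegionBands:
    """Contiguous region bands plus the most-concave/most-convex radii."""
    if flat_threshold is not None and flat_threshold != profile.flat_threshold:
        region = classify_k(profile.K, flat_threshold)
    else:
        region = profile.region
    r = profile.r_grid
    bands: list[tuple[str, float, float]] = []
    start = 0
    for i in range(1, len(region) + 1):
        if i == len(region) or region[i] != region[start]:
            bands.append((str(region[start]), float(r[start]), float(r[i - 1])))
            start = i
    kmax, kmin = np.argmax(profile.K), np.argmin(profile.K)
    most_concave = float(r[kmax]) if profile.K[kmax] > 0 else None
    most_convex = float(r[kmin]) if profile.K[kmin] < 0 else None
    return RegionBands(bands=bands, most_concave_r=most_concave,
                       most_convex_r=most_convex)
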
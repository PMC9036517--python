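"""Radial localization statistics: heatmaps, histograms, RDFs and KDEs.

All statistics are computed from xy positions transformed to radial
distance from the central pore,

    r = sqrt((x - x_c)^2 + (y - y_c)^2),

with no periodic wrapping (the pore is centred and the display range stays
inside the box).  Histograms use 100 equally spaced bins between 0 and
25 nm and are normalized so the bin sum is exactly 1; heatmaps bin the
absolute distances |x - x_c|, |y - y_c| on a 50 x 50 grid over [0, 16] x
[0, 20] nm and are normalized the same way.

The RDF normalization divides each bin's count by its annular area (clipped
exactly to the box) and by the species' global area density, so a uniformly
distributed species reads RDF = 1 ("bulk") in every bin.  Values beyond the
display limit (half the shortest in-plane box vector, 16 nm) are computed
but flagged.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .errors import (EmptyHistogramError, InvalidConfigError,
                     InvalidInputError)
from .frames import BeadFrame, ProteinTrace
from .geometry import annulus_rect_areas

#: Default display truncation: half the shortest in-plane box vector.
R_MAX_DISPLAY = 16.0


def radial_distance(com, center):
    """Radial distance of xy point(s) from the pore centre (no wrapping)."""
    com = np.asarray(com, dtype=float)
    center = np.asarray(center, dtype=float)
    if not (np.all(np.isfinite(com)) and np.all(np.isfinite(center))):
        raise InvalidInputError("non-finite coordinates")
    d = com[..., :2] - center
    out = np.hypot(d[..., 0], d[..., 1])
    return float(out) if out.ndim == 0 else out


def _pool_xy(traces) -> np.ndarray:
    if isinstance(traces, ProteinTrace):
        traces = [traces]
    xs = [t.xy for t in traces if len(t)]
    if not xs:
        raise EmptyHistogramError("no frames in any trace")
    return np.concatenate(xs)


@dataclass
class HeatMap2D:
    """50 x 50 frequency grid of absolute distances from the pore centre."""

    grid: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    n_total: int
    n_out_of_range: int

    def __post_init__(self):
        if self.grid.shape != (len(self.x_edges) - 1, len(self.y_edges) - 1):
            raise InvalidInputError("heatmap grid/edges mismatch")


def com_heatmap(traces, center, n_grid: int = 50,
                x_limits=(0.0, 16.0), y_limits=(0.0, 20.0)) -> HeatMap2D:
    """Frequency heatmap of (|x - x_c|, |y - y_c|), normalized to sum 1.

    Out-of-range points are counted and reported on the result, never
    silently dropped.
    """
    xy = _pool_xy(traces)
    ax = np.abs(xy[:, 0] - center[0])
    ay = np.abs(xy[:, 1] - center[1])
    counts, xe, ye = np.histogram2d(
        ax, ay, bins=n_grid, range=[list(x_limits), list(y_limits)])
    total = counts.sum()
    if total == 0:
        raise EmptyHistogramError("all points fall outside the heatmap limits")
    return HeatMap2D(grid=counts / total, x_edges=xe, y_edges=ye,
                     n_total=len(xy), n_out_of_range=int(len(xy) - total))


@dataclass
class RadialDistribution:
    """Radial histogram of one species, in probability or RDF normalization."""

    bin_edges: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    species: str = "protein"
    normalization: str = "probability"      # {"probability", "rdf"}
    r_max_display: float = R_MAX_DISPLAY
    areas: np.ndarray | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def displayed(self) -> np.ndarray:
        """Mask of bins inside the display truncation radius."""
        return self.bin_centers <= self.r_max_display

    def to_table(self):
        import pandas as pd

        return pd.DataFrame({
            "r": self.bin_centers,
            "density": self.density,
            "counts": self.counts,
            "displayed": self.displayed,
        })


def radial_histogram(traces, center, n_bins: int = 100,
                     r_range=(0.0, 25.0), species: str = "protein",
                     r_max_display: float = R_MAX_DISPLAY) -> RadialDistribution:
    """Probability histogram of radial distances; bin sum is exactly 1."""
    if n_bins < 1:
        raise InvalidConfigError("n_bins must be >= 1")
    xy = _pool_xy(traces)
    r = radial_distance(xy, center)
    counts, edges = np.histogram(r, bins=n_bins, range=r_range)
    total = counts.sum()
    if total == 0:
        raise EmptyHistogramError("no radial distances inside r_range")
    return RadialDistribution(bin_edges=edges, density=counts / total,
                              counts=counts, species=species,
                              normalization="probability",
                              r_max_display=r_max_display)


def lipid_radial_histogram(frames, center, species: str,
                           n_bins: int = 100, r_range=(0.0, 25.0),
                           r_max_display: float = R_MAX_DISPLAY) -> RadialDistribution:
    """Radial probability histogram of one lipid headgroup species."""
    if isinstance(frames, BeadFrame):
        frames = [frames]
    pos = [fr.select(species) for fr in frames]
    pos = [p for p in pos if len(p)]
    if not pos:
        raise EmptyHistogramError(f"no {species} beads in any frame")
    xy = np.concatenate(pos)[:, :2]
    r = radial_distance(xy, center)
    counts, edges = np.histogram(r, bins=n_bins, range=r_range)
    if counts.sum() == 0:
        raise EmptyHistogramError("no radial distances inside r_range")
    return RadialDistribution(bin_edges=edges, density=counts / counts.sum(),
                              counts=counts, species=species,
                              normalization="probability",
                              r_max_display=r_max_display)


def rdf_normalize(hist: RadialDistribution, box,
                  center) -> RadialDistribution:
    """Convert a probability histogram to the bulk-referenced RDF.

    Each bin's count is divided by its annular area clipped to the box and
    by the species' global area density (total count / clipped reference
    area), so uniform occupancy gives RDF = 1 in every bin.
    """
    if hist.normalization != "probability":
        raise InvalidInputError("rdf_normalize expects a probability histogram")
    total = hist.counts.sum()
    if total == 0:
        raise InvalidInputError("histogram holds no counts")
    rect = (0.0, float(box[0]), 0.0, float(box[1]))
    areas = annulus_rect_areas(center, hist.bin_edges, rect)
    reference_area = areas.sum()
    if reference_area <= 0:
        raise InvalidInputError("zero reference area")
    bulk_density = total / reference_area
    with np.errstate(divide="ignore", invalid="ignore"):
        rdf = np.where(areas > 0, hist.counts / np.maximum(areas, 1e-300)
                       / bulk_density, 0.0)
    return RadialDistribution(bin_edges=hist.bin_edges, density=rdf,
                              counts=hist.counts, species=hist.species,
                              normalization="rdf",
                              r_max_display=hist.r_max_display, areas=areas)


def radial_kde(radii, bandwidth=None, grid=None):
    """Gaussian KDE of raw radial samples (Scott's-rule bandwidth).

    Returns ``(grid, density)``; the density integrates to 1 over a grid
    wide enough to hold the full kernel mass.
    """
    radii = np.asarray(radii, dtype=float).ravel()
    if len(radii) < 2 or np.ptp(radii) == 0:
        raise InvalidInputError(
            "KDE needs >= 2 distinct radii; for degenerate samples use the "
            "histogram instead")
    kde = gaussian_kde(radii, bw_method=bandwidth)
    if grid is None:
        bw = np.sqrt(kde.covariance[0, 0])
        grid = np.linspace(radii.min() - 6 * bw, radii.max() + 6 * bw, 512)
    return grid, kde(grid)


@dataclass
class PeakLocation:
    """Argmax of an RDF with its curvature-region label."""

    r_peak: float | None
    region: str | None
    tied_radii: list = field(default_factory=list)
    has_peak: bool = True


def peak_location(rdf: RadialDistribution, curvature_profile=None,
                  displayed_only: bool = True,
                  min_count: int = 0) -> PeakLocation:
    """Peak bin centre of an RDF and the curvature region it falls in.

    Ties are broken toward smaller r and reported; a flat distribution
    (max == min) returns ``has_peak=False``.  ``min_count`` excludes bins
    with fewer raw counts from peak candidacy, so shot noise in near-empty
    small-area annuli cannot masquerade as a peak.
    """
    centers = rdf.bin_centers
    dens = rdf.density
    mask = np.ones(len(dens), dtype=bool)
    if displayed_only:
        mask &= rdf.displayed
    if min_count > 0:
        mask &= rdf.counts >= min_count
    centers, dens = centers[mask], dens[mask]
    if len(dens) == 0 or np.ptp(dens) == 0:
        return PeakLocation(r_peak=None, region=None, has_peak=False)
    peak = dens.max()
    tied = centers[dens == peak]
    r_peak = float(tied[0])
    region = (curvature_profile.region_at(r_peak)
              if curvature_profile is not None else None)
    return PeakLocation(r_peak=r_peak, region=region,
                        tied_radii=[float(t) for t in tied[1:]])
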
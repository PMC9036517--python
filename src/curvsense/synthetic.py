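"""Synthetic curved-membrane frames and protein centre-of-mass traces.

This module stands in for the coarse-grained MD output the analysis was
designed for.  It emulates three features of the reference system:

* a radially symmetric membrane draped over a central pore, with headgroup
  heights on the sigmoid surface of :mod:`curvsense.profile` plus Gaussian
  roughness and tail beads offset toward the bilayer midplane;
* curvature-sorted PIP2: headgroups in the top leaflet only, placed with
  probability proportional to ``exp(pip2_curvature_weight * K(r))`` under the
  package-wide convention K > 0 = concave, so a positive weight enriches
  PIP2 at concave and depletes it at convex curvature while the marginal
  PIP2 fraction stays at its nominal value;
* protein localization as a Metropolis random walk on the membrane surface
  with the two-term energy

      U(r) = -w_hydro * A_convex(r) - w_pip2 * A_pip2(r)   [kT]

  where ``A_convex`` is the normalized convexity score (clipped -K, scaled
  to max 1) and ``A_pip2`` the normalized local PIP2 area density.  The
  stationary radial occupancy is the Boltzmann distribution
  ``p(bin) ∝ area(bin) * exp(-U(r_bin))``, which
  :func:`boltzmann_radial_occupancy` evaluates by direct summation.

Seeding: one master seed; per-replica and per-frame streams are derived
through fixed ``SeedSequence`` offsets, so identical configs give
bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GeneratorConfig, ProteinSpec
from .errors import InvalidConfigError
from .frames import NO_RESIDUE, BeadFrame, ProteinTrace
from .geometry import annulus_rect_areas, box_rect
from .profile import surface_derivatives, surface_height

#: z-offsets (nm) from the local headgroup surface for the four beads of a
#: top-leaflet lipid (head, glycerol, tail, tail); bottom leaflet mirrors
#: them across the bilayer midplane 2.1 nm below the top headgroups.
_TOP_OFFSETS = (0.0, -0.7, -1.4, -2.0)
_MIDPLANE_DEPTH = 2.1
_LIPID_ROLES = ("head", "glycerol", "tail", "tail")

#: Protein CoM rides this far above the local headgroup surface.
PROTEIN_Z_OFFSET = 0.5


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child stream for a fixed offset key."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def local_curvature(r, config: GeneratorConfig):
    """Analytic K(r) of the generator's own surface (K > 0 concave)."""
    d1, d2 = surface_derivatives(r, config.profile_params)
    return d2 / (1.0 + d1 ** 2) ** 1.5


def generate_membrane_frame(config: GeneratorConfig, rng=None,
                            time: int = 0) -> BeadFrame:
    """One labelled bead snapshot of the curved bilayer.

    Lipid sites are uniform in the box xy-plane; headgroups sit on
    ``surface_height(r) + N(0, noise_sigma)``, tails toward the midplane.
    PIP2 identity is assigned to top-leaflet sites with probability
    ``pip2_fraction * exp(w*K) / <exp(w*K)>`` so the expected PIP2 count is
    ``pip2_fraction`` of all lipid sites (binomial tolerance).
    """
    config.validate()
    if rng is None:
        rng = _rng(config.seed, 0, time)
    n_lip = config.n_lipids
    if n_lip == 0:
        raise InvalidConfigError("cannot generate a membrane with zero lipids")
    lx, ly, lz = config.box
    xc, yc = config.pore_center

    xy = rng.uniform([0.0, 0.0], [lx, ly], size=(n_lip, 2))
    r = np.hypot(xy[:, 0] - xc, xy[:, 1] - yc)
    h = surface_height(r, config.profile_params)
    n_top = n_lip // 2 + n_lip % 2
    top = np.zeros(n_lip, dtype=bool)
    top[:n_top] = True

    # Curvature-weighted PIP2 identity among top-leaflet sites.
    is_pip2 = np.zeros(n_lip, dtype=bool)
    if config.pip2_fraction > 0:
        k_top = local_curvature(r[top], config)
        w = np.exp(config.pip2_curvature_weight * k_top)
        p = config.pip2_fraction * (n_lip / n_top) * w / np.mean(w)
        if np.any(p > 1.0):
            raise InvalidConfigError(
                "pip2_fraction x curvature weighting exceeds probability 1; "
                "reduce pip2_curvature_weight or pip2_fraction")
        is_pip2[top] = rng.uniform(size=n_top) < p

    positions, species, leaflet, resid = [], [], [], []
    noise = rng.normal(0.0, config.noise_sigma, size=n_lip)
    head_z = np.where(top, h + noise, h - 2 * _MIDPLANE_DEPTH + noise)
    sign = np.where(top, 1.0, -1.0)
    for off, role in zip(_TOP_OFFSETS, _LIPID_ROLES):
        positions.append(np.column_stack([xy[:, 0], xy[:, 1],
                                          head_z + sign * off]))
        if role == "head":
            species.append(np.where(is_pip2, "PIP2_head", "PC_head"))
        else:
            species.append(np.full(n_lip, role, dtype=object))
        leaflet.append(np.where(top, "top", "bottom"))
        resid.append(np.full(n_lip, NO_RESIDUE))

    pos = np.concatenate(positions)
    pos[:, 2] = np.clip(pos[:, 2], 0.0, lz)       # keep inside box in z
    return BeadFrame(
        positions=pos,
        species=np.concatenate(species),
        leaflet=np.concatenate(leaflet),
        residue_index=np.concatenate(resid),
        box=config.box,
        time=time,
    )


def generate_membrane_frames(config: GeneratorConfig) -> list[BeadFrame]:
    """``config.n_frames`` independent snapshots with per-frame streams."""
    return [generate_membrane_frame(config, rng=_rng(config.seed, 0, t), time=t)
            for t in range(config.n_frames)]


# ---------------------------------------------------------------------------
# Radial energy landscape and Boltzmann occupancy


@dataclass
class RadialEnergy:
    """Tabulated U(r) in kT on a radial grid, with its ingredient fields."""

    r: np.ndarray
    U: np.ndarray
    convexity: np.ndarray     # A_convex(r) in [0, 1]
    pip2_density: np.ndarray  # A_pip2(r) in [0, 1]

    def at(self, r):
        return np.interp(r, self.r, self.U)


def pip2_radial_density(frames, config: GeneratorConfig,
                        r_grid: np.ndarray,
                        count_bin_width: float = 1.0) -> np.ndarray:
    """Normalized (max = 1) local PIP2 area density on ``r_grid``.

    Per-annulus PIP2 headgroup counts (coarse ``count_bin_width`` annuli so
    a few-percent species is not shot-noise dominated) divided by clipped
    annulus areas, lightly smoothed and interpolated onto ``r_grid``; zero
    everywhere for PC-only membranes.
    """
    r_max = float(r_grid[-1])
    edges = np.arange(0.0, r_max + count_bin_width, count_bin_width)
    areas = annulus_rect_areas(config.pore_center, edges, box_rect(config.box))
    counts = np.zeros(len(edges) - 1)
    xc, yc = config.pore_center
    for fr in frames:
        pos = fr.select("PIP2_head")
        if not len(pos):
            continue
        r = np.hypot(pos[:, 0] - xc, pos[:, 1] - yc)
        idx = np.digitize(r, edges) - 1
        keep = (idx >= 0) & (idx < len(counts))
        counts += np.bincount(idx[keep], minlength=len(counts))
    if counts.sum() == 0:
        return np.zeros(len(r_grid))
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(areas > 1e-9, counts / np.maximum(areas, 1e-9), 0.0)
    # mild 3-point smoothing: shot noise should not define the energy minimum
    kernel = np.array([0.25, 0.5, 0.25])
    dens = np.convolve(np.pad(dens, 1, mode="edge"), kernel, mode="valid")
    mid = 0.5 * (edges[:-1] + edges[1:])
    out = np.interp(r_grid, mid, dens)
    return out / out.max() if out.max() > 0 else out


def radial_energy(config: GeneratorConfig, frames=None,
                  protein: ProteinSpec | None = None,
                  n_grid: int = 256) -> RadialEnergy:
    """Tabulate U(r) = -w_hydro A_convex(r) - w_pip2 A_pip2(r) in kT."""
    protein = protein or config.protein
    if protein.w_hydro < 0 or protein.w_pip2 < 0:
        raise InvalidConfigError("energy weights must be non-negative "
                                 "(negative temperature equivalent)")
    lx, ly, _ = config.box
    xc, yc = config.pore_center
    r_max = float(np.hypot(max(xc, lx - xc), max(yc, ly - yc)))
    r = np.linspace(0.0, r_max, n_grid)
    K = local_curvature(r, config)
    convex = np.clip(-K, 0.0, None)
    if convex.max() > 0:
        convex = convex / convex.max()
    if frames is not None and protein.w_pip2 > 0:
        pip2 = pip2_radial_density(frames, config, r)
    else:
        pip2 = np.zeros_like(r)
    U = -protein.w_hydro * convex - protein.w_pip2 * pip2
    return RadialEnergy(r=r, U=U, convexity=convex, pip2_density=pip2)


def boltzmann_radial_occupancy(energy: RadialEnergy, config: GeneratorConfig,
                               bin_edges: np.ndarray) -> np.ndarray:
    """Stationary bin occupancy by direct summation on the radial grid.

    ``p(bin) ∝ clipped_area(bin) * mean over the bin of exp(-U)``; the
    area-weighted within-bin average of exp(-U) is taken on a fine radial
    subgrid so narrow bins and wide bins are treated consistently.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    rect = box_rect(config.box)
    p = np.zeros(len(bin_edges) - 1)
    for i, (lo, hi) in enumerate(zip(bin_edges[:-1], bin_edges[1:])):
        sub = np.linspace(lo, hi, 8)
        sub_areas = annulus_rect_areas(config.pore_center, sub, rect)
        mid = 0.5 * (sub[:-1] + sub[1:])
        p[i] = np.sum(sub_areas * np.exp(-energy.at(mid)))
    total = p.sum()
    if total <= 0:
        raise InvalidConfigError("Boltzmann occupancy has zero mass")
    return p / total


def generate_protein_trace(config: GeneratorConfig, energy: RadialEnergy,
                           replica_id: int = 0, n_steps: int | None = None,
                           rng=None, step_sigma: float = 1.0,
                           burn_in: int = 0) -> ProteinTrace:
    """Metropolis random walk of the protein CoM on the membrane surface.

    Symmetric Gaussian xy-proposals; moves outside the box are rejected
    (Metropolis on a bounded domain), so the stationary xy-density is
    ``exp(-U(r))`` per unit area and the radial occupancy matches
    :func:`boltzmann_radial_occupancy` within sampling error.  z rides on
    the membrane surface.
    """
    config.validate()
    if n_steps is None:
        n_steps = 10_000
    if n_steps < 1:
        raise InvalidConfigError("n_steps must be >= 1")
    if rng is None:
        rng = _rng(config.seed, 1, replica_id)
    lx, ly, _ = config.box
    xc, yc = config.pore_center

    xy = np.array([rng.uniform(0, lx), rng.uniform(0, ly)])
    u = energy.at(np.hypot(xy[0] - xc, xy[1] - yc))
    out = np.empty((n_steps, 4))
    steps = rng.normal(0.0, step_sigma, size=(burn_in + n_steps, 2))
    accepts = rng.uniform(size=burn_in + n_steps)
    for i in range(burn_in + n_steps):
        prop = xy + steps[i]
        if 0.0 <= prop[0] <= lx and 0.0 <= prop[1] <= ly:
            u_new = energy.at(np.hypot(prop[0] - xc, prop[1] - yc))
            if u_new <= u or accepts[i] < np.exp(u - u_new):
                xy, u = prop, u_new
        if i >= burn_in:
            j = i - burn_in
            out[j, 0] = j
            out[j, 1:3] = xy
            out[j, 3] = surface_height(np.hypot(xy[0] - xc, xy[1] - yc),
                                       config.profile_params) + PROTEIN_Z_OFFSET
    return ProteinTrace(replica_id=replica_id, frames=out)


def generate_protein_traces(config: GeneratorConfig, energy: RadialEnergy,
                            n_steps: int | None = None,
                            step_sigma: float = 1.0,
                            burn_in: int = 0) -> list[ProteinTrace]:
    """One trace per replica, each from its own fixed-offset stream."""
    return [generate_protein_trace(config, energy, replica_id=k,
                                   n_steps=n_steps, step_sigma=step_sigma,
                                   burn_in=burn_in)
            for k in range(config.n_replicas)]


# ---------------------------------------------------------------------------
# Planted protein beads for contact analysis


def plant_protein_beads(config: GeneratorConfig, frame: BeadFrame,
                        anchor_xy: tuple[float, float] | None = None,
                        protein: ProteinSpec | None = None) -> BeadFrame:
    """Append one backbone bead per residue to ``frame``.

    Residues listed in ``protein.embedded_residues`` are buried at
    hydrophobic-tail depth; PIP2-binding basic residues sit at headgroup
    level; all other residues float above the membrane.  The backbone runs
    along +x at 0.35 nm per residue, anchored by default at the convex band
    (taper_outer_radius) along +x of the pore centre.
    """
    protein = protein or config.protein
    protein.validate()
    xc, yc = config.pore_center
    if anchor_xy is None:
        anchor_xy = (xc + config.taper_outer_radius, yc)
    n = protein.n_residues
    x = anchor_xy[0] + 0.35 * (np.arange(n) - n / 2)
    y = np.full(n, anchor_xy[1])
    r = np.hypot(x - xc, y - yc)
    h = surface_height(r, config.profile_params)
    from .config import PIP2_BINDING_RESIDUES

    z = h + 1.0                                      # default: above heads
    basic = np.isin(np.arange(1, n + 1), PIP2_BINDING_RESIDUES)
    z[basic] = h[basic]                              # headgroup level
    embedded = np.isin(np.arange(1, n + 1), protein.embedded_residues)
    z[embedded] = h[embedded] - 1.7                  # between the tail layers

    pos = np.vstack([frame.positions, np.column_stack([x, y, z])])
    species = np.concatenate([frame.species, np.full(n, "protein", dtype=object)])
    leaflet = np.concatenate([frame.leaflet, np.full(n, "none", dtype=object)])
    resid = np.concatenate([frame.residue_index, np.arange(1, n + 1)])
    return BeadFrame(pos, species, leaflet, resid, frame.box, frame.time)
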
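"""Per-residue protein-lipid contact counting and a tilt-angle measure.

A contact is a (protein bead, target bead) pair within a distance cutoff
under the minimum-image convention in the fully periodic box; counting is
accelerated with a periodic cKD-tree and, by construction, equals the
quadratic pair enumeration.  The two target groups of interest are
hydrophobic lipid tails (``tail`` beads) and PIP2 headgroups
(``PIP2_head`` beads); glycerol is excluded from both.

Residue classes follow the convention used for highlighting: hydrophobic =
{L, I, A, V, M, Y}, basic = {K, H, R}, everything else "other".

The tilt angle is the package's declared stand-in for a rotation-matrix
orientation analysis: the angle between the protein's largest-variance
principal axis (orientation disambiguated by a reference residue pair) and
the membrane normal (+z), in degrees within [0, 180].
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (DegenerateGeometryError, EmptySelectionError,
                     InvalidConfigError)
from .frames import BeadFrame

HYDROPHOBIC_RESIDUES = frozenset("LIAVMY")
BASIC_RESIDUES = frozenset("KHR")

#: Species selections behind the two published contact groups.
TARGET_GROUPS = {"hydrophobic_tails": "tail", "pip2_heads": "PIP2_head"}


def classify_residue(code: str) -> str:
    """Residue class used for profile highlighting."""
    if code in HYDROPHOBIC_RESIDUES:
        return "hydrophobic"
    if code in BASIC_RESIDUES:
        return "basic"
    return "other"


def count_contacts(frame: BeadFrame, target_species: str, cutoff: float,
                   residues: np.ndarray | None = None) -> dict[int, int]:
    """Per-residue pair counts within ``cutoff`` (nm), periodic min-image.

    Parameters
    ----------
    frame : snapshot containing protein beads (residue_index >= 1)
    target_species : species label of the target beads, e.g. ``"tail"``
    cutoff : contact distance in nm
    residues : optional subset of residue indices to report

    Returns a dict residue_index -> number of (residue bead, target bead)
    pairs within the cutoff.
    """
    if cutoff <= 0:
        raise InvalidConfigError("cutoff must be positive")
    box = np.asarray(frame.box, dtype=float)
    prot = frame.residue_index >= 1
    if not np.any(prot):
        raise EmptySelectionError("no protein beads (residue_index >= 1) in frame")
    targ = frame.species == target_species
    if not np.any(targ):
        raise EmptySelectionError(f"no beads of target species {target_species!r}")

    ppos = np.mod(frame.positions[prot], box)
    tpos = np.mod(frame.positions[targ], box)
    presid = frame.residue_index[prot]
    tree = cKDTree(tpos, boxsize=box)
    neighbours = tree.query_ball_point(ppos, r=cutoff)

    if residues is None:
        residues = np.unique(presid)
    counts = {int(r): 0 for r in residues}
    for resid, hits in zip(presid, neighbours):
        key = int(resid)
        if key in counts:
            counts[key] += len(hits)
    return counts


@dataclass
class ContactProfile:
    """Mean per-residue contacts for one target group."""

    residue_index: np.ndarray       # 1-based, contiguous
    residue_code: np.ndarray
    residue_class: np.ndarray
    mean_contacts: np.ndarray
    group: str
    n_frames: int
    n_replicas: int
    per_replica_means: np.ndarray | None = None   # (n_replicas, n_residues)

    def to_table(self):
        import pandas as pd

        df = pd.DataFrame({
            "residue_index": self.residue_index,
            "residue_code": self.residue_code,
            "residue_class": self.residue_class,
            "mean_contacts": self.mean_contacts,
        })
        if self.per_replica_means is not None:
            for k in range(self.per_replica_means.shape[0]):
                df[f"replica_{k}"] = self.per_replica_means[k]
        return df


def average_contact_profile(replica_frames, sequence: str, group: str,
                            cutoff: float = 0.6) -> ContactProfile:
    """Mean contacts per residue over all frames of all replicas.

    ``replica_frames`` is a sequence of per-replica frame lists (a flat
    list of frames is treated as one replica).  The pooled mean weights
    every frame equally; per-replica means are retained for dispersion.
    """
    if group not in TARGET_GROUPS:
        raise InvalidConfigError(
            f"unknown contact group {group!r}; expected {sorted(TARGET_GROUPS)}")
    target = TARGET_GROUPS[group]
    if replica_frames and isinstance(replica_frames[0], BeadFrame):
        replica_frames = [replica_frames]
    n_res = len(sequence)
    residues = np.arange(1, n_res + 1)

    per_rep, frames_per_rep = [], []
    for frames in replica_frames:
        totals = np.zeros(n_res)
        n = 0
        for fr in frames:
            counts = count_contacts(fr, target, cutoff, residues=residues)
            totals += np.array([counts[int(i)] for i in residues], dtype=float)
            n += 1
        if n == 0:
            continue
        per_rep.append(totals / n)
        frames_per_rep.append(n)
    if not per_rep:
        raise EmptySelectionError("no frames supplied to average_contact_profile")
    per_rep = np.asarray(per_rep)
    weights = np.asarray(frames_per_rep, dtype=float)
    mean = (per_rep * weights[:, None]).sum(axis=0) / weights.sum()
    codes = np.array(list(sequence), dtype=object)
    return ContactProfile(
        residue_index=residues, residue_code=codes,
        residue_class=np.array([classify_residue(c) for c in codes], dtype=object),
        mean_contacts=mean, group=group,
        n_frames=int(weights.sum()), n_replicas=len(per_rep),
        per_replica_means=per_rep)


@dataclass
class TopResidues:
    """Ranked top-k contact residues."""

    residues: list[int]
    codes: list[str]
    means: list[float]
    ties_broken: bool = False
    has_peak: bool = True


def top_contact_residues(profile: ContactProfile, k: int) -> TopResidues:
    """k residues of highest mean contacts; ties broken by lower index."""
    n = len(profile.residue_index)
    if k > n:
        warnings.warn(f"k={k} exceeds residue count {n}; truncating", stacklevel=2)
        k = n
    if np.all(profile.mean_contacts == 0):
        return TopResidues(residues=[], codes=[], means=[], has_peak=False)
    # stable sort on (-mean, index): ties go to the lower residue index
    order = np.lexsort((profile.residue_index, -profile.mean_contacts))[:k]
    means = profile.mean_contacts[order]
    tied = False
    if k < n:
        boundary = profile.mean_contacts[
            np.lexsort((profile.residue_index, -profile.mean_contacts))[k]]
        tied = bool(np.any(means == boundary))
    return TopResidues(
        residues=[int(i) for i in profile.residue_index[order]],
        codes=[str(c) for c in profile.residue_code[order]],
        means=[float(m) for m in means],
        ties_broken=tied)


def tilt_angle(frame: BeadFrame,
               reference_axis_residues: tuple[int, int] | None = None) -> float:
    """Angle (degrees) between the protein principal axis and the z-axis.

    The axis is the largest-variance eigenvector of the protein bead
    positions; its orientation is disambiguated so it points from the first
    to the second residue of ``reference_axis_residues`` (default: first to
    last protein residue present).
    """
    prot = frame.residue_index >= 1
    pos = frame.positions[prot]
    resid = frame.residue_index[prot]
    if len(pos) < 3:
        raise DegenerateGeometryError("need >= 3 protein beads for a tilt axis")
    centred = pos - pos.mean(axis=0)
    cov = centred.T @ centred / len(pos)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-12 or (evals[-1] - evals[-2]) / max(evals[-1], 1e-12) < 1e-9:
        raise DegenerateGeometryError(
            "protein bead geometry is degenerate (no unique principal axis)")
    axis = evecs[:, -1]
    if reference_axis_residues is None:
        reference_axis_residues = (int(resid.min()), int(resid.max()))
    i, j = reference_axis_residues
    pi = pos[resid == i].mean(axis=0)
    pj = pos[resid == j].mean(axis=0)
    if np.dot(axis, pj - pi) < 0:
        axis = -axis
    cosang = np.clip(axis[2] / np.linalg.norm(axis), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))
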
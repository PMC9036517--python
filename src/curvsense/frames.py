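"""In-memory containers for coarse-grained snapshots and protein traces.

A :class:`BeadFrame` holds one labelled snapshot of the membrane + protein
system: bead positions in nm, a species label per bead, a leaflet label per
lipid bead, and a 1-based residue index per protein bead.  A
:class:`ProteinTrace` holds the per-frame protein centre of mass for one
replica.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

#: Recognised bead species labels.
SPECIES = ("PC_head", "PIP2_head", "glycerol", "tail", "protein", "wafer")
LEAFLETS = ("top", "bottom", "none")

#: Sentinel residue index for non-protein beads.
NO_RESIDUE = -1


@dataclass
class BeadFrame:
    """One snapshot of labelled bead positions.

    Parameters
    ----------
    positions : (N, 3) float array, nm
    species : (N,) str array with values from :data:`SPECIES`
    leaflet : (N,) str array with values from :data:`LEAFLETS`
    residue_index : (N,) int array, 1-based for protein beads, -1 otherwise
    box : (Lx, Ly, Lz) nm
    time : frame index
    """

    positions: np.ndarray
    species: np.ndarray
    leaflet: np.ndarray
    residue_index: np.ndarray
    box: tuple[float, float, float]
    time: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.species = np.asarray(self.species, dtype=object)
        self.leaflet = np.asarray(self.leaflet, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if not (len(self.species) == len(self.leaflet) == len(self.residue_index) == n):
            raise InvalidInputError(
                "species, leaflet and residue_index must match positions length"
            )
        unknown = set(self.species) - set(SPECIES)
        if unknown:
            raise InvalidInputError(f"unknown species labels: {sorted(unknown)}")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidInputError("non-finite bead positions")
        pip2 = self.species == "PIP2_head"
        if np.any(pip2) and not np.all(self.leaflet[pip2] == "top"):
            raise InvalidInputError("PIP2_head beads must carry leaflet='top'")

    def __len__(self) -> int:
        return len(self.positions)

    def select(self, species: str) -> np.ndarray:
        """Positions of all beads of one species."""
        return self.positions[self.species == species]

    def wrapped(self) -> "BeadFrame":
        """Copy with positions periodically wrapped into [0, box)."""
        box = np.asarray(self.box, dtype=float)
        pos = np.mod(self.positions, box)
        return BeadFrame(pos, self.species.copy(), self.leaflet.copy(),
                         self.residue_index.copy(), self.box, self.time)


@dataclass
class ProteinTrace:
    """Protein centre-of-mass time series for one replica.

    ``frames`` is an (T, 4) array of (time index, x, y, z) in nm with strictly
    increasing times.
    """

    replica_id: int
    frames: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float).reshape(-1, 4)
        if not np.all(np.isfinite(self.frames)):
            raise InvalidInputError("non-finite trace entries")
        t = self.frames[:, 0]
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InvalidInputError(
                f"times must be strictly increasing within replica {self.replica_id}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def xy(self) -> np.ndarray:
        return self.frames[:, 1:3]

    @property
    def xyz(self) -> np.ndarray:
        return self.frames[:, 1:4]
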
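"""Run configuration objects and YAML I/O.

The generator defaults reproduce the study conditions of the reference
system: a 32 x 40 x 33 nm box, a radially symmetric curved membrane over a
central pore at (16, 20) nm with a tapered transition region between 6 and
11 nm, membranes of 100% PC or 97.5% PC + 2.5% PIP2 (PIP2 in the top
leaflet only), and 8 replicas per condition.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidConfigError

#: Synthetic 55-residue analogue of the ANTH N-terminal region.  The key
#: hydrophobic residues (L6, I10, V17, Y44, M52) and PIP2-binding basic
#: residues (K24, K28, K38-K40) sit at their literature 1-based positions;
#: every other position is filled with residues outside both the hydrophobic
#: {L,I,A,V,M,Y} and basic {K,H,R} classes so planted-contact recovery is
#: unambiguous.  This is a synthetic stand-in, not a crystal-structure
#: sequence.
SYNTHETIC_ANTH_SEQUENCE = (
    "STNQE" "L" "DGS" "I" "TNQEDG" "V" "STNQED" "K" "GST" "K" "NQEDGSTNQ"
    "KKK" "EDG" "Y" "STNQEDG" "M" "STN"
)

#: Residues inserted into the hydrophobic tail region for each terminal-helix
#: analogue; counts follow the 5 : 2 : 2 hydrophobic-residue ratio of the
#: full, split and short variants.
EMBEDDED_RESIDUES = {
    "full": (6, 10, 17, 44, 52),
    "split": (6, 10),
    "short": (44, 52),
}

#: Basic residues engaging PIP2 headgroups; identical for all variants.
PIP2_BINDING_RESIDUES = (24, 28, 38, 39, 40)

#: Per-hydrophobic-residue membrane-insertion weight and the PIP2-site
#: electrostatic weight, both in kT.  See docs/methods.md for the rationale.
W_HYDRO_PER_RESIDUE = 1.2
W_PIP2_SITE = 4.0


@dataclass
class ProteinSpec:
    """Protein analogue: sequence, energy weights and embedded residues."""

    n_residues: int = 55
    sequence: str = SYNTHETIC_ANTH_SEQUENCE
    w_hydro: float = W_HYDRO_PER_RESIDUE * 5
    w_pip2: float = W_PIP2_SITE
    embedded_residues: tuple[int, ...] = EMBEDDED_RESIDUES["full"]

    def validate(self) -> None:
        if self.n_residues < 1:
            raise InvalidConfigError("n_residues must be >= 1")
        if len(self.sequence) != self.n_residues:
            raise InvalidConfigError(
                f"sequence length {len(self.sequence)} != n_residues {self.n_residues}"
            )
        if self.w_hydro < 0 or self.w_pip2 < 0:
            raise InvalidConfigError("energy weights must be non-negative")
        for r in self.embedded_residues:
            if not 1 <= r <= self.n_residues:
                raise InvalidConfigError(f"embedded residue {r} outside sequence")

    @classmethod
    def preset(cls, name: str) -> "ProteinSpec":
        """The full/split/short terminal-helix analogue presets.

        Hydrophobic weights scale with the number of embedded hydrophobic
        residues (5, 2 and 2); the PIP2 weight is identical across presets
        because PIP2 binding is unaffected by the terminal helix.
        """
        try:
            embedded = EMBEDDED_RESIDUES[name]
        except KeyError:
            raise InvalidConfigError(
                f"unknown preset {name!r}; expected one of {sorted(EMBEDDED_RESIDUES)}"
            ) from None
        return cls(
            w_hydro=W_HYDRO_PER_RESIDUE * len(embedded),
            w_pip2=W_PIP2_SITE,
            embedded_residues=embedded,
        )


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic curved-membrane + protein generator.

    ``profile_params`` are the five membrane-height sigmoid parameters
    (a, b, c, d, x0); defaults place the concave band near r = 6 nm and the
    convex band near r = 11 nm.  ``n_pc`` counts PC lipids over both
    leaflets; the total lipid count is ``n_pc / (1 - pip2_fraction)`` so the
    expected PIP2 count is ``pip2_fraction`` of all lipids, all placed in the
    top leaflet.
    """

    box: tuple[float, float, float] = (32.0, 40.0, 33.0)
    pore_center: tuple[float, float] = (16.0, 20.0)
    pore_depth: float = 4.0
    taper_inner_radius: float = 6.0
    taper_outer_radius: float = 11.0
    profile_params: tuple[float, float, float, float, float] = (
        15.0, 0.527, 11.0, 1.0, 8.5)
    n_pc: int = 3900
    pip2_fraction: float = 0.025
    pip2_curvature_weight: float = 12.0
    protein: ProteinSpec = field(default_factory=ProteinSpec)
    n_frames: int = 10
    n_replicas: int = 8
    noise_sigma: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.pip2_fraction <= 1.0:
            raise InvalidConfigError("pip2_fraction must lie in [0, 1]")
        lx, ly, lz = self.box
        if min(lx, ly, lz) <= 0:
            raise InvalidConfigError("box lengths must be positive")
        if not (0 < self.taper_inner_radius < self.taper_outer_radius
                < min(lx, ly) / 2):
            raise InvalidConfigError(
                "require 0 < taper_inner_radius < taper_outer_radius < min(Lx,Ly)/2"
            )
        if self.pore_depth <= 0 or self.noise_sigma < 0:
            raise InvalidConfigError("length scales must be positive")
        if self.n_frames < 1:
            raise InvalidConfigError("n_frames must be >= 1")
        if self.n_replicas < 1:
            raise InvalidConfigError("n_replicas must be >= 1")
        if self.n_pc < 0:
            raise InvalidConfigError("n_pc must be non-negative")
        if self.pip2_fraction > 0 and self.n_pc == 0:
            raise InvalidConfigError("pip2_fraction > 0 requires lipids (n_pc > 0)")
        import numpy as np
        if not np.all(np.isfinite(self.profile_params)):
            raise InvalidConfigError("profile_params must be finite")
        self.protein.validate()

    @property
    def n_lipids(self) -> int:
        """Total lipid sites over both leaflets (PC + expected PIP2)."""
        if self.pip2_fraction >= 1.0:
            raise InvalidConfigError("pip2_fraction must be < 1 for a PC membrane")
        return int(round(self.n_pc / (1.0 - self.pip2_fraction)))


@dataclass
class AnalysisConfig:
    """Analysis-stage parameters shared across the pipeline."""

    center: tuple[float, float] = (16.0, 20.0)
    n_bins: int = 100
    r_range: tuple[float, float] = (0.0, 25.0)
    r_max_display: float = 16.0
    cutoff: float = 0.6
    flat_threshold: float = 0.01
    bin_width: float = 0.5
    discard_frames: int = 0

    def validate(self) -> None:
        if self.n_bins < 1 or self.bin_width <= 0 or self.cutoff <= 0:
            raise InvalidConfigError("n_bins, bin_width and cutoff must be positive")
        if not self.r_range[0] < self.r_range[1]:
            raise InvalidConfigError("r_range must be increasing")
        if self.flat_threshold < 0:
            raise InvalidConfigError("flat_threshold must be non-negative")
        if self.discard_frames < 0:
            raise InvalidConfigError("discard_frames must be non-negative")


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    input_traces: str | None = None
    input_frames: str | None = None
    output_dir: str = "curvsense_out"
    seed: int = 0

    def validate(self) -> None:
        self.generator.validate()
        self.analysis.validate()

    @property
    def synthetic(self) -> bool:
        return self.input_traces is None and self.input_frames is None

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the scientific configuration, for the run manifest.

        The output directory is excluded: where results are written must not
        change what they are.
        """
        payload = self.to_dict()
        payload.pop("output_dir", None)
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration mirroring the dataclass field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen = raw.get("generator", {})
    protein = ProteinSpec(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in gen.pop("protein", {}).items()})
    gen = {k: tuple(v) if isinstance(v, list) else v for k, v in gen.items()}
    ana = {k: tuple(v) if isinstance(v, list) else v
           for k, v in raw.get("analysis", {}).items()}
    cfg = RunConfig(
        generator=GeneratorConfig(protein=protein, **gen),
        analysis=AnalysisConfig(**ana),
        input_traces=raw.get("input_traces"),
        input_frames=raw.get("input_frames"),
        output_dir=raw.get("output_dir", "curvsense_out"),
        seed=int(raw.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
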
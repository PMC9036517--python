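"""File formats: GRO coordinate files and the tabular trace format.

GRO files are written with the fixed-width Gromos87 layout (coordinates in
nm to 3 decimals, box vectors on the final line) and read back through
MDAnalysis.  Species and leaflet labels are encoded in residue/atom names
so standard viewers parse the files:

========== ============ ======================================
species     resname      atom name
========== ============ ======================================
PC_head     DOPC         NC3T / NC3B (top / bottom leaflet)
PIP2_head   POP2         P1T  (top leaflet only)
glycerol    DOPC, POP2   GL1T / GL1B
tail        DOPC, POP2   C1AT / C1AB
protein     3-letter AA  BB   (resid = 1-based residue index)
wafer       WAF          Q0
========== ============ ======================================

The trace format is plain tab-separated text with a required header line
``replica frame x y z species`` (coordinates in nm).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ParseError
from .frames import NO_RESIDUE, BeadFrame, ProteinTrace

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}

_ROLE_ATOM = {"PC_head": "NC3", "PIP2_head": "P1", "glycerol": "GL1",
              "tail": "C1A"}
_ATOM_ROLE = {v: k for k, v in _ROLE_ATOM.items()}


def write_gro(frame: BeadFrame, path, title: str = "curvsense frame",
              sequence: str | None = None) -> Path:
    """Write a :class:`BeadFrame` as a fixed-width GRO file (nm units).

    ``sequence`` supplies one-letter codes for protein residue names; if
    absent, protein residues are written as ``GLY``.
    """
    path = Path(path)
    lines = [title, f"{len(frame):d}"]
    for i in range(len(frame)):
        sp = frame.species[i]
        resid = i % 99999 + 1
        if sp == "protein":
            ridx = int(frame.residue_index[i])
            resid = ridx % 99999
            code = (sequence[ridx - 1] if sequence and 1 <= ridx <= len(sequence)
                    else "G")
            resname, atom = AA3.get(code, "GLY"), "BB"
        elif sp == "wafer":
            resname, atom = "WAF", "Q0"
        else:
            resname = "POP2" if sp == "PIP2_head" else "DOPC"
            suffix = {"top": "T", "bottom": "B"}.get(frame.leaflet[i], "")
            atom = _ROLE_ATOM[sp] + suffix
        x, y, z = frame.positions[i]
        lines.append(f"{resid:5d}{resname:<5s}{atom:>5s}{(i % 99999) + 1:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}")
    lx, ly, lz = frame.box
    lines.append(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gro(path, time: int = 0) -> BeadFrame:
    """Read a GRO file (via MDAnalysis) back into a :class:`BeadFrame`."""
    import warnings

    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    pos = u.atoms.positions / 10.0          # Angstrom -> nm
    if u.dimensions is None:
        raise ParseError("GRO file is missing its box line", path=path)
    box = tuple(float(v) / 10.0 for v in u.dimensions[:3])

    n = len(u.atoms)
    species = np.empty(n, dtype=object)
    leaflet = np.full(n, "none", dtype=object)
    resid = np.full(n, NO_RESIDUE)
    for i, (resname, atom, rid) in enumerate(
            zip(u.atoms.resnames, u.atoms.names, u.atoms.resids)):
        if resname in AA1:
            species[i] = "protein"
            resid[i] = int(rid)
        elif resname == "WAF":
            species[i] = "wafer"
        else:
            role = atom[:-1] if atom[-1] in "TB" else atom
            if role not in _ATOM_ROLE:
                raise ParseError(f"unrecognised lipid atom name {atom!r}",
                                 path=path)
            species[i] = _ATOM_ROLE[role]
            if atom[-1] in "TB":
                leaflet[i] = "top" if atom[-1] == "T" else "bottom"
    return BeadFrame(positions=pos, species=species, leaflet=leaflet,
                     residue_index=resid, box=box, time=time)


TRACE_COLUMNS = ("replica", "frame", "x", "y", "z", "species")


def write_traces(traces, path, species: str = "protein") -> Path:
    """Write protein traces as tab-separated text with a header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        for tr in traces:
            for row in tr.frames:
                fh.write(f"{tr.replica_id}\t{int(row[0])}\t"
                         f"{row[1]:.6f}\t{row[2]:.6f}\t{row[3]:.6f}\t"
                         f"{species}\n")
    return path


def read_traces(path) -> list[ProteinTrace]:
    """Parse the tabular trace format; malformed lines are reported by number.

    This is the package's own invented format, so parsing is explicit: a
    wrong column count or non-numeric field raises :class:`ParseError`
    carrying the 1-based line number (and, for truncation, the last good
    line).
    """
    path = Path(path)
    rows: dict[int, list[list[float]]] = {}
    last_good = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError("empty trace file (missing header)", path=path, line=1)
        cols = header.rstrip("\n").split("\t")
        if tuple(cols) != TRACE_COLUMNS:
            raise ParseError(
                f"bad header {cols!r}, expected {list(TRACE_COLUMNS)}",
                path=path, line=1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(TRACE_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(TRACE_COLUMNS)} columns, "
                    f"got {len(parts)} (last good line: {last_good or 'header'})",
                    path=path, line=lineno)
            try:
                rep = int(parts[0])
                frame = float(parts[1])
                xyz = [float(v) for v in parts[2:5]]
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno}: non-numeric field ({exc}); "
                    f"last good line: {last_good or 'header'}",
                    path=path, line=lineno) from None
            rows.setdefault(rep, []).append([frame, *xyz])
            last_good = lineno
    if not rows:
        raise ParseError("trace file holds no data rows", path=path, line=1)
    return [ProteinTrace(replica_id=rep, frames=np.asarray(data))
            for rep, data in sorted(rows.items())]


def read_frames(path) -> list[BeadFrame]:
    """Read one GRO file or every ``*.gro`` in a directory, time-ordered."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.gro"))
        if not files:
            raise ParseError(f"no .gro files in directory {path}", path=path)
        return [read_gro(f, time=t) for t, f in enumerate(files)]
    return [read_gro(path)]
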
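"""Extended-XYZ dialect reader/writer.

Frame layout::

    <n_atoms>
    key=value comment line
    <species> <x> <y> <z> [<fx> <fy> <fz>]
    ...

Recognized comment-line keys (all optional except as noted):

* ``Lattice="ax ay az bx by bz cx cy cz"`` — lattice vectors as rows, Å
* ``pbc="T T F"`` — periodic flags
* ``field="ex ey ez"`` — applied uniform field, V Å⁻¹ (default zero)
* ``energy=<float>`` — reference energy, eV
* ``dipole="mx my mz"`` — reference dipole, e·Å
* ``polarizability="a11 ... a33"`` — 3×3 row-major, e·Å² V⁻¹

Per-atom lines have 4 columns, or 7 when forces (eV Å⁻¹) are present; the
column count must be uniform within a frame.  Absent targets come back as
``None`` on the :class:`~fieldpot.systems.ReferenceRecord`.  Writing uses
full float precision (repr round-trip) and a deterministic key order.
"""

from __future__ import annotations

import re
from typing import Iterator, List, Optional, Sequence

import numpy as np

from .systems import AtomicSystem, FormatError, ReferenceRecord

__all__ = ["read_frames", "write_frames", "parse_comment_line"]

_KEY_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def parse_comment_line(line: str) -> dict:
    out = {}
    for m in _KEY_RE.finditer(line):
        key = m.group(1)
        out[key] = m.group(2) if m.group(2) is not None else m.group(3)
    return out


def _floats(text: str, n: int, what: str, lineno: int) -> np.ndarray:
    try:
        vals = np.array([float(tok) for tok in text.split()], dtype=float)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric {what}: {exc}") from exc
    if vals.size != n:
        raise FormatError(f"line {lineno}: {what} needs {n} numbers, got {vals.size}")
    return vals


def read_frames(path: str) -> List[ReferenceRecord]:
    """Parse every frame of an extended-XYZ file into reference records."""
    records: List[ReferenceRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        lineno = i + 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"line {lineno}: expected atom count") from exc
        if i + 1 + n_atoms >= len(lines) + 1 and n_atoms > 0:
            pass
        if i + 1 >= len(lines):
            raise FormatError(f"line {lineno}: truncated frame header")
        header = parse_comment_line(lines[i + 1])
        cell = None
        pbc = np.zeros(3, dtype=bool)
        if "Lattice" in header:
            cell = _floats(header["Lattice"], 9, "Lattice", lineno + 1).reshape(3, 3)
        if "pbc" in header:
            toks = header["pbc"].split()
            if len(toks) != 3:
                raise FormatError(f"line {lineno + 1}: pbc needs three flags")
            pbc = np.array([t.upper() in ("T", "TRUE", "1") for t in toks])
        field = np.zeros(3)
        if "field" in header:
            field = _floats(header["field"], 3, "field", lineno + 1)
        energy = None
        if "energy" in header:
            try:
                energy = float(header["energy"])
            except ValueError as exc:
                raise FormatError(f"line {lineno + 1}: bad energy") from exc
        dipole = (_floats(header["dipole"], 3, "dipole", lineno + 1)
                  if "dipole" in header else None)
        polar = (_floats(header["polarizability"], 9, "polarizability",
                         lineno + 1).reshape(3, 3)
                 if "polarizability" in header else None)

        body = lines[i + 2:i + 2 + n_atoms]
        if len(body) < n_atoms:
            raise FormatError(f"line {lineno}: frame truncated "
                              f"({len(body)} of {n_atoms} atom lines)")
        species: List[str] = []
        positions = np.zeros((n_atoms, 3))
        forces: Optional[np.ndarray] = None
        ncols = None
        for a, raw in enumerate(body):
            toks = raw.split()
            if ncols is None:
                ncols = len(toks)
                if ncols not in (4, 7):
                    raise FormatError(
                        f"line {lineno + 2 + a}: expected 4 or 7 columns, got {ncols}")
                if ncols == 7:
                    forces = np.zeros((n_atoms, 3))
            elif len(toks) != ncols:
                raise FormatError(
                    f"line {lineno + 2 + a}: column count changed within frame")
            species.append(toks[0])
            positions[a] = _floats(" ".join(toks[1:4]), 3, "coordinate",
                                   lineno + 2 + a)
            if ncols == 7:
                forces[a] = _floats(" ".join(toks[4:7]), 3, "force",
                                    lineno + 2 + a)
        system = AtomicSystem(tuple(species), positions, cell=cell, pbc=pbc,
                              field=field)
        records.append(ReferenceRecord(system, energy=energy, forces=forces,
                                       dipole=dipole, polarizability=polar))
        i = i + 2 + n_atoms
    return records


def _fmt(values) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(values).ravel())


def write_frames(records: Sequence[ReferenceRecord], path: str) -> None:
    """Write records in the extended-XYZ dialect (full float precision)."""
    with open(path, "w") as fh:
        for rec in records:
            s = rec.system
            fh.write(f"{s.n_atoms}\n")
            parts = []
            if s.cell is not None:
                parts.append(f'Lattice="{_fmt(s.cell)}"')
            if s.pbc.any():
                parts.append('pbc="' + " ".join("T" if p else "F" for p in s.pbc) + '"')
            parts.append(f'field="{_fmt(s.field)}"')
            if rec.energy is not None:
                parts.append(f"energy={rec.energy!r}")
            if rec.dipole is not None:
                parts.append(f'dipole="{_fmt(rec.dipole)}"')
            if rec.polarizability is not None:
                parts.append(f'polarizability="{_fmt(rec.polarizability)}"')
            fh.write(" ".join(parts) + "\n")
            for a in range(s.n_atoms):
                row = f"{s.species[a]} " + _fmt(s.positions[a])
                if rec.forces is not None:
                    row += " " + _fmt(rec.forces[a])
                fh.write(row + "\n")
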
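"""Atomistic configurations and reference data containers.

An :class:`AtomicSystem` is one configuration: element labels, Cartesian
coordinates, an optional periodic cell, and the uniform external field
vector applied to it.  A :class:`ReferenceRecord` attaches whatever subset
of reference targets (energy, forces, dipole, polarizability) is known for
that configuration; absent targets are ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np


class FormatError(ValueError):
    """Malformed input data (file contents, singular cells, ...)."""


class ParameterError(ValueError):
    """Invalid parameter value passed to an operation."""


class ConsistencyError(ValueError):
    """Internally inconsistent inputs (e.g. missing coefficients)."""


@dataclass
class AtomicSystem:
    """One atomistic configuration with an applied uniform field.

    Parameters
    ----------
    species : sequence of str
        Element label per atom.
    positions : (n_atoms, 3) float array
        Cartesian coordinates in Å.
    cell : (3, 3) float array, optional
        Lattice vectors as rows, in Å. Required if any ``pbc`` flag is set.
    pbc : (3,) bool array
        Periodic flags per lattice direction.
    field : (3,) float array
        Applied uniform electric field in V Å⁻¹ (may be zero).
    """

    species: Tuple[str, ...]
    positions: np.ndarray
    cell: Optional[np.ndarray] = None
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))
    field: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.species = tuple(str(s) for s in self.species)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.species) != len(self.positions):
            raise ConsistencyError(
                f"{len(self.species)} species but {len(self.positions)} positions"
            )
        if not np.all(np.isfinite(self.positions)):
            raise FormatError("non-finite atomic positions")
        self.pbc = np.asarray(self.pbc, dtype=bool).reshape(3)
        self.field = np.asarray(self.field, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.field)):
            raise FormatError("non-finite field vector")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        if self.pbc.any():
            if self.cell is None:
                raise FormatError("periodic flags set but no cell given")
            if abs(np.linalg.det(self.cell)) < 1e-12:
                raise FormatError("singular lattice matrix")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def with_positions(self, positions) -> "AtomicSystem":
        return AtomicSystem(self.species, positions, self.cell, self.pbc, self.field)

    def with_field(self, field) -> "AtomicSystem":
        return AtomicSystem(self.species, self.positions, self.cell, self.pbc, field)


@dataclass
class ReferenceRecord:
    """Reference targets attached to a configuration; any may be absent.

    Units: energy eV, forces eV Å⁻¹, dipole e·Å, polarizability e·Å² V⁻¹.
    """

    system: AtomicSystem
    energy: Optional[float] = None
    forces: Optional[np.ndarray] = None
    dipole: Optional[np.ndarray] = None
    polarizability: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.energy is not None:
            self.energy = float(self.energy)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float).reshape(-1, 3)
            if len(self.forces) != self.system.n_atoms:
                raise ConsistencyError("forces/atom count mismatch")
        if self.dipole is not None:
            self.dipole = np.asarray(self.dipole, dtype=float).reshape(3)
        if self.polarizability is not None:
            self.polarizability = np.asarray(
                self.polarizability, dtype=float
            ).reshape(3, 3)


@dataclass
class ResponseSet:
    """Model (or oracle) output for one configuration."""

    energy: float
    forces: np.ndarray
    dipole: np.ndarray
    polarizability: np.ndarray

    def __post_init__(self):
        self.energy = float(self.energy)
        self.forces = np.asarray(self.forces, dtype=float).reshape(-1, 3)
        self.dipole = np.asarray(self.dipole, dtype=float).reshape(3)
        self.polarizability = np.asarray(self.polarizability, dtype=float).reshape(3, 3)


def unique_elements(systems: Sequence[AtomicSystem]) -> Tuple[str, ...]:
    seen = []
    for s in systems:
        for el in s.species:
            if el not in seen:
                seen.append(el)
    return tuple(sorted(seen))
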
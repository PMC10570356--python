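"""Analytic toy systems replacing ab initio reference data in tests.

Two toys are provided, both with closed-form energies that are *exactly
quadratic* in the applied field, so that dipole and polarizability targets
are exact and the identity μ(ε) = μ₀(r) + α(r)·ε holds identically:

* a polarizable bent (water-like) molecule — harmonic bonds and angle, a
  permanent body-frame dipole along the symmetry axis and a body-frame
  polarizability tensor, both rotated to the lab frame by the molecule's
  instantaneous orientation:

      E(r, ε) = E_intra(r) − μ(r)·ε − ½ ε·α(r)·ε

* a periodic box of non-interacting dipolar diatomics with fixed ±q point
  charges — the total dipole Σ_a q_a r_a grows with the number of molecules
  and, wrapped into the first polarization branch, emulates the
  multivalued dipole of periodic electronic-structure data while the
  forces stay smooth and single-valued.

Forces are exact gradients of the analytic energy (by automatic
differentiation of the closed form); the default label noise is zero so
parameter-recovery tests compare against exact targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence, Tuple

import autograd
import autograd.numpy as anp
import numpy as np

from .systems import AtomicSystem, ParameterError, ReferenceRecord, ResponseSet

__all__ = [
    "ToyModelParams",
    "OracleModel",
    "oracle_energy",
    "gen_h2o_toy",
    "gen_polarizable_molecule_dataset",
    "gen_periodic_training_set",
    "gen_periodic_multivalued_dataset",
    "wrap_dipole",
    "water_geometry",
    "random_rotation",
]


# ---------------------------------------------------------------------------
# toy parameters

#: Harmonic constants give OH-stretch/HOH-bend frequencies in a physical
#: range (~3500 / ~1600 cm⁻¹); the dipole is the familiar ~1.85 D of water
#: (0.385 e·Å) and the polarizability ~1.4 Å³ expressed in e·Å² V⁻¹.
#: These are package constants for a caricature of a polarizable molecule,
#: not claims about any particular electronic-structure method.
@dataclass
class ToyModelParams:
    kind: str = "water"                  # "water" | "diatomic"
    # intramolecular potential
    k_bond: float = 45.0                 # eV Å⁻²
    r0_bond: float = 0.96                # Å
    k_angle: float = 3.5                 # eV rad⁻²
    theta0_deg: float = 104.5
    # response constants (body frame)
    mu0: float = 0.385                   # e·Å along the symmetry axis
    alpha0_body: np.ndarray = dc_field(
        default_factory=lambda: np.diag([0.092, 0.098, 0.105])
    )                                    # e·Å² V⁻¹
    # sampling
    perturb_bond: float = 0.02           # Å, Gaussian σ of bond perturbations
    perturb_angle_deg: float = 2.0       # deg, Gaussian σ of angle perturbation
    field_range: Tuple[float, float] = (0.0, 0.4)  # V Å⁻¹
    noise: float = 0.0                   # Gaussian label noise (per unit target)
    # periodic diatomic toy
    n_mols: int = 8
    box: float = 10.0                    # Å, cubic box edge
    charge: float = 1.0                  # e on the two diatomic sites (±q)
    r0_diatomic: float = 2.0             # Å
    k_diatomic: float = 20.0             # eV Å⁻²
    species_pair: Tuple[str, str] = ("Na", "Cl")

    def __post_init__(self):
        self.alpha0_body = np.asarray(self.alpha0_body, dtype=float).reshape(3, 3)
        if not np.allclose(self.alpha0_body, self.alpha0_body.T):
            raise ParameterError("body polarizability must be symmetric")
        if np.any(np.linalg.eigvalsh(self.alpha0_body) < -1e-12):
            raise ParameterError("body polarizability must be PSD")
        if self.noise < 0:
            raise ParameterError("label noise must be ≥ 0")

    @property
    def theta0(self) -> float:
        return math.radians(self.theta0_deg)


# ---------------------------------------------------------------------------
# geometry helpers


def water_geometry(r1: float, r2: float, theta: float) -> np.ndarray:
    """O at the origin, H atoms in the yz plane, bisector along +z."""
    h = theta / 2.0
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, r1 * math.sin(h), r1 * math.cos(h)],
            [0.0, -r2 * math.sin(h), r2 * math.cos(h)],
        ]
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a normalized random quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _molecule_size(toy: ToyModelParams) -> int:
    return 3 if toy.kind == "water" else 2


# ---------------------------------------------------------------------------
# analytic oracle (autograd expressions in the positions)


def _water_frame(pos):
    """Body frame of one bent molecule: columns (x̂' out-of-plane, ŷ'
    in-plane ⟂ bisector, ẑ' bisector), as a function of positions."""
    b1 = pos[1] - pos[0]
    b2 = pos[2] - pos[0]
    zc = b1 + b2
    zc = zc / anp.sqrt(anp.sum(zc * zc))
    xc = anp.array(
        [
            b1[1] * b2[2] - b1[2] * b2[1],
            b1[2] * b2[0] - b1[0] * b2[2],
            b1[0] * b2[1] - b1[1] * b2[0],
        ]
    )
    xc = xc / anp.sqrt(anp.sum(xc * xc))
    yc = anp.array(
        [
            zc[1] * xc[2] - zc[2] * xc[1],
            zc[2] * xc[0] - zc[0] * xc[2],
            zc[0] * xc[1] - zc[1] * xc[0],
        ]
    )
    return anp.stack([xc, yc, zc], axis=1)


def _water_intra(pos, toy: ToyModelParams):
    b1 = pos[1] - pos[0]
    b2 = pos[2] - pos[0]
    r1 = anp.sqrt(anp.sum(b1 * b1))
    r2 = anp.sqrt(anp.sum(b2 * b2))
    cosang = anp.sum(b1 * b2) / (r1 * r2)
    theta = anp.arccos(anp.clip(cosang, -1.0 + 1e-12, 1.0 - 1e-12))
    return (
        0.5 * toy.k_bond * (r1 - toy.r0_bond) ** 2
        + 0.5 * toy.k_bond * (r2 - toy.r0_bond) ** 2
        + 0.5 * toy.k_angle * (theta - toy.theta0) ** 2
    )


def _oracle_terms(positions, toy: ToyModelParams):
    """(E_intra, μ(r), α(r)) as autograd expressions; positions may hold
    several molecules concatenated."""
    nm = _molecule_size(toy)
    n_mols = positions.shape[0] // nm
    e_intra = 0.0
    mu = anp.zeros(3)
    alpha = anp.zeros((3, 3))
    for m in range(n_mols):
        pos = positions[m * nm:(m + 1) * nm]
        if toy.kind == "water":
            e_intra = e_intra + _water_intra(pos, toy)
            R = _water_frame(pos)
            mu = mu + toy.mu0 * R[:, 2]
            alpha = alpha + anp.dot(anp.dot(R, toy.alpha0_body), R.T)
        elif toy.kind == "diatomic":
            b = pos[1] - pos[0]
            r = anp.sqrt(anp.sum(b * b))
            e_intra = e_intra + 0.5 * toy.k_diatomic * (r - toy.r0_diatomic) ** 2
            # point charges +q on atom 0, −q on atom 1
            mu = mu + toy.charge * (pos[0] - pos[1])
            alpha = alpha + toy.alpha0_body
        else:
            raise ParameterError(f"unknown toy kind {toy.kind!r}")
    return e_intra, mu, alpha


def _oracle_energy_expr(positions, field, toy: ToyModelParams):
    e_intra, mu, alpha = _oracle_terms(positions, toy)
    return e_intra - anp.dot(mu, field) - 0.5 * anp.dot(field, anp.dot(alpha, field))


def oracle_energy(system: AtomicSystem, toy: ToyModelParams) -> ResponseSet:
    """Exact analytic energy, forces, dipole and polarizability of the toy.

    The energy is quadratic in ε by construction, so μ = μ₀(r) + α(r)·ε and
    α is field-independent; forces are exact gradients (including the
    orientation dependence of μ and α).
    """
    pos = system.positions.astype(float)
    eps = system.field.astype(float)
    energy = float(_oracle_energy_expr(pos, eps, toy))
    forces = -np.asarray(
        autograd.grad(lambda p: _oracle_energy_expr(p, eps, toy))(pos)
    )
    _, mu, alpha = _oracle_terms(pos, toy)
    mu = np.asarray(mu)
    alpha = np.asarray(alpha)
    return ResponseSet(energy, forces, mu + alpha @ eps, alpha)


class OracleModel:
    """Adapter exposing the analytic toy through the model protocol, so the
    MD driver and finite-difference checks can run on exact physics."""

    def __init__(self, toy: ToyModelParams):
        self.toy = toy

    def energy(self, system: AtomicSystem) -> float:
        return oracle_energy(system, self.toy).energy

    def forces(self, system: AtomicSystem) -> np.ndarray:
        return oracle_energy(system, self.toy).forces

    def dipole(self, system: AtomicSystem) -> np.ndarray:
        return oracle_energy(system, self.toy).dipole

    def polarizability(self, system: AtomicSystem) -> np.ndarray:
        return oracle_energy(system, self.toy).polarizability


# ---------------------------------------------------------------------------
# dataset generators


def _record(system: AtomicSystem, toy: ToyModelParams, rng=None,
            with_forces=True) -> ReferenceRecord:
    res = oracle_energy(system, toy)
    energy, forces = res.energy, res.forces
    dipole, alpha = res.dipole, res.polarizability
    if toy.noise > 0 and rng is not None:
        energy = energy + rng.normal(0, toy.noise)
        forces = forces + rng.normal(0, toy.noise, forces.shape)
        dipole = dipole + rng.normal(0, toy.noise, 3)
        alpha = alpha + toy.noise * _sym_noise(rng)
    return ReferenceRecord(
        system, energy=energy, forces=forces if with_forces else None,
        dipole=dipole, polarizability=alpha,
    )


def _sym_noise(rng):
    a = rng.normal(size=(3, 3))
    return 0.5 * (a + a.T)


def gen_h2o_toy(toy: ToyModelParams, field=(0.1, 0.0, 0.0)) -> List[ReferenceRecord]:
    """Single equilibrium bent molecule lying in the yz plane with the field
    along x; targets are energy, dipole and polarizability (no forces)."""
    pos = water_geometry(toy.r0_bond, toy.r0_bond, toy.theta0)
    system = AtomicSystem(("O", "H", "H"), pos, field=np.asarray(field, dtype=float))
    return [_record(system, toy, with_forces=False)]


def gen_polarizable_molecule_dataset(
    toy: ToyModelParams, n: int, seed: int,
    field_range: Optional[Tuple[float, float]] = None,
) -> List[ReferenceRecord]:
    """n molecules with Gaussian-perturbed internal coordinates, uniformly
    random rigid orientations and fields of uniform magnitude over the toy's
    field range along uniformly random directions; full oracle targets."""
    if n < 1:
        raise ParameterError("n must be ≥ 1")
    rng = np.random.default_rng(seed)
    lo, hi = field_range if field_range is not None else toy.field_range
    records = []
    for _ in range(n):
        r1 = toy.r0_bond + rng.normal(0, toy.perturb_bond)
        r2 = toy.r0_bond + rng.normal(0, toy.perturb_bond)
        th = toy.theta0 + rng.normal(0, math.radians(toy.perturb_angle_deg))
        pos = water_geometry(r1, r2, th) @ random_rotation(rng).T
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        field = rng.uniform(lo, hi) * direction
        system = AtomicSystem(("O", "H", "H"), pos, field=field)
        records.append(_record(system, toy, rng))
    return records


# -- periodic dipolar toy ----------------------------------------------------


def _grid_centers(n_mols: int, box: float) -> np.ndarray:
    per_axis = math.ceil(n_mols ** (1 / 3))
    pts = []
    for i in range(per_axis):
        for j in range(per_axis):
            for k in range(per_axis):
                pts.append([(i + 0.5), (j + 0.5), (k + 0.5)])
    return np.array(pts[:n_mols]) * box / per_axis


def _diatomic_system(toy: ToyModelParams, centers, axes, bondlens, field) -> AtomicSystem:
    pos = []
    species = []
    for c, u, b in zip(centers, axes, bondlens):
        pos.append(c + 0.5 * b * u)
        pos.append(c - 0.5 * b * u)
        species.extend(toy.species_pair)
    cell = np.eye(3) * toy.box
    return AtomicSystem(
        tuple(species), np.array(pos), cell=cell,
        pbc=np.array([True, True, True]), field=np.asarray(field, dtype=float),
    )


def gen_periodic_training_set(
    toy: ToyModelParams, n: int, seed: int, field_max: float = 0.6,
) -> List[ReferenceRecord]:
    """Random configurations of the periodic dipolar toy with fields of
    uniform magnitude in [0, field_max] along random directions.

    Records carry exact forces and the *unwrapped* dipole; force-only
    training simply ignores the other targets.
    """
    rng = np.random.default_rng(seed)
    centers = _grid_centers(toy.n_mols, toy.box)
    records = []
    for _ in range(n):
        axes = rng.normal(size=(toy.n_mols, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        bondlens = toy.r0_diatomic + rng.normal(0, toy.perturb_bond, toy.n_mols)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        field = rng.uniform(0.0, field_max) * direction
        jitter = rng.normal(0, 0.1, (toy.n_mols, 3))
        system = _diatomic_system(toy, centers + jitter, axes, bondlens, field)
        records.append(_record(system, toy, rng))
    return records


def gen_periodic_multivalued_dataset(
    toy: ToyModelParams, n: int, seed: int, field=(0.0, 0.0, 0.0),
) -> Tuple[List[ReferenceRecord], np.ndarray]:
    """Smooth trajectory of the periodic toy whose *stored* dipole labels are
    wrapped into the first polarization branch.

    Molecules spin about fixed random axes at incommensurate rates and the
    bond lengths breathe slightly, so the true total dipole varies
    continuously and repeatedly crosses the branch boundaries.  Returns
    (records, true_dipoles): each record's ``dipole`` is the wrapped label
    (emulating branch jumps of periodic electronic-structure dipoles) while
    forces are exact and smooth; ``true_dipoles`` holds the continuous
    ground truth for comparison.
    """
    if toy.kind != "diatomic":
        toy = ToyModelParams(**{**toy.__dict__, "kind": "diatomic"})
    rng = np.random.default_rng(seed)
    centers = _grid_centers(toy.n_mols, toy.box)
    spin_axes = rng.normal(size=(toy.n_mols, 3))
    spin_axes /= np.linalg.norm(spin_axes, axis=1, keepdims=True)
    rates = rng.uniform(0.5, 1.5, toy.n_mols)          # rad per unit time
    phases = rng.uniform(0, 2 * np.pi, toy.n_mols)
    u0 = rng.normal(size=(toy.n_mols, 3))
    u0 /= np.linalg.norm(u0, axis=1, keepdims=True)
    cell = np.eye(3) * toy.box
    records: List[ReferenceRecord] = []
    truths = []
    times = np.linspace(0.0, 4 * np.pi, n)
    for t in times:
        axes = np.stack([
            rotation_about(spin_axes[m], rates[m] * t + phases[m]) @ u0[m]
            for m in range(toy.n_mols)
        ])
        bondlens = toy.r0_diatomic * (1.0 + 0.05 * np.sin(0.7 * t + phases))
        system = _diatomic_system(toy, centers, axes, bondlens, field)
        res = oracle_energy(system, toy)
        truths.append(res.dipole)
        records.append(
            ReferenceRecord(
                system, energy=None, forces=res.forces,
                dipole=wrap_dipole(res.dipole, cell),
                polarizability=None,
            )
        )
    return records, np.array(truths)


def gen_layered_dataset(
    toy: ToyModelParams, n: int, seed: int, field_max: float = 0.6,
    n_layers: int = 4, mols_per_layer: int = 4,
) -> List[ReferenceRecord]:
    """Pathological layered construction: molecules sit in evenly spaced
    layers perpendicular to x with all bond axes in the yz plane and the
    first/second layer duplicated as the third/fourth, so the x component
    of the total dipole is zero by construction at any field."""
    rng = np.random.default_rng(seed)
    cell = np.eye(3) * toy.box
    records = []
    per_side = math.ceil(math.sqrt(mols_per_layer))
    base_yz = (
        np.array([(i + 0.5, j + 0.5) for i in range(per_side) for j in range(per_side)])
        * toy.box / per_side
    )[:mols_per_layer]
    for _ in range(n):
        half = n_layers // 2
        layer_axes, layer_yz = [], []
        for _l in range(half):
            ang = rng.uniform(0, 2 * np.pi, mols_per_layer)
            axes = np.stack(
                [np.zeros_like(ang), np.cos(ang), np.sin(ang)], axis=1
            )  # in yz plane -> zero x dipole per molecule
            layer_axes.append(axes)
            layer_yz.append(base_yz + rng.uniform(-0.3, 0.3, (mols_per_layer, 2)))
        centers, axes_all = [], []
        for l in range(n_layers):
            src = l % half
            x = (l + 0.5) * toy.box / n_layers
            for m in range(mols_per_layer):
                centers.append([x, layer_yz[src][m][0], layer_yz[src][m][1]])
                axes_all.append(layer_axes[src][m])
        bondlens = np.full(n_layers * mols_per_layer, toy.r0_diatomic)
        field = np.array([rng.uniform(0.0, field_max), 0.0, 0.0])
        sysm = _diatomic_system(
            ToyModelParams(**{**toy.__dict__, "kind": "diatomic",
                              "n_mols": n_layers * mols_per_layer}),
            np.array(centers), np.stack(axes_all), bondlens, field,
        )
        records.append(_record(sysm, ToyModelParams(
            **{**toy.__dict__, "kind": "diatomic",
               "n_mols": n_layers * mols_per_layer})))
    return records


# ---------------------------------------------------------------------------
# polarization-branch wrapping


def wrap_dipole(mu, cell, window: str = "halfopen") -> np.ndarray:
    """Map a dipole into the canonical polarization branch.

    A periodic system's dipole is defined only modulo e·(lattice vectors);
    this adds the integer combination that brings each lattice coefficient
    into (−½, ½], emulating the multivalued quantity of the modern theory
    of polarization.  Idempotent by construction.
    """
    cell = np.asarray(cell, dtype=float).reshape(3, 3)
    if abs(np.linalg.det(cell)) < 1e-12:
        raise ParameterError("singular cell")
    if window != "halfopen":
        raise ParameterError(f"unknown wrapping rule {window!r}")
    mu = np.asarray(mu, dtype=float).reshape(3)
    frac = np.linalg.solve(cell.T, mu)        # μ = Σ_k frac_k a_k
    frac_wrapped = frac - np.ceil(frac - 0.5)  # into (−½, ½]
    return cell.T @ frac_wrapped
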
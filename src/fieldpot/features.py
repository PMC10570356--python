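"""Field-induced embedded-atom-density (FI-EAD) descriptors.

The descriptor of atom *i* is built from Gaussian-type orbitals (GTOs)
centered on its neighbors within a cutoff radius.  For each angular channel
(lx, ly, lz) with lx+ly+lz = l ≤ L and each contracted radial function n,
the neighbor contributions are summed linearly with per-atom orbital
coefficients c_j, the square of the sum is taken, and the squares are
accumulated over channels with multinomial weights l!/(lx! ly! lz!):

    ρ_i^n = Σ_l Σ_{lx+ly+lz=l} l!/(lx!ly!lz!)
            [ Σ_m d_m^n ( Σ_{j≠i} c_j φ^m_{lxlylz}(r_ij)
                          + c_ε φ_{lxlylz}(ε_i) ) ]²

The applied uniform field ε enters as a *pseudo-orbital*: the monomial
ε_x^lx ε_y^ly ε_z^lz with coefficient c_ε, added inside the square exactly
like one more neighbor (no radial factor, no cutoff; channels with l ≥ 1
only, since the l = 0 monomial is the field-independent constant 1).  The
result is
invariant under joint rotation of the system and the field, translation,
and permutation of like atoms, but changes when the field rotates alone —
which is precisely how the system–field interaction breaks rotational
symmetry physically.

Monomials are evaluated by repeated multiplication (never ``x**0``) so that
all derivatives, including with respect to a zero field vector, are finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import autograd.numpy as anp
import numpy as np
import scipy.sparse as sp
from autograd.extend import defvjp, primitive

from .systems import AtomicSystem, ConsistencyError, FormatError, ParameterError

__all__ = [
    "FeatureParams",
    "NeighborList",
    "build_neighbor_list",
    "cutoff_function",
    "primitive_gto",
    "field_orbital",
    "compute_ead",
    "compute_fiead",
    "fiead_oracle",
    "angular_channels",
]


# ---------------------------------------------------------------------------
# angular channels


@lru_cache(maxsize=None)
def angular_channels(L: int) -> Tuple[Tuple[Tuple[int, int, int], ...], Tuple[float, ...]]:
    """All Cartesian monomial exponents with lx+ly+lz ≤ L and their weights.

    Channels are enumerated in lexicographic (lx, ly, lz) order within each
    l; the weight is the multinomial coefficient l!/(lx! ly! lz!).
    """
    chans: List[Tuple[int, int, int]] = []
    weights: List[float] = []
    for l in range(L + 1):
        block = sorted(
            (lx, ly, l - lx - ly)
            for lx in range(l + 1)
            for ly in range(l + 1 - lx)
        )
        for lx, ly, lz in block:
            chans.append((lx, ly, lz))
            weights.append(
                math.factorial(l)
                / (math.factorial(lx) * math.factorial(ly) * math.factorial(lz))
            )
    return tuple(chans), tuple(weights)


def _monomials(vecs, channels):
    """Monomial v_x^lx v_y^ly v_z^lz per row of ``vecs`` and per channel.

    Built by repeated multiplication so autograd derivatives stay finite at
    zero components (the 0⁰ = 1 convention is the constant 1, not 0**0).
    """
    cols = []
    for lx, ly, lz in channels:
        m = anp.ones(vecs.shape[0])
        for _ in range(lx):
            m = m * vecs[:, 0]
        for _ in range(ly):
            m = m * vecs[:, 1]
        for _ in range(lz):
            m = m * vecs[:, 2]
        cols.append(m)
    return anp.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# scalar building blocks


def cutoff_function(r, r_c: float):
    """Squared-cosine switching function.

    f_c(r) = [½(cos(πr/r_c)+1)]² for r < r_c and 0 beyond; the value and its
    first and second derivatives vanish continuously at r = r_c, which keeps
    forces and polarizabilities smooth as neighbors cross the cutoff.
    """
    r = anp.asarray(r, dtype=float) if isinstance(r, np.ndarray) else r
    base = (0.5 * (anp.cos(anp.pi * r / r_c) + 1.0)) ** 2
    return anp.where(r < r_c, base, anp.zeros_like(base))


def primitive_gto(r_vec, lx: int, ly: int, lz: int, alpha_m: float, r_m: float, r_c: float):
    """Primitive Cartesian GTO: x^lx y^ly z^lz · exp(−α_m (r−r_m)²) · f_c(r)."""
    if min(lx, ly, lz) < 0:
        raise ParameterError("angular exponents must be non-negative")
    v = anp.reshape(anp.asarray(r_vec, dtype=float), (1, 3))
    r = anp.sqrt(anp.sum(v * v))
    mono = _monomials(v, ((lx, ly, lz),))[0, 0]
    return mono * anp.exp(-alpha_m * (r - r_m) ** 2) * cutoff_function(r, r_c)


def field_orbital(eps, lx: int, ly: int, lz: int):
    """Field pseudo-orbital ε_x^lx ε_y^ly ε_z^lz, with 0⁰ = 1.

    There is no radial factor and no cutoff: the field is uniform, so the
    pseudo-atom has no distance attached to it.
    """
    if min(lx, ly, lz) < 0:
        raise ParameterError("angular exponents must be non-negative")
    v = anp.reshape(anp.asarray(eps, dtype=float) if isinstance(eps, np.ndarray) else eps, (1, 3))
    return _monomials(v, ((lx, ly, lz),))[0, 0]


# ---------------------------------------------------------------------------
# hyperparameters


def _default_centers(r_c: float, n_rad: int) -> np.ndarray:
    return np.linspace(0.0, r_c, n_rad)


def _default_widths(r_c: float, n_rad: int) -> np.ndarray:
    spacing = r_c / max(n_rad - 1, 1)
    return np.full(n_rad, 1.0 / (2.0 * spacing ** 2))


@dataclass
class FeatureParams:
    """Descriptor hyperparameters.

    Parameters
    ----------
    r_c : float
        Cutoff radius in Å.
    L : int
        Maximum angular momentum of the Cartesian GTOs (0 = s only).
    n_rad : int
        Number of primitive radial Gaussians per angular channel.
    n_features : int
        Number of contracted density values per atom (rows of ``d``).
    alpha : (n_rad,) array
        Gaussian widths in Å⁻²; default from the center spacing.
    r_centers : (n_rad,) array
        Gaussian centers in Å, evenly spaced on [0, r_c] by default.
    d : (n_features, n_rad) array
        Initial contraction matrix; the model treats its own copy of this
        as learnable.
    """

    r_c: float
    L: int = 2
    n_rad: int = 8
    n_features: int = 12
    alpha: Optional[np.ndarray] = None
    r_centers: Optional[np.ndarray] = None
    d: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        if self.r_c <= 0:
            raise ParameterError("cutoff radius must be positive")
        if self.L < 0 or self.n_rad < 1 or self.n_features < 1:
            raise ParameterError("L ≥ 0, n_rad ≥ 1, n_features ≥ 1 required")
        if self.alpha is None:
            self.alpha = _default_widths(self.r_c, self.n_rad)
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(self.n_rad)
        if np.any(self.alpha <= 0):
            raise ParameterError("Gaussian widths must be positive")
        if self.r_centers is None:
            self.r_centers = _default_centers(self.r_c, self.n_rad)
        self.r_centers = np.asarray(self.r_centers, dtype=float).reshape(self.n_rad)
        if np.any(self.r_centers < 0) or np.any(self.r_centers > self.r_c):
            raise ParameterError("Gaussian centers must lie in [0, r_c]")
        if self.d is None:
            rng = np.random.default_rng(self.seed)
            self.d = rng.normal(0.0, 1.0, (self.n_features, self.n_rad)) / np.sqrt(
                self.n_rad
            )
        self.d = np.asarray(self.d, dtype=float).reshape(self.n_features, self.n_rad)

    @property
    def channels(self):
        return angular_channels(self.L)[0]

    @property
    def channel_weights(self) -> np.ndarray:
        return np.array(angular_channels(self.L)[1])


# ---------------------------------------------------------------------------
# neighbor list


@dataclass
class NeighborList:
    """Directed neighbor pairs within a cutoff.

    ``i_idx[p]`` is the center, ``j_idx[p]`` the neighbor, and
    ``shifts[p]`` the integer lattice-image triple of the neighbor; the
    displacement is r_j + shifts·cell − r_i.  Pairs are sorted by
    (i, j, shift) so the list is deterministic.
    """

    i_idx: np.ndarray
    j_idx: np.ndarray
    shifts: np.ndarray          # integer triples
    shift_vectors: np.ndarray   # Cartesian, Å
    distances: np.ndarray
    displacements: np.ndarray
    r_c: float

    @property
    def n_pairs(self) -> int:
        return len(self.i_idx)


def build_neighbor_list(system: AtomicSystem, r_c: float) -> NeighborList:
    """All directed pairs with distance ≤ r_c, via lattice-replica search.

    Replicas are enumerated generously enough that cutoffs exceeding half
    the box are handled; self-image pairs (i == j, nonzero shift) are
    included for periodic systems.
    """
    if r_c <= 0:
        raise ParameterError("cutoff radius must be positive")
    pos = system.positions
    n = system.n_atoms
    if system.pbc.any():
        cell = system.cell
        if abs(np.linalg.det(cell)) < 1e-12:
            raise FormatError("singular lattice matrix")
        # number of replicas per axis from the perpendicular cell heights
        inv = np.linalg.inv(cell)
        heights = 1.0 / np.linalg.norm(inv, axis=0)  # height along each axis
        nrep = np.where(system.pbc, np.ceil(r_c / heights).astype(int) + 1, 0)
    else:
        cell = np.eye(3)
        nrep = np.zeros(3, dtype=int)

    shift_range = [range(-nrep[k], nrep[k] + 1) for k in range(3)]
    entries = []
    for sx in shift_range[0]:
        for sy in shift_range[1]:
            for sz in shift_range[2]:
                svec = np.array([sx, sy, sz], dtype=float) @ cell
                # displacement r_j + s - r_i for all (i, j)
                disp = pos[None, :, :] + svec[None, None, :] - pos[:, None, :]
                dist = np.linalg.norm(disp, axis=2)
                mask = dist <= r_c
                if sx == 0 and sy == 0 and sz == 0:
                    np.fill_diagonal(mask, False)
                ii, jj = np.nonzero(mask)
                for a, b in zip(ii, jj):
                    entries.append((a, b, (sx, sy, sz), dist[a, b], disp[a, b]))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    if entries:
        i_idx = np.array([e[0] for e in entries], dtype=int)
        j_idx = np.array([e[1] for e in entries], dtype=int)
        shifts = np.array([e[2] for e in entries], dtype=int)
        dists = np.array([e[3] for e in entries], dtype=float)
        disps = np.array([e[4] for e in entries], dtype=float)
    else:
        i_idx = np.zeros(0, dtype=int)
        j_idx = np.zeros(0, dtype=int)
        shifts = np.zeros((0, 3), dtype=int)
        dists = np.zeros(0)
        disps = np.zeros((0, 3))
    shift_vectors = shifts @ cell if len(shifts) else np.zeros((0, 3))
    return NeighborList(i_idx, j_idx, shifts, shift_vectors, dists, disps, r_c)


# ---------------------------------------------------------------------------
# differentiable segment sum (constant sparse matrix is opaque to autograd)


@primitive
def _spmm(x, mat, mat_t):
    return mat @ x


defvjp(_spmm, lambda ans, x, mat, mat_t: lambda g: _spmm(g, mat_t, mat))


def segment_sum(x, mat: sp.csr_matrix, mat_t: sp.csr_matrix):
    """mat @ x with a constant CSR matrix; differentiable to any order."""
    return _spmm(x, mat, mat_t)


def scatter_matrix(indices: np.ndarray, n_out: int) -> Tuple[sp.csr_matrix, sp.csr_matrix]:
    n_in = len(indices)
    mat = sp.csr_matrix(
        (np.ones(n_in), (indices, np.arange(n_in))), shape=(n_out, n_in)
    )
    return mat, mat.T.tocsr()


def gather_matrix(indices: np.ndarray, n_in: int) -> Tuple[sp.csr_matrix, sp.csr_matrix]:
    """Row-selection matrix: (G @ x)[k] = x[indices[k]]."""
    n_out = len(indices)
    mat = sp.csr_matrix(
        (np.ones(n_out), (np.arange(n_out), indices)), shape=(n_out, n_in)
    )
    return mat, mat.T.tocsr()


# ---------------------------------------------------------------------------
# packed structure + core descriptor evaluation


@dataclass
class PackedStructure:
    """Static (non-differentiable) structure of a batch of configurations.

    Atoms of all configurations are concatenated; neighbor pairs carry
    global atom indices and fixed Cartesian image shifts, so the descriptor
    becomes a pure function of (positions, fields, coefficients).
    """

    n_atoms: int
    n_mols: int
    species: Tuple[str, ...]
    elem_idx: np.ndarray       # (N,) index into the element table
    mol_idx: np.ndarray        # (N,) owning configuration
    i_idx: np.ndarray          # (P,)
    j_idx: np.ndarray          # (P,)
    shift_vectors: np.ndarray  # (P, 3)
    pair_to_atom: sp.csr_matrix
    pair_to_atom_t: sp.csr_matrix
    atom_to_mol: sp.csr_matrix
    atom_to_mol_t: sp.csr_matrix
    sel_i: sp.csr_matrix       # (P, N) gather of center rows
    sel_i_t: sp.csr_matrix
    sel_j: sp.csr_matrix       # (P, N) gather of neighbor rows
    sel_j_t: sp.csr_matrix
    atom_from_mol: sp.csr_matrix    # (N, M) broadcast per-configuration rows
    atom_from_mol_t: sp.csr_matrix
    elem_masks: np.ndarray     # (N, n_elements) 0/1 one-hot of the element


def pack_structures(
    systems: Sequence[AtomicSystem],
    r_c: float,
    element_table: Sequence[str],
    neighbor_lists: Optional[Sequence[NeighborList]] = None,
) -> PackedStructure:
    elem_lookup = {el: k for k, el in enumerate(element_table)}
    species: List[str] = []
    elem_idx: List[int] = []
    mol_idx: List[int] = []
    ii: List[np.ndarray] = []
    jj: List[np.ndarray] = []
    sv: List[np.ndarray] = []
    offset = 0
    for m, sysm in enumerate(systems):
        for el in sysm.species:
            if el not in elem_lookup:
                raise ParameterError(f"element {el!r} not in model element table")
        nl = neighbor_lists[m] if neighbor_lists is not None else build_neighbor_list(sysm, r_c)
        species.extend(sysm.species)
        elem_idx.extend(elem_lookup[el] for el in sysm.species)
        mol_idx.extend([m] * sysm.n_atoms)
        ii.append(nl.i_idx + offset)
        jj.append(nl.j_idx + offset)
        sv.append(nl.shift_vectors)
        offset += sysm.n_atoms
    i_idx = np.concatenate(ii) if ii else np.zeros(0, dtype=int)
    j_idx = np.concatenate(jj) if jj else np.zeros(0, dtype=int)
    shift_vectors = np.concatenate(sv) if sv else np.zeros((0, 3))
    n_atoms = offset
    n_mols = len(systems)
    elem_idx = np.asarray(elem_idx, dtype=int)
    mol_idx_arr = np.asarray(mol_idx, dtype=int)
    p2a, p2a_t = scatter_matrix(i_idx, n_atoms)
    a2m, a2m_t = scatter_matrix(mol_idx_arr, n_mols)
    sel_i, sel_i_t = gather_matrix(i_idx, n_atoms)
    sel_j, sel_j_t = gather_matrix(j_idx, n_atoms)
    afm, afm_t = gather_matrix(mol_idx_arr, n_mols)
    masks = np.zeros((n_atoms, len(element_table)))
    masks[np.arange(n_atoms), elem_idx] = 1.0
    return PackedStructure(
        n_atoms=n_atoms,
        n_mols=n_mols,
        species=tuple(species),
        elem_idx=elem_idx,
        mol_idx=mol_idx_arr,
        i_idx=i_idx,
        j_idx=j_idx,
        shift_vectors=shift_vectors,
        pair_to_atom=p2a,
        pair_to_atom_t=p2a_t,
        atom_to_mol=a2m,
        atom_to_mol_t=a2m_t,
        sel_i=sel_i,
        sel_i_t=sel_i_t,
        sel_j=sel_j,
        sel_j_t=sel_j_t,
        atom_from_mol=afm,
        atom_from_mol_t=afm_t,
        elem_masks=masks,
    )


def fiead_packed(
    positions,
    fields,
    c_atoms,
    ceps_atoms,
    d,
    st: PackedStructure,
    feat: FeatureParams,
    include_field: bool = True,
    alpha=None,
    r_centers=None,
):
    """FI-EAD feature matrix (n_atoms, n_features) for a packed batch.

    Differentiable (autograd) in positions, fields, c_atoms, ceps_atoms, d
    and, when given, the radial widths/centers (which the model treats as
    learnable).  With ``include_field=False`` (or c_ε = 0) this is the
    plain EAD.
    """
    channels, weights = angular_channels(feat.L)
    weights = anp.array(weights)
    n_chan = len(channels)
    nf = feat.n_features
    if alpha is None:
        alpha = feat.alpha
    if r_centers is None:
        r_centers = feat.r_centers
    if st.i_idx.size:
        disp = (
            segment_sum(positions, st.sel_j, st.sel_j_t)
            + st.shift_vectors
            - segment_sum(positions, st.sel_i, st.sel_i_t)
        )
        r = anp.sqrt(anp.sum(disp * disp, axis=1))
        rad = anp.exp(-alpha[None, :] * (r[:, None] - r_centers[None, :]) ** 2)
        rad = rad * cutoff_function(r, feat.r_c)[:, None]
        radc = anp.dot(rad, d.T)                         # (P, nf)
        ang = _monomials(disp, channels)                  # (P, n_chan)
        c_pairs = segment_sum(
            anp.reshape(c_atoms, (st.n_atoms, 1)), st.sel_j, st.sel_j_t
        )[:, 0]
        contrib = c_pairs[:, None, None] * ang[:, :, None] * radc[:, None, :]
        flat = anp.reshape(contrib, (st.i_idx.size, n_chan * nf))
        s = anp.reshape(
            segment_sum(flat, st.pair_to_atom, st.pair_to_atom_t),
            (st.n_atoms, n_chan, nf),
        )
    else:
        s = anp.zeros((st.n_atoms, n_chan, nf))
    if include_field:
        eps_atoms = segment_sum(fields, st.atom_from_mol, st.atom_from_mol_t)
        ang_eps = _monomials(eps_atoms, channels)         # (N, n_chan)
        dsum = anp.sum(d, axis=1)                         # (nf,)
        # the l = 0 pseudo-orbital is the constant 1 for every field and so
        # carries no field information, only a configuration-dependent cross
        # term; restricting the field channel to l ≥ 1 makes the descriptor
        # reduce *exactly* to the field-free EAD at ε = 0 while keeping all
        # derivatives in ε smooth
        lmask = anp.array([1.0 if sum(ch) > 0 else 0.0 for ch in channels])
        s = s + (
            ceps_atoms[:, None, None]
            * (ang_eps * lmask[None, :])[:, :, None]
            * dsum[None, None, :]
        )
    return anp.sum(weights[None, :, None] * s * s, axis=1)


# ---------------------------------------------------------------------------
# public single-system wrappers


def _as_coeff_array(system: AtomicSystem, coeffs) -> np.ndarray:
    arr = np.asarray(coeffs, dtype=float).reshape(-1)
    if arr.size != system.n_atoms:
        raise ConsistencyError(
            f"need one orbital coefficient per atom ({system.n_atoms}), got {arr.size}"
        )
    return arr


def compute_ead(system: AtomicSystem, orbital_coeffs, params: FeatureParams, d=None):
    """Field-free EAD feature vectors ρ_i^n, shape (n_atoms, n_features)."""
    c = _as_coeff_array(system, orbital_coeffs)
    st = pack_structures([system], params.r_c, sorted(set(system.species)))
    dmat = params.d if d is None else np.asarray(d, dtype=float)
    return np.asarray(
        fiead_packed(
            system.positions, np.zeros((1, 3)), c, np.zeros(system.n_atoms),
            dmat, st, params, include_field=False,
        )
    )


def compute_fiead(system: AtomicSystem, orbital_coeffs, c_eps, params: FeatureParams, d=None):
    """Field-induced EAD features; the field of ``system`` enters as a
    pseudo-orbital with per-center coefficient(s) ``c_eps``."""
    c = _as_coeff_array(system, orbital_coeffs)
    ce = np.asarray(c_eps, dtype=float)
    if ce.ndim == 0:
        ce = np.full(system.n_atoms, float(ce))
    ce = _as_coeff_array(system, ce)
    st = pack_structures([system], params.r_c, sorted(set(system.species)))
    dmat = params.d if d is None else np.asarray(d, dtype=float)
    return np.asarray(
        fiead_packed(
            system.positions, system.field.reshape(1, 3), c, ce,
            dmat, st, params, include_field=True,
        )
    )


def fiead_oracle(system: AtomicSystem, orbital_coeffs, c_eps, params: FeatureParams, d=None):
    """Brute-force FI-EAD via the expanded square, for testing.

    Expanding the square over the combined neighbor set (real atoms plus the
    field pseudo-atom) and applying the multinomial theorem collapses the
    angular sum to dot products:

        ρ_i^n = Σ_l Σ_{q,q'} c_q c_q' (v_q · v_q')^l  g_q^n g_q'^n

    where for a real neighbor v = r_ij and g^n = Σ_m d_m^n f_m(r_ij), and for
    the pseudo-atom v = ε, c = c_ε, g^n = Σ_m d_m^n.  This includes the
    atom–field cross terms (with their factor 2) *and* the pure field–field
    self term c_ε² |ε|^{2l} that the expansion forces.
    """
    c = _as_coeff_array(system, orbital_coeffs)
    ce = np.asarray(c_eps, dtype=float)
    if ce.ndim == 0:
        ce = np.full(system.n_atoms, float(ce))
    ce = _as_coeff_array(system, ce)
    dmat = params.d if d is None else np.asarray(d, dtype=float)
    nl = build_neighbor_list(system, params.r_c)
    n, nf = system.n_atoms, params.n_features
    rho = np.zeros((n, nf))
    eps = system.field
    for i in range(n):
        sel = nl.i_idx == i
        vecs = [nl.displacements[p] for p in np.nonzero(sel)[0]]
        coefs = [c[j] for j in nl.j_idx[sel]]
        rads = []
        for v in vecs:
            r = np.linalg.norm(v)
            fm = np.exp(-params.alpha * (r - params.r_centers) ** 2) * float(
                cutoff_function(r, params.r_c)
            )
            rads.append(dmat @ fm)  # (nf,)
        # field pseudo-atom: contributes to l ≥ 1 terms only (the l = 0
        # pseudo-orbital is a field-independent constant; see fiead_packed)
        n_real = len(vecs)
        vecs.append(eps.copy())
        coefs.append(ce[i])
        rads.append(dmat.sum(axis=1))
        for q in range(len(vecs)):
            for qp in range(len(vecs)):
                dot = float(np.dot(vecs[q], vecs[qp]))
                l_start = 0 if (q < n_real and qp < n_real) else 1
                for l in range(l_start, params.L + 1):
                    rho[i] += coefs[q] * coefs[qp] * dot ** l * rads[q] * rads[qp]
    return rho
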
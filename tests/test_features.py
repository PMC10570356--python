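"""Descriptor layer: neighbor lists, GTOs, FI-EAD and its brute-force oracle."""

import autograd
import numpy as np
import pytest

from fieldpot import (
    AtomicSystem,
    FeatureParams,
    ParameterError,
    build_neighbor_list,
    compute_ead,
    compute_fiead,
    cutoff_function,
    field_orbital,
    fiead_oracle,
    primitive_gto,
)
from fieldpot.features import angular_channels, fiead_packed, pack_structures
from fieldpot.synthetic import random_rotation

from conftest import random_system


# ---------------------------------------------------------------------------
# neighbor list


def test_neighbor_list_pair_within_cutoff():
    sysm = AtomicSystem(("H", "H"), [[0, 0, 0], [0, 0, 2.0]])
    nl = build_neighbor_list(sysm, 3.0)
    assert nl.n_pairs == 2  # one directed pair each way
    assert np.allclose(nl.distances, 2.0)


def test_neighbor_list_beyond_cutoff_empty():
    sysm = AtomicSystem(("H", "H"), [[0, 0, 0], [0, 0, 3.5]])
    assert build_neighbor_list(sysm, 3.0).n_pairs == 0


def test_neighbor_list_periodic_self_images():
    """One atom in a 3 Å cubic box with r_c = 3.5 Å sees its six nearest
    self-images at 3.0 Å; counts match brute-force replica enumeration."""
    sysm = AtomicSystem(
        ("H",), [[0.5, 0.5, 0.5]], cell=np.eye(3) * 3.0,
        pbc=[True, True, True],
    )
    nl = build_neighbor_list(sysm, 3.5)
    # brute force over ±2 replicas
    expected = []
    for sx in range(-2, 3):
        for sy in range(-2, 3):
            for sz in range(-2, 3):
                if (sx, sy, sz) == (0, 0, 0):
                    continue
                d = 3.0 * np.linalg.norm([sx, sy, sz])
                if d <= 3.5:
                    expected.append(d)
    assert nl.n_pairs == len(expected) == 6
    assert np.allclose(np.sort(nl.distances), np.sort(expected))


def test_neighbor_list_cutoff_beyond_half_box():
    sysm = AtomicSystem(
        ("H",), [[0.0, 0.0, 0.0]], cell=np.eye(3) * 3.0, pbc=[True] * 3
    )
    nl = build_neighbor_list(sysm, 6.5)
    # brute force over ±3 replicas
    count = sum(
        1
        for sx in range(-3, 4) for sy in range(-3, 4) for sz in range(-3, 4)
        if (sx, sy, sz) != (0, 0, 0)
        and 3.0 * np.linalg.norm([sx, sy, sz]) <= 6.5
    )
    assert nl.n_pairs == count


def test_neighbor_list_invalid_inputs():
    sysm = AtomicSystem(("H", "H"), [[0, 0, 0], [0, 0, 1.0]])
    with pytest.raises(ParameterError):
        build_neighbor_list(sysm, -1.0)


# ---------------------------------------------------------------------------
# scalar orbital pieces


def test_cutoff_function_values():
    assert cutoff_function(3.0, 3.0) == 0.0
    assert cutoff_function(0.0, 3.0) == 1.0
    assert np.isclose(float(cutoff_function(1.5, 3.0)), 0.25)
    assert cutoff_function(5.0, 3.0) == 0.0


def test_cutoff_function_smooth_at_cutoff():
    """Value, first and second finite-difference derivatives all vanish
    continuously approaching r_c."""
    rc, h = 3.0, 1e-4
    r = np.array([rc - 2 * h, rc - h, rc, rc + h, rc + 2 * h])
    f = np.array([float(cutoff_function(x, rc)) for x in r])
    d1 = np.gradient(f, h)
    d2 = np.gradient(d1, h)
    assert abs(f[2]) < 1e-12
    assert np.all(np.abs(d1[1:]) < 1e-6)
    assert np.all(np.abs(d2[1:]) < 1e-2)


def test_primitive_gto_values():
    assert primitive_gto([0, 0, 4.0], 1, 0, 0, 1.0, 0.5, 3.0) == 0.0
    r_m = 1.2
    val = primitive_gto([0, 0, r_m], 0, 0, 0, 2.0, r_m, 3.0)
    assert np.isclose(float(val), float(cutoff_function(r_m, 3.0)))
    val = primitive_gto([1.0, 0, 0], 1, 0, 0, 1.0, 0.0, 3.0)
    assert np.isclose(float(val), np.exp(-1.0) * float(cutoff_function(1.0, 3.0)))


def test_field_orbital_values():
    assert float(field_orbital([0.1, 0, 0], 1, 0, 0)) == pytest.approx(0.1)
    assert float(field_orbital([0.3, -0.2, 0.9], 0, 0, 0)) == 1.0  # 0-degree
    assert float(field_orbital([0.0, 0.0, 0.0], 0, 0, 0)) == 1.0   # 0⁰ = 1
    assert float(field_orbital([0.1, 0, 0], 0, 1, 0)) == 0.0


def test_multinomial_weights():
    chans, weights = angular_channels(2)
    w = dict(zip(chans, weights))
    assert w[(1, 1, 0)] == 2.0   # 2!/(1!1!0!)
    assert w[(2, 0, 0)] == 1.0
    assert w[(0, 0, 0)] == 1.0
    assert len([c for c in chans if sum(c) == 2]) == 6


# ---------------------------------------------------------------------------
# EAD / FI-EAD


def test_isolated_atom_has_zero_features(feat_small):
    sysm = AtomicSystem(("O",), [[0.0, 0.0, 0.0]])
    rho = compute_ead(sysm, [1.0], feat_small)
    assert np.allclose(rho, 0.0)


def test_fiead_with_zero_field_coeff_equals_ead(feat_small, rng):
    sysm = random_system(rng)
    c = rng.normal(1, 0.2, sysm.n_atoms)
    assert np.allclose(
        compute_fiead(sysm, c, 0.0, feat_small),
        compute_ead(sysm, c, feat_small),
        atol=1e-14,
    )


def test_fiead_zero_field_reduces_to_ead(feat_small, rng):
    """At ε = 0 the descriptor reduces exactly to the field-free EAD even
    with a nonzero field coefficient."""
    sysm = random_system(rng, field_scale=0.0)
    c = rng.normal(1, 0.2, sysm.n_atoms)
    assert np.allclose(
        compute_fiead(sysm, c, 0.8, feat_small),
        compute_ead(sysm, c, feat_small),
        atol=1e-14,
    )


@pytest.mark.parametrize("L", [0, 1, 2])
def test_oracle_equivalence(L, rng):
    """FI-EAD equals the expanded-square sum over distances/angles including
    atom–field cross terms and the field–field self term."""
    feat = FeatureParams(r_c=3.0, L=L, n_rad=4, n_features=5, seed=L)
    for _ in range(10):
        sysm = random_system(rng)
        c = rng.normal(1, 0.3, sysm.n_atoms)
        ce = rng.normal(1, 0.3, sysm.n_atoms)
        a = compute_fiead(sysm, c, ce, feat)
        b = fiead_oracle(sysm, c, ce, feat)
        assert np.max(np.abs(a - b)) < 1e-10


def test_single_neighbor_field_cross_terms(feat_small):
    """l = 1 atom–field cross term ∝ r·ε: maximal for ε ∥ r, zero for ε ⟂ r."""
    pos = [[0, 0, 0], [0, 0, 1.0]]
    c = np.ones(2)
    par = AtomicSystem(("H", "H"), pos, field=[0, 0, 0.2])
    perp = AtomicSystem(("H", "H"), pos, field=[0.2, 0, 0])
    feat1 = FeatureParams(r_c=3.0, L=1, n_rad=4, n_features=5, seed=3)
    rho_par = fiead_oracle(par, c, 1.0, feat1)
    rho_perp = fiead_oracle(perp, c, 1.0, feat1)
    base = compute_ead(par, c, feat1)
    # both include the same self term c_ε²|ε|²; only the parallel case has a
    # cross term, so the two differ
    assert not np.allclose(rho_par, rho_perp)
    # perpendicular: feature minus self term equals the field-free value
    self_term = np.sum(feat1.d, axis=1) ** 2 * 0.2 ** 2
    assert np.allclose(rho_perp[0] - self_term, base[0], atol=1e-12)


# ---------------------------------------------------------------------------
# invariance properties


def test_rotation_invariance_of_features(feat_small, rng):
    for _ in range(25):
        sysm = random_system(rng)
        c = rng.normal(1, 0.2, sysm.n_atoms)
        ce = rng.normal(1, 0.2, sysm.n_atoms)
        R = random_rotation(rng)
        rot = AtomicSystem(sysm.species, sysm.positions @ R.T,
                           field=R @ sysm.field)
        a = compute_fiead(sysm, c, ce, feat_small)
        b = compute_fiead(rot, c, ce, feat_small)
        assert np.max(np.abs(a - b)) < 1e-10


def test_translation_invariance(feat_small, rng):
    sysm = random_system(rng)
    c = rng.normal(1, 0.2, sysm.n_atoms)
    shifted = sysm.with_positions(sysm.positions + np.array([5.0, -3.0, 1.0]))
    a = compute_fiead(sysm, c, 1.0, feat_small)
    b = compute_fiead(shifted, c, 1.0, feat_small)
    assert np.max(np.abs(a - b)) < 1e-12


def test_permutation_invariance(feat_small, rng):
    pos = rng.uniform(-1, 1, (4, 3))
    sysm = AtomicSystem(("H", "H", "O", "H"), pos, field=[0.1, 0.0, 0.2])
    perm = [1, 0, 2, 3]  # swap two H atoms
    swapped = AtomicSystem(("H", "H", "O", "H"), pos[perm], field=sysm.field)
    c = np.array([0.9, 0.9, 1.3, 0.9])  # per-element values
    a = compute_fiead(sysm, c, 1.0, feat_small)
    b = compute_fiead(swapped, c[perm], 1.0, feat_small)
    assert np.max(np.abs(a[perm] - b)) < 1e-12


def test_field_rotation_alone_changes_features(feat_small, rng):
    sysm = random_system(rng, n_atoms=3)
    c = np.ones(3)
    R = random_rotation(rng)
    rot_field = AtomicSystem(sysm.species, sysm.positions, field=R @ sysm.field)
    a = compute_fiead(sysm, c, 1.0, feat_small)
    b = compute_fiead(rot_field, c, 1.0, feat_small)
    assert np.max(np.abs(a - b)) > 1e-6


def test_feature_smoothness_as_neighbor_crosses_cutoff(feat_small):
    """Feature value and its first two finite-difference derivatives are
    continuous as a neighbor crosses r_c."""
    rc = feat_small.r_c
    h = 1e-4
    rs = rc + h * np.arange(-40, 41)
    vals = []
    for r in rs:
        sysm = AtomicSystem(("H", "H"), [[0, 0, 0], [0, 0, r]],
                            field=[0.1, 0.0, 0.0])
        vals.append(compute_fiead(sysm, np.ones(2), 1.0, feat_small)[0])
    vals = np.array(vals)
    scale = np.abs(vals).max() + 1e-12
    d1 = np.gradient(vals, h, axis=0) / scale
    d2 = np.gradient(d1, h, axis=0)
    mid = len(rs) // 2
    # no jump in value, slope, or curvature around the crossing (the constant
    # field self-term keeps the features nonzero there; the *neighbor*
    # contribution and its first two derivatives must vanish continuously)
    assert np.max(np.abs(vals[mid] - vals[-1])) / scale < 1e-8
    assert np.max(np.abs(d1[mid - 2:mid + 3])) < 1e-4
    assert np.max(np.abs(np.diff(d2[mid - 5:mid + 5], axis=0))) < 1.0


def test_field_gradient_finite_at_zero_field(feat_small, rng):
    """∂ρ/∂ε at ε = 0 exists and is finite (0⁰ = 1 monomial convention)."""
    sysm = random_system(rng, n_atoms=3, field_scale=0.0)
    st = pack_structures([sysm], feat_small.r_c, sorted(set(sysm.species)))
    c = np.ones(3)
    ce = np.ones(3)

    def total(fld):
        rho = fiead_packed(sysm.positions, fld.reshape(1, 3), c, ce,
                           feat_small.d, st, feat_small)
        import autograd.numpy as anp
        return anp.sum(rho)

    g = autograd.grad(total)(np.zeros(3))
    assert np.all(np.isfinite(g))
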
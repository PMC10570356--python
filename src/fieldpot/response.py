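"""Forces, dipole and polarizability as exact energy derivatives.

For a field-dependent potential E(r, ε) the response properties follow
from differentiation alone:

    F_i = −∂E/∂r_i          (forces, eV Å⁻¹)
    μ   = −∂E/∂ε            (dipole moment, e·Å)
    α   = −∂²E/∂ε∂ε         (polarizability, e·Å² V⁻¹, symmetric)

All derivatives are evaluated by automatic differentiation of the model
energy; the polarizability is obtained by differentiating the dipole once
more, never by nested finite differences.  Central finite differences are
provided only as an independent consistency check.
"""

from __future__ import annotations

from typing import Dict

import autograd
import autograd.numpy as anp
import numpy as np

from .model import FieldModel
from .systems import AtomicSystem, ResponseSet

__all__ = [
    "compute_forces",
    "compute_dipole",
    "compute_polarizability",
    "evaluate",
    "batch_responses",
    "finite_difference_check",
]


def _energy_fns(system: AtomicSystem, model: FieldModel):
    st = model.pack([system])
    pos0 = system.positions.astype(float)
    fld0 = system.field.reshape(1, 3).astype(float)

    def e_of_pos(pos):
        return model.energies_packed(model.params, pos, fld0, st)[0]

    def e_of_field(fld):
        return model.energies_packed(model.params, pos0, anp.reshape(fld, (1, 3)), st)[0]

    return e_of_pos, e_of_field, pos0, fld0


def compute_forces(system: AtomicSystem, model: FieldModel) -> np.ndarray:
    """F = −∂E/∂r, exact gradient via reverse-mode differentiation."""
    e_of_pos, _, pos0, _ = _energy_fns(system, model)
    return -np.asarray(autograd.grad(e_of_pos)(pos0))


def compute_dipole(system: AtomicSystem, model: FieldModel) -> np.ndarray:
    """μ = −∂E/∂ε, exact gradient with respect to the applied field."""
    _, e_of_field, _, fld0 = _energy_fns(system, model)
    return -np.asarray(autograd.grad(e_of_field)(fld0.reshape(3)))


def compute_polarizability(system: AtomicSystem, model: FieldModel) -> np.ndarray:
    """α = ∂μ/∂ε = −∂²E/∂ε∂ε; symmetric by equality of mixed partials."""
    _, e_of_field, _, fld0 = _energy_fns(system, model)
    mu_fn = autograd.grad(e_of_field)
    alpha = -np.asarray(autograd.jacobian(mu_fn)(fld0.reshape(3)))
    return 0.5 * (alpha + alpha.T)  # symmetrize away float round-off


def evaluate(system: AtomicSystem, model: FieldModel) -> ResponseSet:
    """Energy plus all response properties for one configuration."""
    e_of_pos, e_of_field, pos0, fld0 = _energy_fns(system, model)
    energy = float(e_of_pos(pos0))
    forces = -np.asarray(autograd.grad(e_of_pos)(pos0))
    mu_fn = autograd.grad(e_of_field)
    dipole = -np.asarray(mu_fn(fld0.reshape(3)))
    alpha = -np.asarray(autograd.jacobian(mu_fn)(fld0.reshape(3)))
    return ResponseSet(energy, forces, dipole, 0.5 * (alpha + alpha.T))


def batch_responses(model: FieldModel, params, positions, fields, st,
                    need_forces=True, need_dipole=True, need_alpha=True):
    """Batched differentiable responses for a packed structure.

    Returns (energies (M,), forces (N,3) or None, dipoles (M,3) or None,
    alphas (M,3,3) or None) as autograd-traceable expressions of ``params``
    — this is what the training loss differentiates through.
    """
    n_mols = st.n_mols
    ones = np.ones(n_mols)

    # one forward pass yields the energies; its vjp yields all forces
    vjp_pos, energies = autograd.make_vjp(
        lambda pos: model.energies_packed(params, pos, fields, st)
    )(positions)
    forces = -vjp_pos(ones) if need_forces else None

    dipoles = None
    alphas = None
    if need_dipole or need_alpha:
        def field_gradient(fld):
            vjp_f, _ = autograd.make_vjp(
                lambda f: model.energies_packed(params, positions, f, st)
            )(fld)
            return vjp_f(ones)                    # (M, 3) = ∂E_m/∂ε_m

        if need_alpha:
            # the total-energy Hessian in the fields is block diagonal per
            # configuration; three vjp calls over the traced field gradient
            # give every 3×3 block
            vjp_g, gval = autograd.make_vjp(field_gradient)(fields)
            dipoles = -gval
            rows = []
            for k in range(3):
                cot = np.zeros((n_mols, 3))
                cot[:, k] = 1.0
                rows.append(-vjp_g(cot))          # (M, 3) = −∂²E/∂ε_k∂ε
            alphas = anp.stack(rows, axis=1)
        else:
            dipoles = -field_gradient(fields)
    return energies, forces, dipoles, alphas


def finite_difference_check(system: AtomicSystem, model: FieldModel,
                            step_pos: float = 1e-4, step_field: float = 1e-4) -> Dict[str, float]:
    """Max relative error of analytic F, μ, α against central differences.

    The denominator is the larger of the analytic magnitude and a small
    floor, so near-zero components do not blow up the ratio.
    """
    if step_pos <= 0 or step_field <= 0:
        raise ValueError("finite-difference steps must be positive")
    res = evaluate(system, model)
    pos0 = system.positions.copy()
    fld0 = system.field.copy()

    fd_forces = np.zeros_like(pos0)
    for a in range(system.n_atoms):
        for k in range(3):
            dp = np.zeros_like(pos0)
            dp[a, k] = step_pos
            ep = model.energy(system.with_positions(pos0 + dp))
            em = model.energy(system.with_positions(pos0 - dp))
            fd_forces[a, k] = -(ep - em) / (2 * step_pos)

    fd_dipole = np.zeros(3)
    for k in range(3):
        df = np.zeros(3)
        df[k] = step_field
        ep = model.energy(system.with_field(fld0 + df))
        em = model.energy(system.with_field(fld0 - df))
        fd_dipole[k] = -(ep - em) / (2 * step_field)

    fd_alpha = np.zeros((3, 3))
    for k in range(3):
        df = np.zeros(3)
        df[k] = step_field
        mup = compute_dipole(system.with_field(fld0 + df), model)
        mum = compute_dipole(system.with_field(fld0 - df), model)
        fd_alpha[k] = (mup - mum) / (2 * step_field)
    fd_alpha = 0.5 * (fd_alpha + fd_alpha.T)

    def rel(a, b):
        scale = max(np.max(np.abs(a)), 1e-6)
        return float(np.max(np.abs(a - b)) / scale)

    return {
        "forces": rel(res.forces, fd_forces),
        "dipole": rel(res.dipole, fd_dipole),
        "polarizability": rel(res.polarizability, fd_alpha),
    }
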
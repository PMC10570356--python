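"""Reference study protocols on the synthetic toys.

These functions bundle the package's canonical end-to-end experiments:

* :func:`equivariance_study` — symmetry checks of energy, dipole and
  polarizability under rotations/translations/permutations.
* :func:`descriptor_oracle_study` — FI-EAD against its brute-force
  expanded-square oracle.
* :func:`derivative_consistency_study` — analytic responses against central
  finite differences.
* :func:`single_point_study` — fit one bent-molecule configuration (energy,
  dipole, polarizability at ε = 0.1 V Å⁻¹ along x) and probe rotations and
  field sweeps against the analytic oracle.
* :func:`parameter_recovery_study` — fit the quadratic-oracle dataset and
  report held-out RMSEs.
* :func:`force_only_study` — force-only training on the periodic dipolar
  toy with branch-corrupted dipole labels; dipole recovery up to a constant.
* :func:`spectroscopy_study` — TCF/IR/Raman sanity quantities.

Training stages use full-batch quasi-Newton fits (see
:func:`fieldpot.train.refine_lbfgs`): a warm-up on a subset followed by a
polish on the full training split.  Underdetermined single-configuration
fits are restarted over weight seeds until the training loss interpolates
(the restart decision uses training loss only).  Problem sizes default to
desk-scale settings that run on one CPU core in minutes.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional

import numpy as np

from .dynamics import (
    Trajectory,
    correct_dipole_branch,
    ir_spectrum,
    polarizability_decompose,
    raman_spectra,
)
from .features import FeatureParams, compute_fiead, fiead_oracle
from .model import FieldModel
from .response import batch_responses, evaluate, finite_difference_check
from .synthetic import (
    ToyModelParams,
    gen_h2o_toy,
    gen_periodic_multivalued_dataset,
    gen_periodic_training_set,
    gen_polarizable_molecule_dataset,
    oracle_energy,
    random_rotation,
    rotation_about,
)
from .systems import AtomicSystem
from .train import _PackedBatch, LossWeights, evaluate_rmse, loss, refine_lbfgs, split_dataset
from .units import C_CM_PER_FS


def _random_system(rng, n_lo=2, n_hi=6, field_scale=0.3) -> AtomicSystem:
    n = int(rng.integers(n_lo, n_hi + 1))
    return AtomicSystem(
        tuple(rng.choice(["H", "O"], n)),
        rng.uniform(-1.5, 1.5, (n, 3)),
        field=rng.normal(0.0, field_scale, 3),
    )


def _default_model(seed=0, elements=("H", "O"), r_c=3.0, hidden=32,
                   n_iterations=0) -> FieldModel:
    feat = FeatureParams(r_c=r_c, L=2, n_rad=8, n_features=12)
    return FieldModel(elements, feat, hidden=hidden,
                      n_iterations=n_iterations, seed=seed)


# ---------------------------------------------------------------------------
# 1. equivariance


def equivariance_study(seed: int = 0, n_cases: int = 100) -> Dict[str, float]:
    """Max symmetry violations of E/μ/α over random (system, field, op)
    triples, plus the field-only rotation sensitivity of the energy."""
    rng = np.random.default_rng(seed)
    model = _default_model(seed=seed + 1)
    model.calibrate([_random_system(rng) for _ in range(8)])
    worst = {"energy": 0.0, "dipole": 0.0, "polarizability": 0.0,
             "translation": 0.0, "permutation": 0.0}
    field_change = 0.0
    for _ in range(n_cases):
        sysm = _random_system(rng)
        res = evaluate(sysm, model)
        R = random_rotation(rng)
        rot = AtomicSystem(sysm.species, sysm.positions @ R.T, field=R @ sysm.field)
        res_r = evaluate(rot, model)
        worst["energy"] = max(worst["energy"], abs(res_r.energy - res.energy))
        worst["dipole"] = max(worst["dipole"],
                              float(np.max(np.abs(res_r.dipole - R @ res.dipole))))
        worst["polarizability"] = max(
            worst["polarizability"],
            float(np.max(np.abs(res_r.polarizability
                                - R @ res.polarizability @ R.T))))
        shift = sysm.with_positions(sysm.positions + rng.normal(0, 5, 3))
        worst["translation"] = max(worst["translation"],
                                   abs(model.energy(shift) - res.energy))
        perm = rng.permutation(sysm.n_atoms)
        permuted = AtomicSystem(tuple(np.array(sysm.species)[perm]),
                                sysm.positions[perm], field=sysm.field)
        worst["permutation"] = max(worst["permutation"],
                                   abs(model.energy(permuted) - res.energy))
        rot_field = AtomicSystem(sysm.species, sysm.positions,
                                 field=R @ sysm.field)
        # an isolated atom (or empty neighbor list) feels only |ε|, so the
        # demonstration that a lone field rotation changes the energy is the
        # maximum sensitivity over the sampled cases
        field_change = max(field_change,
                           abs(model.energy(rot_field) - res.energy))
    worst["max_field_rotation_energy_change"] = field_change
    worst["n_cases"] = n_cases
    return worst


# ---------------------------------------------------------------------------
# 2. descriptor oracle


def descriptor_oracle_study(seed: int = 0, n_systems: int = 50) -> Dict[str, float]:
    """Max |FI-EAD − brute-force oracle| over random small systems, L ≤ 2."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_systems):
        L = int(rng.integers(0, 3))
        feat = FeatureParams(r_c=3.0, L=L, n_rad=4, n_features=5, seed=k)
        sysm = _random_system(rng)
        c = rng.normal(1, 0.3, sysm.n_atoms)
        ce = rng.normal(1, 0.3, sysm.n_atoms)
        diff = np.max(np.abs(compute_fiead(sysm, c, ce, feat)
                             - fiead_oracle(sysm, c, ce, feat)))
        worst = max(worst, float(diff))
    return {"max_abs_diff": worst, "n_systems": n_systems}


# ---------------------------------------------------------------------------
# 3. derivative consistency


def derivative_consistency_study(seed: int = 0, n_systems: int = 20) -> Dict[str, float]:
    """Max relative error of analytic F/μ/α vs central finite differences."""
    rng = np.random.default_rng(seed)
    model = _default_model(seed=seed + 2)
    model.calibrate([_random_system(rng) for _ in range(8)])
    worst = {"forces": 0.0, "dipole": 0.0, "polarizability": 0.0}
    for _ in range(n_systems):
        report = finite_difference_check(_random_system(rng), model)
        for key in worst:
            worst[key] = max(worst[key], report[key])
    worst["n_systems"] = n_systems
    return worst


# ---------------------------------------------------------------------------
# 4. single-configuration fit (bent molecule in a field)


def train_single_point(toy: Optional[ToyModelParams] = None, seed: int = 0,
                       max_restarts: int = 8, maxiter: int = 600,
                       loss_tol: float = 1e-10):
    """Fit E/μ/α of the single yz-plane geometry at ε = (0.1, 0, 0).

    The 13 scalar targets heavily under-determine the network, and a
    fraction of weight initializations fail to interpolate; restarts over
    seeds are accepted or rejected on the *training* loss alone.
    """
    toy = toy or ToyModelParams()
    rec = gen_h2o_toy(toy)[0]
    weights = LossWeights(start=[0.1, 0, 10, 10], end=[0.1, 0, 10, 10])
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for attempt in range(max_restarts):
            model = _default_model(seed=seed + attempt)
            model.calibrate([rec.system])
            model = refine_lbfgs([rec], model, [0.1, 0, 10, 10], maxiter=maxiter)
            final = loss([rec], model, weights)
            if best is None or final < best[0]:
                best = (final, model, attempt)
            if final < loss_tol:
                break
    final, model, attempt = best
    return model, rec, {"train_loss": float(final), "restarts_used": attempt + 1}


def single_point_study(seed: int = 0, n_angles: int = 37,
                       n_fields: int = 41) -> Dict[str, float]:
    """Rotation and field-sweep extrapolation of the single-point fit.

    Returns the peak-to-peak energy variation for rotation about the field
    axis (symmetry-exact in the descriptor), and RMSEs against the analytic
    oracle for rotation about y and for ε_x ∈ [−0.2, 0.2] V Å⁻¹.
    """
    toy = ToyModelParams()
    model, rec, info = train_single_point(toy, seed=seed)
    sys0 = rec.system
    angles = np.linspace(0.0, 2 * np.pi, n_angles)

    def rotated(axis, a):
        return AtomicSystem(sys0.species,
                            sys0.positions @ rotation_about(axis, a).T,
                            field=sys0.field)

    e_x = np.array([model.energy(rotated([1, 0, 0], a)) for a in angles])
    e_y_model = np.array([model.energy(rotated([0, 1, 0], a)) for a in angles])
    e_y_oracle = np.array([oracle_energy(rotated([0, 1, 0], a), toy).energy
                           for a in angles])
    eps_x = np.linspace(-0.2, 0.2, n_fields)
    e_f_model = np.array([model.energy(sys0.with_field([e, 0, 0]))
                          for e in eps_x])
    e_f_oracle = np.array([oracle_energy(sys0.with_field([e, 0, 0]), toy).energy
                           for e in eps_x])
    return {
        "rotation_x_energy_variation": float(np.ptp(e_x)),
        "rotation_y_rmse": float(np.sqrt(np.mean((e_y_model - e_y_oracle) ** 2))),
        "field_sweep_rmse": float(np.sqrt(np.mean((e_f_model - e_f_oracle) ** 2))),
        **info,
    }


# ---------------------------------------------------------------------------
# 5. parameter recovery on the quadratic oracle


def parameter_recovery_study(seed: int = 0, n_records: int = 2000,
                             warmup_records: int = 400,
                             warmup_iters: int = 700,
                             full_iters: int = 200,
                             final_iters: int = 150) -> Dict[str, float]:
    """Train on the polarizable-molecule dataset (fields 0–0.4 V Å⁻¹) and
    report held-out RMSEs plus the toy's ‖α₀‖ for scale.

    Three quasi-Newton stages: a subset warm-up and a full-split pass with
    weights λ = (1, 0, 0.003, 0.014), then a polish with λ = (2, 0, 0.003,
    0.05) — the energy and polarizability weights raised together so both
    contribute comparably near their target accuracies (1 meV energy,
    0.01 e·Å dipole, 1 % of ‖α₀‖ polarizability).  The model uses a richer
    descriptor (24 contracted densities over 12 radial Gaussians) than the
    symmetry studies: the extra linear-readout capacity measurably lowers
    the spurious field curvature that dominates the polarizability error.
    """
    toy = ToyModelParams()
    records = gen_polarizable_molecule_dataset(toy, n_records, seed=seed + 11)
    train_recs, _val, test_recs = split_dataset(records, (0.8, 0.1, 0.1),
                                                seed=seed + 7)
    lam = [1.0, 0.0, 0.003, 0.014]
    feat = FeatureParams(r_c=3.0, L=2, n_rad=12, n_features=24)
    model = FieldModel(("H", "O"), feat, hidden=32, n_iterations=0, seed=seed)
    model.calibrate([r.system for r in train_recs[:warmup_records]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = refine_lbfgs(train_recs[:warmup_records], model, lam,
                             maxiter=warmup_iters)
        model = refine_lbfgs(train_recs, model, lam, maxiter=full_iters)
        model = refine_lbfgs(train_recs, model, [2.0, 0.0, 0.003, 0.05],
                             maxiter=final_iters)
    rmse = evaluate_rmse(test_recs, model)
    alpha_norm = float(np.linalg.norm(toy.alpha0_body))
    return {
        "energy_rmse": rmse["energy"]["rmse"],
        "dipole_rmse": rmse["dipole"]["rmse"],
        "polarizability_rmse": rmse["polarizability"]["rmse"],
        "alpha0_norm": alpha_norm,
        "n_train": len(train_recs),
        "n_test": len(test_recs),
        "model": model,
    }


# ---------------------------------------------------------------------------
# 6. force-only training on the periodic toy


def force_only_study(seed: int = 0, n_train: int = 200, n_traj: int = 120,
                     maxiter: int = 300,
                     traj_field=(0.2, 0.0, 0.0)) -> Dict[str, float]:
    """Force-only training on the periodic dipolar toy.

    The training dipole labels are multivalued (branch-wrapped) and are not
    used; the model learns the field-dependent surface from forces alone.
    Predicted dipoles along a smooth trajectory are compared with the
    continuous truth after removing one constant offset per component, and
    the greedy branch-correction utility is checked against the truth.
    """
    toy = ToyModelParams(kind="diatomic")
    train_recs = gen_periodic_training_set(toy, n_train, seed=seed + 3)
    traj_recs, truth = gen_periodic_multivalued_dataset(
        toy, n_traj, seed=seed + 4, field=traj_field)
    model = _default_model(seed=seed, elements=("Na", "Cl"), r_c=4.0)
    model.calibrate([r.system for r in train_recs[:50]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = refine_lbfgs(train_recs, model, [0, 1, 0, 0], maxiter=maxiter)
    force_rmse = evaluate_rmse(train_recs, model)["forces"]["rmse"]

    batch = _PackedBatch(traj_recs, model)
    _E, _F, mu, _al = batch_responses(
        model, model.params, batch.positions, batch.fields, batch.st,
        need_forces=False, need_alpha=False)
    mu = np.asarray(mu)
    pearson = []
    resid_frac = []
    for k in range(3):
        pearson.append(float(np.corrcoef(mu[:, k], truth[:, k])[0, 1]))
        offset = np.mean(mu[:, k] - truth[:, k])
        resid_frac.append(float(np.std(mu[:, k] - offset - truth[:, k])
                                / max(np.ptp(truth[:, k]), 1e-12)))

    # the branch-correction utility must invert the wrapping exactly (up to
    # one global quantum)
    cell = traj_recs[0].system.cell
    wrapped = np.array([r.dipole for r in traj_recs])
    fixed = correct_dipole_branch(wrapped, cell)
    k0 = np.linalg.solve(cell.T, fixed[0] - truth[0])
    branch_err = np.max(np.abs(fixed - truth - (cell.T @ np.round(k0))))
    return {
        "force_rmse": float(force_rmse),
        "dipole_pearson_min": float(min(pearson)),
        "dipole_resid_frac_max": float(max(resid_frac)),
        "branch_correction_max_err": float(branch_err),
        "branch_global_shift_integer": bool(np.allclose(k0, np.round(k0), atol=1e-9)),
        "n_train": n_train,
        "n_traj": n_traj,
        "model": model,
    }


# ---------------------------------------------------------------------------
# 7. spectroscopy sanity


def spectroscopy_study(seed: int = 0) -> Dict[str, float]:
    """IR peak recovery for a cosine dipole, iso/aniso Raman separation for
    a rigid rotor, and the iso part of a fixed tensor."""
    dt, n = 0.5, 6000
    t = np.arange(n) * dt
    freq = 1500.0                                  # cm⁻¹
    w = 2 * np.pi * freq * C_CM_PER_FS
    dip = np.stack([np.cos(w * t), 0 * t, 0 * t], axis=1)
    zeros = np.zeros((n, 1, 3))
    traj = Trajectory(dt=dt, positions=zeros, velocities=zeros.copy(),
                      energies=np.zeros(n), dipoles=dip)
    ir = ir_spectrum([traj])
    bin_width = float(ir.wavenumber[1] - ir.wavenumber[0])
    ir_peak = ir.peak()

    rot_freq = 300.0                               # cm⁻¹ rigid rotation
    wr = 2 * np.pi * rot_freq * C_CM_PER_FS
    body = np.diag([2.0, 1.0, 1.0])
    alphas = np.empty((n, 3, 3))
    for k, ang in enumerate(wr * t):
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        alphas[k] = R @ body @ R.T
    traj_rot = Trajectory(dt=dt, positions=zeros, velocities=zeros.copy(),
                          energies=np.zeros(n), dipoles=np.zeros((n, 3)),
                          polarizabilities=alphas)
    iso_spec, aniso_spec = raman_spectra([traj_rot])
    iso_val, _ = polarizability_decompose(np.diag([1.0, 2.0, 3.0]))
    return {
        "ir_peak_cm1": ir_peak,
        "ir_peak_error_bins": abs(ir_peak - freq) / bin_width,
        "raman_iso_to_aniso_ratio": float(iso_spec.intensity.max()
                                          / aniso_spec.intensity.max()),
        "raman_aniso_peak_cm1": aniso_spec.peak(),
        "raman_aniso_expected_cm1": 2 * rot_freq,
        "iso_of_diag123": float(iso_val),
    }
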
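"""Loss, schedules, splitting, metrics, and short end-to-end fits."""

import numpy as np
import pytest

from fieldpot import FieldModel, FeatureParams, ParameterError
from fieldpot.response import evaluate
from fieldpot.synthetic import gen_polarizable_molecule_dataset
from fieldpot.systems import ReferenceRecord
from fieldpot.train import (
    LossWeights,
    TrainingConfig,
    evaluate_rmse,
    loss,
    lr_schedule,
    schedule_weights,
    split_dataset,
    train,
)


# ---------------------------------------------------------------------------
# loss


def test_loss_zero_for_perfect_predictions(model_small, molecule_records):
    rec = molecule_records[0]
    res = evaluate(rec.system, model_small)
    perfect = ReferenceRecord(rec.system, energy=res.energy, forces=res.forces,
                              dipole=res.dipole, polarizability=res.polarizability)
    w = LossWeights()  # all four weights positive
    assert loss([perfect], model_small, w) < 1e-20


def test_loss_energy_only_formula(model_small, molecule_records):
    rec = molecule_records[0]
    e_pred = model_small.energy(rec.system)
    record = ReferenceRecord(rec.system, energy=e_pred + 0.1)
    w = LossWeights.constant(lam_V=0.1)
    assert loss([record], model_small, w) == pytest.approx(0.1 * 0.1 ** 2, rel=1e-9)


def test_loss_ignores_absent_and_zero_weight_targets(model_small, molecule_records):
    rec = molecule_records[0]
    e_pred = model_small.energy(rec.system)
    with_forces = ReferenceRecord(rec.system, energy=e_pred + 0.1,
                                  forces=np.ones((rec.system.n_atoms, 3)))
    without = ReferenceRecord(rec.system, energy=e_pred + 0.1)
    w = LossWeights.constant(lam_V=0.1)  # λ_F = 0: force errors must not count
    assert loss([with_forces], model_small, w) == pytest.approx(
        loss([without], model_small, w), rel=1e-12)


def test_loss_empty_batch_rejected(model_small):
    with pytest.raises(ParameterError):
        loss([], model_small, LossWeights())


def test_weights_validation():
    with pytest.raises(ParameterError):
        LossWeights(start=[-1, 0, 0, 0], end=[0, 0, 0, 0])
    with pytest.raises(ParameterError):
        LossWeights(start=[0, 0, 0, 0], end=[0, 0, 0, 0])


# ---------------------------------------------------------------------------
# schedules


def test_weight_schedule_endpoints_and_midpoint():
    w = LossWeights(start=[0.1, 50, 10, 10], end=[0.1, 0.5, 0.5, 0.5])
    assert np.allclose(schedule_weights(w, 0.0), [0.1, 50, 10, 10])
    assert np.allclose(schedule_weights(w, 1.0), [0.1, 0.5, 0.5, 0.5])
    assert schedule_weights(w, 0.5)[1] == pytest.approx(25.25)
    with pytest.raises(ParameterError):
        schedule_weights(w, 1.5)


def test_lr_plateau_halving():
    cfg = TrainingConfig(lr_init=0.002, lr_decay=0.5, patience=100, lr_stop=1e-5)
    # 100 non-improving epochs after the first one -> one decay
    history = [1.0] + [1.0] * 100
    lr, stop = lr_schedule(history, cfg)
    assert lr == pytest.approx(0.001)
    assert not stop


def test_lr_unchanged_while_improving():
    cfg = TrainingConfig(lr_init=0.002, patience=100)
    history = list(np.linspace(1.0, 0.1, 500))
    lr, stop = lr_schedule(history, cfg)
    assert lr == pytest.approx(0.002)
    assert not stop


def test_lr_stop_below_threshold():
    cfg = TrainingConfig(lr_init=1.5e-5, lr_decay=0.5, patience=2, lr_stop=1e-5)
    history = [1.0, 1.0, 1.0]
    lr, stop = lr_schedule(history, cfg)
    assert lr == pytest.approx(7.5e-6)
    assert stop


def test_lr_progress_is_log_scaled():
    cfg = TrainingConfig(lr_init=0.002, lr_stop=1e-5)
    assert cfg.lr_progress(0.002) == 0.0
    assert cfg.lr_progress(1e-5) == 1.0
    mid = np.sqrt(0.002 * 1e-5)
    assert cfg.lr_progress(mid) == pytest.approx(0.5, abs=1e-9)


# ---------------------------------------------------------------------------
# splitting


def test_split_sizes_and_reproducibility(molecule_records):
    records = molecule_records * 50  # 1200 entries
    tr, va, te = split_dataset(records, (0.8, 0.1, 0.1), seed=3)
    assert (len(tr), len(va), len(te)) == (960, 120, 120)
    tr2, va2, te2 = split_dataset(records, (0.8, 0.1, 0.1), seed=3)
    assert all(a is b for a, b in zip(tr, tr2))
    tr3, _, _ = split_dataset(records, (0.8, 0.1, 0.1), seed=4)
    assert any(a is not b for a, b in zip(tr, tr3))
    # disjoint and exhaustive
    ids = [id(r) for r in tr + va + te]
    assert sorted(ids) == sorted(id(r) for r in records)


# ---------------------------------------------------------------------------
# metrics


def test_rmse_closed_form(model_small, molecule_records):
    recs = molecule_records[:2]
    preds = [evaluate(r.system, model_small) for r in recs]
    offset = [0.05, -0.03]
    refs = [ReferenceRecord(r.system, energy=p.energy + o)
            for r, p, o in zip(recs, preds, offset)]
    out = evaluate_rmse(refs, model_small)
    assert out["energy"]["rmse"] == pytest.approx(
        np.sqrt((0.05 ** 2 + 0.03 ** 2) / 2), rel=1e-9)


def test_rmse_perfect_predictions(model_small, molecule_records):
    recs = molecule_records[:2]
    refs = []
    for r in recs:
        p = evaluate(r.system, model_small)
        refs.append(ReferenceRecord(r.system, energy=p.energy, dipole=p.dipole))
    out = evaluate_rmse(refs, model_small)
    assert out["energy"]["rmse"] == pytest.approx(0.0, abs=1e-12)
    assert out["dipole"]["pearson"] == pytest.approx(1.0)


def test_constant_offset_energy_rmse(model_small, molecule_records):
    recs = molecule_records[:4]
    refs = [ReferenceRecord(r.system, energy=evaluate(r.system, model_small).energy + 0.2)
            for r in recs]
    out = evaluate_rmse(refs, model_small)
    assert out["energy"]["rmse"] == pytest.approx(0.2, rel=1e-9)


# ---------------------------------------------------------------------------
# training loop behavior


def test_zero_epoch_budget_returns_model_unchanged(feat_small, molecule_records):
    model = FieldModel(("H", "O"), feat_small, hidden=8, seed=1)
    model.calibrate([r.system for r in molecule_records[:4]])
    before = model.energy(molecule_records[0].system)
    cfg = TrainingConfig(max_epochs=0, batch_size=4)
    model, log = train(molecule_records[:8], model, cfg,
                       LossWeights.constant(lam_V=1.0),
                       validation=molecule_records[8:10])
    assert model.energy(molecule_records[0].system) == before
    assert log == []


def test_training_on_self_generated_targets_is_already_converged(
        feat_small, molecule_records):
    """Self-consistency: targets produced by the model itself give ~zero loss
    and training does not degrade it."""
    model = FieldModel(("H", "O"), feat_small, hidden=8, seed=1)
    model.calibrate([r.system for r in molecule_records[:4]])
    refs = []
    for r in molecule_records[:8]:
        p = evaluate(r.system, model)
        refs.append(ReferenceRecord(r.system, energy=p.energy, dipole=p.dipole))
    w = LossWeights.constant(lam_V=1.0, lam_mu=1.0)
    assert loss(refs, model, w) < 1e-8
    cfg = TrainingConfig(max_epochs=3, batch_size=8, lr_init=1e-4, patience=10)
    model, _ = train(refs, model, cfg, w, validation=refs)
    assert loss(refs, model, w) < 1e-8


def test_gradient_descent_decreases_loss(toy, feat_small):
    records = gen_polarizable_molecule_dataset(toy, 16, seed=8)
    model = FieldModel(("H", "O"), feat_small, hidden=8, seed=5)
    w = LossWeights.constant(lam_V=1.0)
    cfg = TrainingConfig(max_epochs=12, batch_size=16, lr_init=0.005, patience=50)
    before = None
    model.calibrate([r.system for r in records])
    before = loss(records, model, w)
    model, log = train(records, model, cfg, w, validation=records)
    assert loss(records, model, w) < before
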
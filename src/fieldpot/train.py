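"""Multi-property training of the field-dependent potential.

The loss is a weighted sum of squared residuals of whatever reference
targets each record carries:

    L = ⟨ λ_V ΔE² + λ_F ‖ΔF‖² + λ_μ ‖Δμ‖² + λ_α ‖Δα‖² ⟩_batch

with the predicted forces, dipole and polarizability obtained from the
*same* energy by differentiation, so the response targets constrain the
field dependence of the energy surface rather than being fitted
independently.  Property weights decay linearly (in log-learning-rate
progress) between start and end values; the learning rate halves whenever
the validation loss has not improved for ``patience`` epochs and training
stops once it falls below the stop threshold.

Force-only training (all weights but λ_F zero) fits the field-dependent
surface through its position gradients alone; the energy then carries an
undetermined field-dependent constant, so only energy differences at fixed
field, forces, and dipoles up to a field-dependent additive constant are
determined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import autograd
import autograd.numpy as anp
import numpy as np
from autograd.misc import flatten

from .features import build_neighbor_list, pack_structures
from .model import FieldModel
from .response import batch_responses
from .systems import ParameterError, ReferenceRecord

__all__ = [
    "LossWeights",
    "TrainingConfig",
    "TrainingError",
    "loss",
    "schedule_weights",
    "lr_schedule",
    "split_dataset",
    "train",
    "evaluate_rmse",
]


class TrainingError(RuntimeError):
    """Training diverged; carries the last finite checkpoint."""

    def __init__(self, message, model=None):
        super().__init__(message)
        self.model = model


@dataclass
class LossWeights:
    """Property weights with linear start→end decay tied to the lr decay.

    Defaults are the full-property schedule (energy, forces, dipole,
    polarizability) = (0.1, 50, 10, 10) decaying to (0.1, 0.5, 0.5, 0.5).
    """

    start: np.ndarray = dc_field(
        default_factory=lambda: np.array([0.1, 50.0, 10.0, 10.0])
    )
    end: np.ndarray = dc_field(
        default_factory=lambda: np.array([0.1, 0.5, 0.5, 0.5])
    )

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float).reshape(4)
        self.end = np.asarray(self.end, dtype=float).reshape(4)
        if np.any(self.start < 0) or np.any(self.end < 0):
            raise ParameterError("loss weights must be non-negative")
        if not (self.start.max() > 0 or self.end.max() > 0):
            raise ParameterError("at least one loss weight must be positive")

    @classmethod
    def constant(cls, lam_V=0.0, lam_F=0.0, lam_mu=0.0, lam_alpha=0.0):
        w = np.array([lam_V, lam_F, lam_mu, lam_alpha], dtype=float)
        return cls(start=w, end=w)

    @classmethod
    def force_only(cls, lam_F: float = 1.0):
        return cls.constant(lam_F=lam_F)


def schedule_weights(weights: LossWeights, lr_progress: float) -> np.ndarray:
    """Element-wise linear interpolation between start and end weights.

    ``lr_progress`` runs from 0 (initial learning rate) to 1 (stop
    threshold), measured in log-learning-rate.
    """
    if not 0.0 <= lr_progress <= 1.0:
        raise ParameterError("lr_progress must lie in [0, 1]")
    return (1.0 - lr_progress) * weights.start + lr_progress * weights.end


@dataclass
class TrainingConfig:
    batch_size: int = 32
    lr_init: float = 0.002
    lr_decay: float = 0.5
    patience: int = 100
    lr_stop: float = 1e-5
    max_epochs: int = 10000
    split: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.lr_decay < 1.0:
            raise ParameterError("decay factor must lie in (0, 1)")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ParameterError("split ratios must sum to 1")
        if min(self.split) < 0:
            raise ParameterError("split ratios must be non-negative")

    def lr_progress(self, lr: float) -> float:
        span = math.log(self.lr_init / self.lr_stop)
        if span <= 0:
            return 1.0
        return float(np.clip(math.log(self.lr_init / max(lr, self.lr_stop)) / span, 0.0, 1.0))


def lr_schedule(val_history: Sequence[float], config: TrainingConfig) -> Tuple[float, bool]:
    """Plateau schedule: starting from ``lr_init``, halve (by ``lr_decay``)
    every time the validation loss fails to improve for ``patience``
    consecutive epochs; signal stop once lr < ``lr_stop``.

    Returns (learning rate after the recorded history, stop flag).
    """
    if len(val_history) == 0:
        raise ParameterError("empty validation history")
    lr = config.lr_init
    best = math.inf
    stale = 0
    for v in val_history:
        if v < best - 1e-12:
            best = v
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                lr *= config.lr_decay
                stale = 0
                if lr < config.lr_stop:
                    return lr, True
    return lr, False


def split_dataset(records: Sequence[ReferenceRecord], ratios, seed: int):
    """Disjoint, exhaustive, seed-reproducible (train, validation, test)."""
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ParameterError("split ratios must be positive")
    ratios = ratios / ratios.sum()
    n = len(records)
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    idx_train = perm[:n_train]
    idx_val = perm[n_train:n_train + n_val]
    idx_test = perm[n_train + n_val:]
    pick = lambda idx: [records[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)


# ---------------------------------------------------------------------------
# packed batches with target masks


class _PackedBatch:
    """Concatenated records with per-property presence masks."""

    def __init__(self, records: Sequence[ReferenceRecord], model: FieldModel,
                 nl_cache: Optional[dict] = None):
        systems = [r.system for r in records]
        nls = None
        if nl_cache is not None:
            nls = []
            for r in records:
                key = id(r)
                if key not in nl_cache:
                    nl_cache[key] = build_neighbor_list(r.system, model.feat.r_c)
                nls.append(nl_cache[key])
        self.st = pack_structures(systems, model.feat.r_c, model.elements,
                                  neighbor_lists=nls)
        self.positions = np.concatenate([s.positions for s in systems])
        self.fields = np.stack([s.field for s in systems])
        M = len(records)
        N = self.st.n_atoms
        self.e_ref = np.zeros(M)
        self.e_mask = np.zeros(M)
        self.f_ref = np.zeros((N, 3))
        self.f_mask = np.zeros(N)
        self.mu_ref = np.zeros((M, 3))
        self.mu_mask = np.zeros(M)
        self.al_ref = np.zeros((M, 3, 3))
        self.al_mask = np.zeros(M)
        offset = 0
        for m, r in enumerate(records):
            na = r.system.n_atoms
            if r.energy is not None:
                self.e_ref[m] = r.energy
                self.e_mask[m] = 1.0
            if r.forces is not None:
                self.f_ref[offset:offset + na] = r.forces
                self.f_mask[offset:offset + na] = 1.0
            if r.dipole is not None:
                self.mu_ref[m] = r.dipole
                self.mu_mask[m] = 1.0
            if r.polarizability is not None:
                self.al_ref[m] = r.polarizability
                self.al_mask[m] = 1.0
            offset += na
        self.n_records = M


def _batch_loss(model: FieldModel, params, batch: _PackedBatch, lam) -> float:
    need_f = lam[1] > 0 and batch.f_mask.any()
    need_mu = lam[2] > 0 and batch.mu_mask.any()
    need_al = lam[3] > 0 and batch.al_mask.any()
    need_e = lam[0] > 0 and batch.e_mask.any()
    E, F, mu, al = batch_responses(
        model, params, batch.positions, batch.fields, batch.st,
        need_forces=need_f, need_dipole=need_mu, need_alpha=need_al,
    )
    total = 0.0
    M = batch.n_records
    if need_e:
        total = total + lam[0] * anp.sum(batch.e_mask * (E - batch.e_ref) ** 2)
    if need_f:
        total = total + lam[1] * anp.sum(
            batch.f_mask * anp.sum((F - batch.f_ref) ** 2, axis=1)
        )
    if need_mu:
        total = total + lam[2] * anp.sum(
            batch.mu_mask * anp.sum((mu - batch.mu_ref) ** 2, axis=1)
        )
    if need_al:
        total = total + lam[3] * anp.sum(
            batch.al_mask * anp.sum((al - batch.al_ref) ** 2, axis=(1, 2))
        )
    return total / M


def loss(records: Sequence[ReferenceRecord], model: FieldModel,
         weights: LossWeights, lr_progress: float = 0.0) -> float:
    """Weighted multi-property loss of the current model on a batch.

    Absent targets contribute zero regardless of their weight.
    """
    if len(records) == 0:
        raise ParameterError("empty batch")
    lam = schedule_weights(weights, lr_progress)
    batch = _PackedBatch(records, model)
    return float(_batch_loss(model, model.params, batch, lam))


# ---------------------------------------------------------------------------
# optimizer


class _Adam:
    def __init__(self, x0: np.ndarray, b1=0.9, b2=0.999, eps=1e-8):
        self.m = np.zeros_like(x0)
        self.v = np.zeros_like(x0)
        self.t = 0
        self.b1, self.b2, self.eps = b1, b2, eps

    def step(self, x, g, lr):
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        return x - lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    records: Sequence[ReferenceRecord],
    model: FieldModel,
    config: TrainingConfig,
    weights: LossWeights,
    validation: Optional[Sequence[ReferenceRecord]] = None,
    log_every: int = 1,
) -> Tuple[FieldModel, List[Dict]]:
    """Fit the model in place; returns (model, per-epoch log).

    If ``validation`` is None the records are split internally with the
    config's ratios and seed (the test share is simply held out).  The
    model is calibrated (feature standardization) on the training split if
    it has not been calibrated yet.
    """
    if len(records) == 0:
        raise ParameterError("no training records")
    if validation is None and config.split[1] > 0 and len(records) >= 10:
        train_recs, val_recs, _ = split_dataset(records, config.split, config.seed)
    else:
        train_recs = list(records)
        val_recs = list(validation) if validation is not None else list(records)

    if np.allclose(model.feat_scale, 1.0) and np.allclose(model.feat_shift, 0.0):
        model.calibrate([r.system for r in train_recs])

    flat0, unflatten = flatten(model.params)
    x = flat0.copy()
    adam = _Adam(x)
    rng = np.random.default_rng(config.seed)
    nl_cache: dict = {}
    val_batch = _PackedBatch(val_recs, model, nl_cache)

    lr = config.lr_init
    best_val = math.inf
    stale = 0
    best_x = x.copy()
    log: List[Dict] = []
    n = len(train_recs)
    bs = min(config.batch_size, n)

    # pre-build fixed mini-batches once; reshuffling assignment each epoch
    for epoch in range(config.max_epochs):
        lam = schedule_weights(weights, config.lr_progress(lr))
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for k0 in range(0, n, bs):
            idx = order[k0:k0 + bs]
            batch = _PackedBatch([train_recs[i] for i in idx], model, nl_cache)

            def f(flat):
                return _batch_loss(model, unflatten(flat), batch, lam)

            val, g = autograd.value_and_grad(f)(x)
            if not np.isfinite(val) or not np.all(np.isfinite(g)):
                model.params = unflatten(best_x)
                raise TrainingError("loss diverged (non-finite)", model)
            x = adam.step(x, g, lr)
            epoch_loss += float(val)
            n_batches += 1

        vloss = float(_batch_loss(model, unflatten(x), val_batch, lam))
        if vloss < best_val - 1e-12:
            best_val = vloss
            stale = 0
            best_x = x.copy()
        else:
            stale += 1
        if epoch % log_every == 0 or stale >= config.patience:
            log.append({
                "epoch": epoch, "lr": lr,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_loss": vloss,
                "weights": lam.tolist(),
            })
        if stale >= config.patience:
            lr *= config.lr_decay
            stale = 0
            best_val = math.inf  # fresh plateau window at the new rate
            if lr < config.lr_stop:
                break

    model.params = unflatten(best_x if best_val < math.inf else x)
    # keep the most recent parameters if they beat the stored best
    final_val = float(_batch_loss(model, model.params, val_batch,
                                  schedule_weights(weights, config.lr_progress(lr))))
    last_val = float(_batch_loss(model, unflatten(x), val_batch,
                                 schedule_weights(weights, config.lr_progress(lr))))
    if last_val < final_val:
        model.params = unflatten(x)
    model.metadata = {
        "epochs_run": len(log), "final_lr": lr,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()},
        "weights_start": weights.start.tolist(),
        "weights_end": weights.end.tolist(),
    }
    return model, log


def refine_lbfgs(
    records: Sequence[ReferenceRecord],
    model: FieldModel,
    weights: np.ndarray,
    maxiter: int = 200,
    ridge: float = 0.0,
) -> FieldModel:
    """Full-batch quasi-Newton fit/polish with fixed property weights.

    On the smooth, noise-free synthetic targets the stochastic optimizer
    quickly reaches the right basin but then creeps; a limited-memory BFGS
    pass over the whole dataset with fixed property weights converges the
    last orders of magnitude far faster.  ``weights`` are the four fixed
    loss weights (energy, forces, dipole, polarizability).

    ``ridge`` adds an L2 penalty on the network weight matrices.  For
    heavily under-determined fits (e.g. a single training configuration)
    this selects a small-norm interpolant, which extrapolates far more
    smoothly in the field than an arbitrary exact fit.
    """
    from scipy.optimize import minimize

    batch = _PackedBatch(records, model)
    lam = np.asarray(weights, dtype=float).reshape(4)
    flat0, unflatten = flatten(model.params)

    def penalty(params):
        if ridge <= 0:
            return 0.0
        total = 0.0
        nets = [params["en"]] + list(params["coef"])
        for per_elem in nets:
            for net in per_elem:
                for key in ("W1", "W2", "W3"):
                    total = total + anp.sum(net[key] ** 2)
        return ridge * total

    def fun(x):
        val, g = autograd.value_and_grad(
            lambda xx: _batch_loss(model, unflatten(xx), batch, lam)
            + penalty(unflatten(xx))
        )(x)
        return float(val), np.asarray(g, dtype=float)

    res = minimize(fun, flat0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "maxcor": 30,
                            "ftol": 1e-16, "gtol": 1e-12})
    model.params = unflatten(res.x)
    return model


# ---------------------------------------------------------------------------
# metrics


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    if a.size < 2 or np.std(a) < 1e-300 or np.std(b) < 1e-300:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_rmse(records: Sequence[ReferenceRecord], model: FieldModel) -> Dict[str, Dict[str, float]]:
    """Per-property RMSE (over all scalar components) and Pearson r.

    Perfect predictions give RMSE 0; the correlation of a constant series is
    reported as NaN rather than being silently coerced to 1.
    """
    batch = _PackedBatch(records, model)
    E, F, mu, al = batch_responses(
        model, model.params, batch.positions, batch.fields, batch.st,
        need_forces=bool(batch.f_mask.any()),
        need_dipole=bool(batch.mu_mask.any()),
        need_alpha=bool(batch.al_mask.any()),
    )
    out: Dict[str, Dict[str, float]] = {}
    if batch.e_mask.any():
        sel = batch.e_mask > 0
        pred, ref = np.asarray(E)[sel], batch.e_ref[sel]
        out["energy"] = {"rmse": float(np.sqrt(np.mean((pred - ref) ** 2))),
                         "pearson": _pearson(pred, ref)}
    if batch.f_mask.any():
        sel = batch.f_mask > 0
        pred, ref = np.asarray(F)[sel], batch.f_ref[sel]
        out["forces"] = {"rmse": float(np.sqrt(np.mean((pred - ref) ** 2))),
                         "pearson": _pearson(pred, ref)}
    if batch.mu_mask.any():
        sel = batch.mu_mask > 0
        pred, ref = np.asarray(mu)[sel], batch.mu_ref[sel]
        out["dipole"] = {"rmse": float(np.sqrt(np.mean((pred - ref) ** 2))),
                         "pearson": _pearson(pred, ref)}
    if batch.al_mask.any():
        sel = batch.al_mask > 0
        pred, ref = np.asarray(al)[sel], batch.al_ref[sel]
        out["polarizability"] = {"rmse": float(np.sqrt(np.mean((pred - ref) ** 2))),
                                 "pearson": _pearson(pred, ref)}
    return out
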
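"""Atomistic energy model on FI-EAD features.

Each element gets its own small feed-forward network mapping an atom's
(standardized) descriptor vector to an atomic energy; the total energy is
the sum of atomic energies, which makes the model size-extensive and
strictly local within the cutoff.  Orbital coefficients are refined by
message passing: at every iteration each atom's c_j (and its field
coefficient c_ε) is re-predicted from the atom's current descriptor by an
element-specific coefficient network, after which the descriptors are
rebuilt.  Because the descriptor is invariant under joint rotation of the
system and the field at every stage, so is the energy.

All learnable state lives in a nested dict of numpy arrays (an autograd
pytree), so energies — and through them forces, dipoles and
polarizabilities — are differentiable to any order.
"""

from __future__ import annotations

import io
import json
import zipfile
from typing import Dict, List, Optional, Sequence, Tuple

import autograd.numpy as anp
import numpy as np

from .features import FeatureParams, PackedStructure, fiead_packed, pack_structures, segment_sum
from .systems import AtomicSystem, ParameterError

__all__ = [
    "FieldModel",
    "init_orbital_coefficients",
    "message_pass",
    "total_energy",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA = 1


def _sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def activation(x):
    """SiLU (x·σ(x)): smooth to all orders, required because the
    polarizability is a second derivative of the energy."""
    return x * _sigmoid(x)


ACTIVATIONS = {
    "silu": activation,
    "tanh": anp.tanh,
}


def _init_net(rng, n_elem, n_in, hidden, n_out, out_scale=1.0):
    def w(shape, fan_in):
        return rng.normal(0.0, 1.0 / np.sqrt(fan_in), shape)

    return [
        {
            "W1": w((n_in, hidden), n_in),
            "b1": np.zeros(hidden),
            "W2": w((hidden, hidden), hidden),
            "b2": np.zeros(hidden),
            "W3": w((hidden, n_out), hidden) * out_scale,
            "b3": np.zeros(n_out),
            # linear shortcut: the descriptor components are themselves
            # quadratic in the field, so a linear readout term represents
            # exact linear-response physics; the hidden layers only need to
            # model the remainder
            "Ws": np.zeros((n_in, n_out)),
        }
        for _ in range(n_elem)
    ]


def _mlp(net, x, act=activation):
    h1 = act(anp.dot(x, net["W1"]) + net["b1"])
    h2 = act(anp.dot(h1, net["W2"]) + net["b2"])
    return anp.dot(h2, net["W3"]) + net["b3"] + anp.dot(x, net["Ws"])


def _elem_mlp(nets, x, elem_masks, act=activation):
    """Per-element MLPs: every element's dense network runs over all atoms
    and the outputs are combined with the 0/1 element masks (cheap for the
    few element types a model carries, and avoids scatter-adds)."""
    out = None
    for e, net in enumerate(nets):
        y = _mlp(net, x, act) * elem_masks[:, e:e + 1]
        out = y if out is None else out + y
    return out


class FieldModel:
    """Field-dependent interatomic potential.

    Parameters
    ----------
    elements : sequence of str
        Element table; every configuration fed to the model must only
        contain these species.
    feat : FeatureParams
        Descriptor hyperparameters (cutoff, angular momenta, radial basis).
    hidden : int
        Width of the two hidden layers of every network.
    n_iterations : int
        Number of message-passing refinements of the orbital coefficients
        (0 = plain descriptor with per-element constant coefficients).
    static_field_coeff : bool
        If true, c_ε stays a per-element constant instead of being updated
        by the coefficient networks (ablation switch).
    seed : int
        Seed for weight initialization.
    """

    def __init__(
        self,
        elements: Sequence[str],
        feat: FeatureParams,
        hidden: int = 64,
        n_iterations: int = 0,
        static_field_coeff: bool = False,
        seed: int = 0,
        activation: str = "silu",
    ):
        self.elements: Tuple[str, ...] = tuple(elements)
        if len(set(self.elements)) != len(self.elements):
            raise ParameterError("duplicate element in element table")
        self.feat = feat
        self.hidden = int(hidden)
        self.n_iterations = int(n_iterations)
        if self.n_iterations < 0:
            raise ParameterError("n_iterations must be ≥ 0")
        self.static_field_coeff = bool(static_field_coeff)
        self.activation = str(activation)
        if self.activation not in ACTIVATIONS:
            raise ParameterError(f"unknown activation {activation!r}")
        self._act = ACTIVATIONS[self.activation]
        self.seed = int(seed)
        self.feat_shift = np.zeros(feat.n_features)
        self.feat_scale = np.ones(feat.n_features)
        self.params = self._init_params(np.random.default_rng(seed))
        self.metadata: Dict = {}

    # -- parameters ---------------------------------------------------------

    def _init_params(self, rng) -> Dict:
        nE = len(self.elements)
        nf, nm, h = self.feat.n_features, self.feat.n_rad, self.hidden
        params = {
            "d": self.feat.d.copy(),
            # radial widths/centers are refined during training, like the
            # contraction coefficients (widths through log for positivity)
            "log_alpha": np.log(self.feat.alpha.copy()),
            "r_centers": self.feat.r_centers.copy(),
            "c0": 1.0 + 0.1 * rng.normal(size=nE),
            # the field coefficient starts deliberately small: the field
            # channel then perturbs the descriptor gently and the learned
            # energy stays close to the linear-response (quadratic-in-ε)
            # regime, which markedly improves field extrapolation
            "ce0": 0.3 + 0.03 * rng.normal(size=nE),
            "eshift": np.zeros(nE),
            "en": _init_net(rng, nE, nf, h, 1, out_scale=0.1),
            "coef": [
                _init_net(rng, nE, nf, h, 2, out_scale=0.1)
                for _ in range(self.n_iterations)
            ],
        }
        return params

    def elem_index(self, species: Sequence[str]) -> np.ndarray:
        table = {el: k for k, el in enumerate(self.elements)}
        try:
            return np.array([table[s] for s in species], dtype=int)
        except KeyError as exc:
            raise ParameterError(f"unknown element {exc.args[0]!r}") from exc

    # -- packing ------------------------------------------------------------

    def pack(self, systems: Sequence[AtomicSystem]) -> PackedStructure:
        return pack_structures(systems, self.feat.r_c, self.elements)

    # -- forward ------------------------------------------------------------

    def features_packed(self, params, positions, fields, st: PackedStructure,
                        include_field: bool = True):
        """Final (standardized) per-atom feature matrix after message passing."""
        c0 = anp.dot(st.elem_masks, params["c0"])
        ce0 = anp.dot(st.elem_masks, params["ce0"])
        alpha = anp.exp(params["log_alpha"])
        r_centers = params["r_centers"]
        c, ce = c0, ce0
        rho = fiead_packed(positions, fields, c, ce, params["d"], st, self.feat,
                           include_field=include_field,
                           alpha=alpha, r_centers=r_centers)
        x = (rho - self.feat_shift) / self.feat_scale
        for t in range(self.n_iterations):
            upd = _elem_mlp(params["coef"][t], x, st.elem_masks, self._act)
            c = c0 + upd[:, 0]
            if not self.static_field_coeff:
                ce = ce0 + upd[:, 1]
            rho = fiead_packed(positions, fields, c, ce, params["d"], st, self.feat,
                               include_field=include_field,
                               alpha=alpha, r_centers=r_centers)
            x = (rho - self.feat_shift) / self.feat_scale
        return x

    def energies_packed(self, params, positions, fields, st: PackedStructure,
                        include_field: bool = True):
        """Total energy per configuration, shape (n_mols,)."""
        x = self.features_packed(params, positions, fields, st, include_field)
        e_atoms = _elem_mlp(params["en"], x, st.elem_masks, self._act)[:, 0]
        e_atoms = e_atoms + anp.dot(st.elem_masks, params["eshift"])
        return segment_sum(
            anp.reshape(e_atoms, (st.n_atoms, 1)), st.atom_to_mol, st.atom_to_mol_t
        )[:, 0]

    # -- calibration --------------------------------------------------------

    def calibrate(self, systems: Sequence[AtomicSystem]) -> None:
        """Freeze feature standardization from iteration-0 descriptors.

        Uses the current initial orbital coefficients over the given
        configurations; constant features get unit scale so a single
        training configuration is handled gracefully.
        """
        st = self.pack(systems)
        positions = np.concatenate([s.positions for s in systems])
        fields = np.stack([s.field for s in systems])
        c = self.params["c0"][st.elem_idx]
        ce = self.params["ce0"][st.elem_idx]
        rho = np.asarray(
            fiead_packed(
                positions, fields, c, ce, self.params["d"], st, self.feat,
                alpha=np.exp(self.params["log_alpha"]),
                r_centers=self.params["r_centers"],
            )
        )
        self.feat_shift = rho.mean(axis=0)
        scale = rho.std(axis=0)
        scale[scale < 1e-8] = 1.0
        self.feat_scale = scale

    # -- convenience single-system API ---------------------------------------

    def _single(self, system: AtomicSystem):
        st = self.pack([system])
        return st, system.positions.astype(float), system.field.reshape(1, 3)

    def energy(self, system: AtomicSystem) -> float:
        st, pos, fld = self._single(system)
        return float(self.energies_packed(self.params, pos, fld, st)[0])

    def atomic_features(self, system: AtomicSystem) -> np.ndarray:
        st, pos, fld = self._single(system)
        return np.asarray(self.features_packed(self.params, pos, fld, st))

    # derivative-based properties live in fieldpot.response; re-exported here
    # for the "model object" protocol used by the MD driver.
    def forces(self, system: AtomicSystem) -> np.ndarray:
        from .response import compute_forces
        return compute_forces(system, self)

    def dipole(self, system: AtomicSystem) -> np.ndarray:
        from .response import compute_dipole
        return compute_dipole(system, self)

    def polarizability(self, system: AtomicSystem) -> np.ndarray:
        from .response import compute_polarizability
        return compute_polarizability(system, self)


# ---------------------------------------------------------------------------
# functional wrappers over the model object


def init_orbital_coefficients(system: AtomicSystem, model: FieldModel) -> np.ndarray:
    """Iteration-0 orbital coefficients: the per-element learnable scalars."""
    return model.params["c0"][model.elem_index(system.species)].copy()


def message_pass(system: AtomicSystem, model: FieldModel) -> np.ndarray:
    """Final per-atom feature vectors after the model's message-passing
    iterations (standardized, as seen by the energy networks)."""
    return model.atomic_features(system)


def total_energy(system: AtomicSystem, model: FieldModel) -> float:
    """Total field-dependent potential energy E = Σ_i E_i in eV."""
    return model.energy(system)


# ---------------------------------------------------------------------------
# checkpointing


def _flatten_params(params, prefix=""):
    out = {}
    if isinstance(params, dict):
        for k, v in params.items():
            out.update(_flatten_params(v, f"{prefix}{k}/"))
    elif isinstance(params, list):
        for i, v in enumerate(params):
            out.update(_flatten_params(v, f"{prefix}{i}/"))
    else:
        out[prefix[:-1]] = np.asarray(params)
    return out


def save_checkpoint(model: FieldModel, path: str, metadata: Optional[Dict] = None) -> None:
    """Single-archive checkpoint: descriptor hyperparameters, weights,
    standardization and training metadata (versioned schema)."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "elements": list(model.elements),
        "hidden": model.hidden,
        "n_iterations": model.n_iterations,
        "static_field_coeff": model.static_field_coeff,
        "activation": model.activation,
        "seed": model.seed,
        "feat": {
            "r_c": model.feat.r_c,
            "L": model.feat.L,
            "n_rad": model.feat.n_rad,
            "n_features": model.feat.n_features,
        },
        "metadata": metadata or model.metadata,
    }
    arrays = _flatten_params(model.params, "params/")
    arrays["feat/alpha"] = model.feat.alpha
    arrays["feat/r_centers"] = model.feat.r_centers
    arrays["feat/d"] = model.feat.d
    arrays["feat_shift"] = model.feat_shift
    arrays["feat_scale"] = model.feat_scale
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        zf.writestr("arrays.npz", buf.getvalue())


def load_checkpoint(path: str) -> FieldModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ParameterError(f"unsupported checkpoint schema {meta.get('schema')}")
        with zf.open("arrays.npz") as fh:
            arrays = dict(np.load(io.BytesIO(fh.read())))
    feat = FeatureParams(
        r_c=meta["feat"]["r_c"],
        L=meta["feat"]["L"],
        n_rad=meta["feat"]["n_rad"],
        n_features=meta["feat"]["n_features"],
        alpha=arrays["feat/alpha"],
        r_centers=arrays["feat/r_centers"],
        d=arrays["feat/d"],
    )
    model = FieldModel(
        meta["elements"], feat, hidden=meta["hidden"],
        n_iterations=meta["n_iterations"],
        static_field_coeff=meta["static_field_coeff"], seed=meta["seed"],
        activation=meta.get("activation", "silu"),
    )
    model.feat_shift = arrays["feat_shift"]
    model.feat_scale = arrays["feat_scale"]
    model.metadata = meta.get("metadata", {})

    def rebuild(template, prefix):
        if isinstance(template, dict):
            return {k: rebuild(v, f"{prefix}{k}/") for k, v in template.items()}
        if isinstance(template, list):
            return [rebuild(v, f"{prefix}{i}/") for i, v in enumerate(template)]
        return arrays[prefix[:-1]]

    model.params = rebuild(model.params, "params/")
    return model
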
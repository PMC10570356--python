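"""YAML run configuration with strict schema validation.

A run config has up to five sections — ``featurization``, ``model``,
``training``, ``weights`` and ``md`` — plus global ``seed`` and
``verbosity``.  Unknown keys anywhere are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional

import numpy as np
import yaml

from .dynamics import MDProtocol
from .features import FeatureParams
from .systems import FormatError
from .train import LossWeights, TrainingConfig

__all__ = ["RunConfig", "load_config"]

_ALLOWED = {
    "featurization": {"r_c", "L", "n_rad", "n_features", "seed"},
    "model": {"elements", "hidden", "n_iterations", "static_field_coeff",
              "activation", "seed"},
    "training": {"batch_size", "lr_init", "lr_decay", "patience", "lr_stop",
                 "max_epochs", "split", "seed"},
    "weights": {"start", "end"},
    "md": {"temperature", "dt", "equil_steps", "n_segments", "segment_steps",
           "gap_steps", "collision_prob", "seed", "record_alpha"},
}
_TOP = set(_ALLOWED) | {"seed", "verbosity"}


def _check(section: str, mapping: Dict) -> Dict:
    unknown = set(mapping) - _ALLOWED[section]
    if unknown:
        raise FormatError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return mapping


@dataclass
class RunConfig:
    featurization: Dict = dc_field(default_factory=dict)
    model: Dict = dc_field(default_factory=dict)
    training: Dict = dc_field(default_factory=dict)
    weights: Dict = dc_field(default_factory=dict)
    md: Dict = dc_field(default_factory=dict)
    seed: int = 0
    verbosity: str = "info"

    def feature_params(self, r_c: Optional[float] = None) -> FeatureParams:
        kw = dict(self.featurization)
        if r_c is not None:
            kw.setdefault("r_c", r_c)
        if "r_c" not in kw:
            raise FormatError("featurization.r_c is required")
        return FeatureParams(**kw)

    def training_config(self) -> TrainingConfig:
        kw = dict(self.training)
        if "split" in kw:
            kw["split"] = tuple(kw["split"])
        kw.setdefault("seed", self.seed)
        return TrainingConfig(**kw)

    def loss_weights(self) -> LossWeights:
        if not self.weights:
            return LossWeights()
        kw = {}
        if "start" in self.weights:
            kw["start"] = np.asarray(self.weights["start"], dtype=float)
        if "end" in self.weights:
            kw["end"] = np.asarray(self.weights.get(
                "end", self.weights["start"]), dtype=float)
        elif "start" in self.weights:
            kw["end"] = kw["start"]
        return LossWeights(**kw)

    def md_protocol(self) -> MDProtocol:
        kw = dict(self.md)
        kw.setdefault("seed", self.seed)
        return MDProtocol(**kw)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("config root must be a mapping")
    unknown = set(raw) - _TOP
    if unknown:
        raise FormatError(f"unknown top-level key(s): {sorted(unknown)}")
    sections = {k: _check(k, raw.get(k, {}) or {}) for k in _ALLOWED}
    return RunConfig(
        **sections,
        seed=int(raw.get("seed", 0)),
        verbosity=str(raw.get("verbosity", "info")),
    )
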
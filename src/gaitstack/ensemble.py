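"""Probability-level fusion of independently trained SAE classifiers.

An ensemble holds N >= 2 stacked auto-encoders that were trained on the same
training split but differ in hidden-layer sizes and initialization seeds.
Their softmax outputs are combined per sample either by the sum rule
(elementwise mean of the probability vectors) or the product rule
(elementwise product, computed in log space and renormalized so the fused
vector is again a distribution; renormalization does not change the argmax).
The class decision is the argmax of the fused vector, ties broken toward the
lowest class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .autoencoder import TrainConfig
from .stacked import SAEModel, build_sae, model_from_dict, model_to_dict, predict_proba

__all__ = [
    "EnsembleModel",
    "fuse_sum",
    "fuse_product",
    "train_ensemble",
    "classify",
    "save_ensemble",
    "load_ensemble",
]

_FORMAT = "gaitstack-ensemble"
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class EnsembleModel:
    """N member SAEs plus the fusion rule used to combine their outputs."""

    members: tuple[SAEModel, ...]
    fusion: str = "sum"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("ensemble needs >= 2 members")
        if self.fusion not in ("sum", "product"):
            raise ValueError("fusion must be 'sum' or 'product'")
        first = self.members[0]
        for m in self.members[1:]:
            if m.head.class_names != first.head.class_names:
                raise ValueError("members must share class names")
            if m.input_size != first.input_size:
                raise ValueError("members must share input width")
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def class_names(self) -> tuple[str, ...]:
        return self.members[0].head.class_names

    @property
    def member_hidden_sizes(self) -> tuple[tuple[int, ...], ...]:
        return tuple(m.hidden_sizes for m in self.members)


def _stack(probas: list[np.ndarray] | tuple[np.ndarray, ...]) -> np.ndarray:
    if len(probas) == 0:
        raise ValueError("empty member list")
    arrs = [np.atleast_2d(np.asarray(p, float)) for p in probas]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("member probability shapes differ")
    return np.stack(arrs)  # members x rows x classes


def fuse_sum(probas) -> np.ndarray:
    """Sum rule: elementwise mean of the members' probability vectors."""
    fused = _stack(probas).mean(axis=0)
    return fused if np.asarray(probas[0]).ndim > 1 else fused[0]


def fuse_product(probas) -> np.ndarray:
    """Product rule: elementwise product, renormalized to sum to one.

    Computed in log space for numerical safety. A row whose product is zero
    in every class has no defined normalization and is rejected.
    """
    P = _stack(probas)
    with np.errstate(divide="ignore"):
        logs = np.log(P).sum(axis=0)  # rows x classes; -inf where any member is 0
    finite_max = logs.max(axis=1, keepdims=True)
    if np.any(~np.isfinite(finite_max)):
        raise ValueError("degenerate product: a zero in every class")
    raw = np.exp(logs - finite_max)
    fused = raw / raw.sum(axis=1, keepdims=True)
    return fused if np.asarray(probas[0]).ndim > 1 else fused[0]


def train_ensemble(
    features: np.ndarray,
    labels: np.ndarray,
    member_hidden_sizes: tuple[tuple[int, ...], ...],
    config: TrainConfig,
    fusion: str = "sum",
) -> EnsembleModel:
    """Train each member independently on the same data.

    Members differ only in their hidden sizes and in seeds derived
    deterministically from ``config.seed`` (member i uses seed + 7919*(i+1)),
    so the ensemble is reproducible from the single master config.
    """
    if len(member_hidden_sizes) < 2:
        raise ValueError("ensemble needs >= 2 members")
    labels = np.asarray(labels)
    class_names = tuple(sorted(set(labels.tolist())))
    members = []
    for i, hidden in enumerate(member_hidden_sizes):
        member_cfg = replace(config, seed=(config.seed + 7919 * (i + 1)) % 2**31)
        members.append(
            build_sae(features, labels, tuple(hidden), member_cfg, class_names)
        )
    return EnsembleModel(members=tuple(members), fusion=fusion)


def ensemble_proba(model: EnsembleModel, features: np.ndarray) -> np.ndarray:
    """Fused class probabilities for each feature row."""
    probas = [predict_proba(m, features) for m in model.members]
    return fuse_sum(probas) if model.fusion == "sum" else fuse_product(probas)


def classify(model, features: np.ndarray) -> np.ndarray:
    """Predicted gait labels: argmax of (fused) probabilities.

    Accepts either an :class:`EnsembleModel` or a single
    :class:`~gaitstack.stacked.SAEModel`. numpy's argmax returns the first
    maximum, so ties break toward the lowest class index.
    """
    if isinstance(model, EnsembleModel):
        proba = ensemble_proba(model, features)
        names = model.class_names
    else:
        proba = predict_proba(model, features)
        names = model.head.class_names
    idx = np.argmax(np.atleast_2d(proba), axis=1)
    return np.array([names[i] for i in idx], dtype=object)


def save_ensemble(model: EnsembleModel, path: str | Path) -> None:
    payload = {
        "format": _FORMAT,
        "version": _FORMAT_VERSION,
        "fusion": model.fusion,
        "members": [model_to_dict(m) for m in model.members],
    }
    Path(path).write_text(json.dumps(payload))


def load_ensemble(path: str | Path) -> EnsembleModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _FORMAT or payload.get("version") != _FORMAT_VERSION:
        raise ValueError("unrecognized ensemble file format/version")
    return EnsembleModel(
        members=tuple(model_from_dict(m) for m in payload["members"]),
        fusion=payload["fusion"],
    )
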
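"""Greedy layerwise stacking of auto-encoders with a softmax head.

A stacked auto-encoder (SAE) is built in two phases. Pretraining trains the
first auto-encoder on the feature table, then each subsequent auto-encoder
on the previous layer's hidden codes; the decoder halves are discarded and
only the encoders are kept. Fine-tuning then attaches a softmax
classification head (initialized at zero, so an untrained head outputs
uniform probabilities) and runs full-batch gradient descent on the softmax
cross-entropy through the head and all encoder layers jointly.

Gradients of the full stacked objective are analytic and finite-difference
checked in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .autoencoder import (
    AEParams,
    TrainConfig,
    TrainingDiverged,
    encode,
    train_ae,
)

__all__ = [
    "SoftmaxHead",
    "SAEModel",
    "softmax",
    "pretrain",
    "fine_tune",
    "fit_head",
    "predict_proba",
    "save_model",
    "load_model",
]

_FORMAT = "gaitstack-sae"
_FORMAT_VERSION = 1


def softmax(z: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax f_j = e^{z_j} / sum_k e^{z_k} (rows for 2-D)."""
    z = np.asarray(z, float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class SoftmaxHead:
    """Linear-softmax classifier on top of the last hidden layer."""

    weights: np.ndarray  # n_classes x hidden
    biases: np.ndarray  # n_classes
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, float)
        b = np.asarray(self.biases, float)
        if W.shape[0] != len(self.class_names) or b.shape != (W.shape[0],):
            raise ValueError("inconsistent head shapes")
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "biases", b)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @classmethod
    def zeros(cls, hidden_size: int, class_names: tuple[str, ...]) -> "SoftmaxHead":
        return cls(
            weights=np.zeros((len(class_names), hidden_size)),
            biases=np.zeros(len(class_names)),
            class_names=tuple(class_names),
        )


@dataclass(frozen=True)
class SAEModel:
    """Encoder stack + softmax head; only encoders are used at inference."""

    layers: tuple[AEParams, ...]
    head: SoftmaxHead
    config: TrainConfig
    fine_tuned: bool = False

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if nxt.input_size != prev.hidden_size:
                raise ValueError("layer sizes do not chain")
        if self.layers and self.head.weights.shape[1] != self.layers[-1].hidden_size:
            raise ValueError("head input must equal last hidden size")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return tuple(layer.hidden_size for layer in self.layers)

    @property
    def input_size(self) -> int:
        return self.layers[0].input_size

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Push rows through every encoder layer."""
        A = np.asarray(X, float)
        for layer in self.layers:
            A = encode(layer, A)
        return A


def pretrain(
    features: np.ndarray, hidden_sizes: tuple[int, ...], config: TrainConfig
) -> list[AEParams]:
    """Greedy layerwise pretraining.

    The first auto-encoder reconstructs the features; auto-encoder k
    reconstructs the hidden codes of auto-encoder k-1. Layer seeds are
    offset from ``config.seed`` so layers are independently initialized.
    """
    if not hidden_sizes:
        raise ValueError("hidden_sizes must be nonempty")
    X = np.atleast_2d(np.asarray(features, float))
    layers: list[AEParams] = []
    for i, h in enumerate(hidden_sizes):
        layer_cfg = replace(config, hidden_size=h, seed=(config.seed + 1009 * i) % 2**31)
        params, _ = train_ae(X, layer_cfg)
        layers.append(params)
        X = encode(params, X)
    return layers


def _one_hot(labels: np.ndarray, class_names: tuple[str, ...]) -> np.ndarray:
    index = {name: i for i, name in enumerate(class_names)}
    try:
        rows = [index[l] for l in labels]
    except KeyError as err:
        raise ValueError(f"unknown label {err.args[0]!r}") from None
    Y = np.zeros((len(rows), len(class_names)))
    Y[np.arange(len(rows)), rows] = 1.0
    return Y


def stack_objective_and_grads(
    layers: tuple[AEParams, ...],
    head: SoftmaxHead,
    X: np.ndarray,
    Y: np.ndarray,
    l2_weight: float,
    train_layers: bool = True,
) -> tuple[float, list[dict[str, np.ndarray]], dict[str, np.ndarray]]:
    """Softmax cross-entropy of the full stack, with analytic gradients.

    Returns (loss, per-layer grads for W/b, head grads). The L2 penalty
    covers the encoder weights and head weights (not biases). With
    ``train_layers=False`` the encoder gradients are still returned but the
    caller is expected to ignore them (frozen-encoder head training).
    """
    A = [np.atleast_2d(np.asarray(X, float))]
    for layer in layers:
        A.append(encode(layer, A[-1]))
    logits = A[-1] @ head.weights.T + head.biases
    P = softmax(logits)
    n = P.shape[0]
    ce = -float(np.sum(Y * np.log(np.clip(P, 1e-300, None)))) / n
    l2 = l2_weight * (
        sum(float((layer.W**2).sum()) for layer in layers)
        + float((head.weights**2).sum())
    )
    loss = ce + l2

    delta = (P - Y) / n  # n x classes
    g_head = {
        "weights": delta.T @ A[-1] + 2 * l2_weight * head.weights,
        "biases": delta.sum(axis=0),
    }
    layer_grads: list[dict[str, np.ndarray]] = [{} for _ in layers]
    if train_layers:
        G = delta @ head.weights  # gradient wrt last activation
        for k in range(len(layers) - 1, -1, -1):
            Zk = A[k + 1]
            d = G * Zk * (1 - Zk)
            layer_grads[k] = {
                "W": d.T @ A[k] + 2 * l2_weight * layers[k].W,
                "b": d.sum(axis=0),
            }
            G = d @ layers[k].W
    return loss, layer_grads, g_head


def _gd_head_and_layers(
    layers: tuple[AEParams, ...],
    head: SoftmaxHead,
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainConfig,
    train_layers: bool,
) -> tuple[tuple[AEParams, ...], SoftmaxHead, np.ndarray, str]:
    eta = config.learning_rate
    losses = []
    prev = np.inf
    stop = "max_epochs"
    for _ in range(config.max_epochs):
        loss, lg, hg = stack_objective_and_grads(
            layers, head, X, Y, config.l2_weight, train_layers
        )
        if not np.isfinite(loss):
            raise TrainingDiverged("training diverged (reduce learning rate)")
        losses.append(loss)
        if abs(prev - loss) < config.tolerance:
            stop = "converged"
            break
        prev = loss
        head = SoftmaxHead(
            weights=head.weights - eta * hg["weights"],
            biases=head.biases - eta * hg["biases"],
            class_names=head.class_names,
        )
        if train_layers:
            layers = tuple(
                replace(layer, W=layer.W - eta * g["W"], b=layer.b - eta * g["b"])
                for layer, g in zip(layers, lg)
            )
    return layers, head, np.array(losses), stop


def fine_tune(
    model: SAEModel, features: np.ndarray, labels: np.ndarray, config: TrainConfig
) -> SAEModel:
    """Supervised end-to-end fine-tuning of encoders + head.

    Minimizes softmax cross-entropy with one-hot targets by full-batch
    gradient descent; deterministic given the config. Requires at least two
    distinct classes in ``labels``.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two classes")
    X = np.atleast_2d(np.asarray(features, float))
    Y = _one_hot(labels, model.head.class_names)
    layers, head, _, _ = _gd_head_and_layers(
        model.layers, model.head, X, Y, config, train_layers=True
    )
    return SAEModel(layers=layers, head=head, config=config, fine_tuned=True)


def fit_head(
    model: SAEModel, features: np.ndarray, labels: np.ndarray, config: TrainConfig
) -> SAEModel:
    """Train only the softmax head on frozen encoder outputs."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two classes")
    X = np.atleast_2d(np.asarray(features, float))
    Y = _one_hot(labels, model.head.class_names)
    layers, head, _, _ = _gd_head_and_layers(
        model.layers, model.head, X, Y, config, train_layers=False
    )
    return SAEModel(layers=layers, head=head, config=config, fine_tuned=model.fine_tuned)


def build_sae(
    features: np.ndarray,
    labels: np.ndarray,
    hidden_sizes: tuple[int, ...],
    config: TrainConfig,
    class_names: tuple[str, ...] | None = None,
) -> SAEModel:
    """Pretrain, attach a zero head, and fine-tune — the full SAE recipe."""
    labels = np.asarray(labels)
    if class_names is None:
        class_names = tuple(sorted(set(labels.tolist())))
    layers = pretrain(features, hidden_sizes, config)
    model = SAEModel(
        layers=tuple(layers),
        head=SoftmaxHead.zeros(hidden_sizes[-1], class_names),
        config=config,
    )
    return fine_tune(model, features, labels, config)


def predict_proba(model: SAEModel, features: np.ndarray) -> np.ndarray:
    """Class probabilities, one row per feature row (rows sum to 1)."""
    X = np.atleast_2d(np.asarray(features, float))
    if X.shape[1] != model.input_size:
        raise ValueError(
            f"input size mismatch: expected {model.input_size}, got {X.shape[1]}"
        )
    Z = model.transform(X)
    return softmax(Z @ model.head.weights.T + model.head.biases)


# ---------------------------------------------------------------------------
# serialization: versioned JSON, bit-exact round trip (floats via repr)

def _arr(a: np.ndarray) -> list:
    return np.asarray(a, float).tolist()


def model_to_dict(model: SAEModel) -> dict:
    return {
        "format": _FORMAT,
        "version": _FORMAT_VERSION,
        "fine_tuned": model.fine_tuned,
        "config": {
            k: getattr(model.config, k)
            for k in (
                "hidden_size", "max_epochs", "learning_rate", "l2_weight",
                "sparsity_weight", "sparsity_target", "tolerance", "seed",
                "loss_kind",
            )
        },
        "layers": [
            {"W": _arr(l.W), "b": _arr(l.b), "W_dec": _arr(l.W_dec), "b_dec": _arr(l.b_dec)}
            for l in model.layers
        ],
        "head": {
            "weights": _arr(model.head.weights),
            "biases": _arr(model.head.biases),
            "class_names": list(model.head.class_names),
        },
    }


def model_from_dict(payload: dict) -> SAEModel:
    if payload.get("format") != _FORMAT or payload.get("version") != _FORMAT_VERSION:
        raise ValueError("unrecognized model file format/version")
    layers = tuple(
        AEParams(
            W=np.array(l["W"]), b=np.array(l["b"]),
            W_dec=np.array(l["W_dec"]), b_dec=np.array(l["b_dec"]),
        )
        for l in payload["layers"]
    )
    head = SoftmaxHead(
        weights=np.array(payload["head"]["weights"]),
        biases=np.array(payload["head"]["biases"]),
        class_names=tuple(payload["head"]["class_names"]),
    )
    return SAEModel(
        layers=layers,
        head=head,
        config=TrainConfig(**payload["config"]),
        fine_tuned=payload["fine_tuned"],
    )


def save_model(model: SAEModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)))


def load_model(path: str | Path) -> SAEModel:
    return model_from_dict(json.loads(Path(path).read_text()))
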
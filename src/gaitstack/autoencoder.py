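"""A from-scratch sigmoid auto-encoder trained by full-batch gradient descent.

The auto-encoder maps an input x through a sigmoid hidden layer,
z = sigma(W x + b), and reconstructs it with a sigmoid output layer,
x' = sigma(W_dec z + b_dec). Training minimizes a reconstruction objective
(squared error by default, cross-entropy available) plus an L2 weight
penalty and an optional KL sparsity penalty on mean hidden activations,
by plain full-batch gradient descent: new = old - eta * gradient.

All gradients are analytic and are validated against central finite
differences in the test suite — that check is the module's correctness gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AEParams",
    "TrainConfig",
    "TrainTrace",
    "TrainingDiverged",
    "sigmoid",
    "encode",
    "decode",
    "reconstruction_loss",
    "ae_objective",
    "gradients",
    "train_ae",
    "init_params",
]

_EPS = 1e-12  # clip for logs under cross-entropy


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class AEParams:
    """Encoder/decoder weights and biases of one auto-encoder.

    ``W`` is hidden x input (encoder), ``W_dec`` input x hidden (decoder);
    weights are untied. The activation is sigmoid on both layers.
    """

    W: np.ndarray
    b: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, float)
        b = np.asarray(self.b, float)
        W_dec = np.asarray(self.W_dec, float)
        b_dec = np.asarray(self.b_dec, float)
        h, d = W.shape
        if b.shape != (h,) or W_dec.shape != (d, h) or b_dec.shape != (d,):
            raise ValueError("inconsistent parameter shapes")
        for a in (W, b, W_dec, b_dec):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite parameters")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "W_dec", W_dec)
        object.__setattr__(self, "b_dec", b_dec)

    @property
    def input_size(self) -> int:
        return self.W.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for auto-encoder and fine-tuning runs.

    Defaults follow the study configuration: hidden size 40, at most 3000
    epochs, L2 weight penalty 1e-4. The learning rate is constant; sparsity
    is off unless ``sparsity_weight`` > 0.
    """

    hidden_size: int = 40
    max_epochs: int = 3000
    learning_rate: float = 0.1
    l2_weight: float = 1e-4
    sparsity_weight: float = 0.0
    sparsity_target: float = 0.05
    tolerance: float = 1e-9
    seed: int = 0
    loss_kind: str = "mse"

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.l2_weight < 0 or self.sparsity_weight < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.sparsity_weight > 0 and not 0 < self.sparsity_target < 1:
            raise ValueError("sparsity_target must lie in (0, 1)")
        if self.loss_kind not in ("mse", "cross_entropy"):
            raise ValueError("loss_kind must be 'mse' or 'cross_entropy'")


@dataclass(frozen=True)
class TrainTrace:
    """Per-epoch objective values and why training stopped."""

    losses: np.ndarray
    stop_reason: str  # "converged" | "max_epochs"

    def __post_init__(self) -> None:
        object.__setattr__(self, "losses", np.asarray(self.losses, float))


def init_params(input_size: int, hidden_size: int, seed: int) -> AEParams:
    """Glorot-style uniform(-r, r) initialization, r = sqrt(6/(fan_in+fan_out));
    biases start at zero."""
    rng = np.random.default_rng(seed)
    r = np.sqrt(6.0 / (input_size + hidden_size))
    return AEParams(
        W=rng.uniform(-r, r, size=(hidden_size, input_size)),
        b=np.zeros(hidden_size),
        W_dec=rng.uniform(-r, r, size=(input_size, hidden_size)),
        b_dec=np.zeros(input_size),
    )


def encode(params: AEParams, x: np.ndarray) -> np.ndarray:
    """Hidden code z = sigma(W x + b); accepts a vector or a batch (rows)."""
    x = np.asarray(x, float)
    if x.shape[-1] != params.input_size:
        raise ValueError(
            f"input size mismatch: expected {params.input_size}, got {x.shape[-1]}"
        )
    return sigmoid(x @ params.W.T + params.b)


def decode(params: AEParams, z: np.ndarray) -> np.ndarray:
    """Reconstruction x' = sigma(W_dec z + b_dec); vector or batch."""
    z = np.asarray(z, float)
    if z.shape[-1] != params.hidden_size:
        raise ValueError(
            f"hidden size mismatch: expected {params.hidden_size}, got {z.shape[-1]}"
        )
    return sigmoid(z @ params.W_dec.T + params.b_dec)


def reconstruction_loss(x: np.ndarray, x_prime: np.ndarray, kind: str = "mse") -> float:
    """Per-sample reconstruction loss.

    ``mse``: squared Euclidean distance ||x - x'||^2 (summed over components).
    ``cross_entropy``: -sum_k [x_k log x'_k + (1-x_k) log(1-x'_k)], with x'
    clipped to [1e-12, 1 - 1e-12] before the logs.
    For batches (2-D inputs) the mean over rows is returned.
    """
    x = np.asarray(x, float)
    xp = np.asarray(x_prime, float)
    if x.shape != xp.shape:
        raise ValueError("x and x' must have the same shape")
    if kind == "mse":
        per = ((x - xp) ** 2).sum(axis=-1)
    elif kind == "cross_entropy":
        xp = np.clip(xp, _EPS, 1 - _EPS)
        per = -(x * np.log(xp) + (1 - x) * np.log(1 - xp)).sum(axis=-1)
    else:
        raise ValueError("kind must be 'mse' or 'cross_entropy'")
    return float(per if per.ndim == 0 else per.mean())


def _kl_sparsity(rho_hat: np.ndarray, rho: float) -> float:
    rho_hat = np.clip(rho_hat, _EPS, 1 - _EPS)
    return float(
        (rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))).sum()
    )


def ae_objective(params: AEParams, batch: np.ndarray, config: TrainConfig) -> float:
    """Full training objective: mean reconstruction loss + L2 + KL sparsity."""
    batch = np.atleast_2d(np.asarray(batch, float))
    z = encode(params, batch)
    xp = decode(params, z)
    loss = reconstruction_loss(batch, xp, config.loss_kind)
    loss += config.l2_weight * float((params.W**2).sum() + (params.W_dec**2).sum())
    if config.sparsity_weight > 0:
        loss += config.sparsity_weight * _kl_sparsity(
            z.mean(axis=0), config.sparsity_target
        )
    return loss


def gradients(
    params: AEParams, batch: np.ndarray, config: TrainConfig
) -> dict[str, np.ndarray]:
    """Analytic gradients of :func:`ae_objective` for all four blocks.

    Backpropagation with the sigmoid derivative factor x'(1 - x') at the
    output (which makes the output delta vanish at a perfect
    reconstruction) and z(1 - z) at the hidden layer; the data term is
    averaged over the batch, L2 adds 2*lambda*W, and the sparsity term
    enters through the mean hidden activation.
    """
    X = np.atleast_2d(np.asarray(batch, float))
    n = X.shape[0]
    Z = encode(params, X)
    Xp = decode(params, Z)

    if config.loss_kind == "mse":
        dL_dXp = -2.0 * (X - Xp)
    else:
        Xc = np.clip(Xp, _EPS, 1 - _EPS)
        dL_dXp = (Xc - X) / (Xc * (1 - Xc))
    delta_out = dL_dXp * Xp * (1 - Xp) / n  # n x d, mean folded in

    gW_dec = delta_out.T @ Z + 2 * config.l2_weight * params.W_dec
    gb_dec = delta_out.sum(axis=0)

    G_z = delta_out @ params.W_dec  # n x h
    if config.sparsity_weight > 0:
        rho = config.sparsity_target
        rho_hat = np.clip(Z.mean(axis=0), _EPS, 1 - _EPS)
        G_z = G_z + config.sparsity_weight * (
            -rho / rho_hat + (1 - rho) / (1 - rho_hat)
        ) / n
    delta_hid = G_z * Z * (1 - Z)
    gW = delta_hid.T @ X + 2 * config.l2_weight * params.W
    gb = delta_hid.sum(axis=0)
    return {"W": gW, "b": gb, "W_dec": gW_dec, "b_dec": gb_dec}


def train_ae(
    data: np.ndarray, config: TrainConfig, params: AEParams | None = None
) -> tuple[AEParams, TrainTrace]:
    """Train one auto-encoder by full-batch gradient descent.

    Runs at most ``config.max_epochs`` epochs of new = old - eta * grad and
    stops early when successive objective values differ by less than
    ``config.tolerance``. Deterministic given the config seed.
    """
    X = np.atleast_2d(np.asarray(data, float))
    if X.shape[0] < 1:
        raise ValueError("need at least one training row")
    if params is None:
        params = init_params(X.shape[1], config.hidden_size, config.seed)
    losses = []
    prev = np.inf
    stop_reason = "max_epochs"
    eta = config.learning_rate
    for _ in range(config.max_epochs):
        loss = ae_objective(params, X, config)
        if not np.isfinite(loss):
            raise TrainingDiverged("training diverged (reduce learning rate)")
        losses.append(loss)
        if abs(prev - loss) < config.tolerance:
            stop_reason = "converged"
            break
        prev = loss
        g = gradients(params, X, config)
        params = replace(
            params,
            W=params.W - eta * g["W"],
            b=params.b - eta * g["b"],
            W_dec=params.W_dec - eta * g["W_dec"],
            b_dec=params.b_dec - eta * g["b_dec"],
        )
    return params, TrainTrace(losses=np.array(losses), stop_reason=stop_reason)
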
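"""Sparse autoencoder and stacked sparse autoencoder (SSAE) classifier.

A sparse autoencoder maps an input x in [0,1]^M through a logistic hidden
layer Z = sigma(W1 x + b1) and reconstructs h = sigma(W2 Z + b2).  Training
minimises

    J(W, b) = (1/N) sum_i 1/2 ||h(x_i) - x_i||^2
            + (lambda/2) (||W1||_F^2 + ||W2||_F^2)
            + beta * sum_j KL(rho || rho_hat_j)

where rho_hat_j is the mean activation of hidden unit j over the batch and
KL is the Bernoulli Kullback-Leibler divergence pushing hidden units toward
the target sparsity rho.  Stacking trains each autoencoder greedily on the
previous layer's hidden activations, then a softmax head is attached and the
whole network fine-tuned by supervised cross-entropy gradient descent.

Default architecture and regularisation follow the EHG classification
setting: 64 -> 30 -> 10 encoder with a 2-way softmax, rho = 0.05, beta = 8,
lambda = 0.001.  All matrices use a column-per-sample layout internally; the
public helpers accept the usual rows-are-samples feature tables and adapt.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SAEHyperParams",
    "SAEParams",
    "SSAEModel",
    "sigmoid",
    "encode",
    "decode",
    "kl_divergence",
    "sae_cost",
    "sae_gradient",
    "train_sae",
    "pretrain_stack",
    "softmax_probs",
    "fine_tune",
    "train_ssae",
]

_KL_EPS = 1e-12


def sigmoid(u: np.ndarray) -> np.ndarray:
    # piecewise form avoids overflow in exp for large |u|
    out = np.empty_like(u, dtype=np.float64)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


@dataclass(frozen=True)
class SAEHyperParams:
    """Regularisation and optimisation settings for one sparse autoencoder."""

    rho: float = 0.05  # target mean hidden activation
    beta: float = 8.0  # sparsity penalty weight
    lambda_: float = 0.001  # weight decay
    epsilon: float = 0.1  # learning rate (pretraining)
    epochs: int = 400

    def __post_init__(self) -> None:
        if not (0 < self.rho < 1):
            raise ValueError("rho must lie in (0, 1)")
        if self.beta < 0 or self.lambda_ < 0:
            raise ValueError("beta and lambda must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class SAEParams:
    """Weights/biases of one autoencoder plus its hyperparameters.

    ``W1`` is hidden x input (encoder), ``W2`` input x hidden (decoder);
    weights are untied as the encoder and decoder are defined separately.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    hyper: SAEHyperParams = field(default_factory=SAEHyperParams)

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.b1 = np.asarray(self.b1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        self.b2 = np.asarray(self.b2, dtype=np.float64)
        h, m = self.W1.shape
        if self.W2.shape != (m, h) or self.b1.shape != (h,) or self.b2.shape != (m,):
            raise ValueError("inconsistent SAE parameter shapes")

    @property
    def n_input(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]


def init_sae(
    n_input: int, n_hidden: int, rng: np.random.Generator, hyper: SAEHyperParams
) -> SAEParams:
    """Uniform Glorot-style initialisation scaled by layer fan-in/out."""
    limit1 = np.sqrt(6.0 / (n_input + n_hidden))
    limit2 = np.sqrt(6.0 / (n_hidden + n_input))
    return SAEParams(
        W1=rng.uniform(-limit1, limit1, size=(n_hidden, n_input)),
        b1=np.zeros(n_hidden),
        W2=rng.uniform(-limit2, limit2, size=(n_input, n_hidden)),
        b2=np.zeros(n_input),
        hyper=hyper,
    )


def _check_columns(p_inputs: int, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != p_inputs:
        raise ValueError(
            f"expected {p_inputs} rows (features) in column-per-sample layout, "
            f"got shape {X.shape}"
        )
    return X


def encode(p: SAEParams, X: np.ndarray) -> np.ndarray:
    """Hidden representation Z = sigma(W1 X + b1); X is features x samples."""
    X = _check_columns(p.n_input, X)
    return sigmoid(p.W1 @ X + p.b1[:, None])


def decode(p: SAEParams, Z: np.ndarray) -> np.ndarray:
    """Reconstruction h = sigma(W2 Z + b2); Z is hidden x samples."""
    Z = _check_columns(p.n_hidden, Z)
    return sigmoid(p.W2 @ Z + p.b2[:, None])


def kl_divergence(rho: float, rho_hat) -> np.ndarray | float:
    """Bernoulli KL(rho || rho_hat); arguments clamped away from {0, 1}."""
    rho_hat = np.clip(np.asarray(rho_hat, dtype=np.float64), _KL_EPS, 1 - _KL_EPS)
    rho = min(max(float(rho), _KL_EPS), 1 - _KL_EPS)
    val = rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))
    return float(val) if val.ndim == 0 else val


def sae_cost(p: SAEParams, X: np.ndarray) -> Tuple[float, np.ndarray]:
    """Full objective value and the mean hidden activations rho_hat."""
    X = _check_columns(p.n_input, X)
    n = X.shape[1]
    Z = encode(p, X)
    H = decode(p, Z)
    rho_hat = Z.mean(axis=1)
    recon = 0.5 * np.sum((H - X) ** 2) / n
    decay = 0.5 * p.hyper.lambda_ * (np.sum(p.W1**2) + np.sum(p.W2**2))
    sparsity = p.hyper.beta * float(np.sum(kl_divergence(p.hyper.rho, rho_hat)))
    return recon + decay + sparsity, rho_hat


def sae_gradient(p: SAEParams, X: np.ndarray) -> Dict[str, np.ndarray]:
    """Analytic gradients of the full objective for every parameter block.

    The sparsity penalty enters the hidden-layer delta through
    d KL / d rho_hat_j = -rho/rho_hat_j + (1-rho)/(1-rho_hat_j), distributed
    over samples by the 1/N in rho_hat.
    """
    X = _check_columns(p.n_input, X)
    n = X.shape[1]
    Z = encode(p, X)
    H = decode(p, Z)
    rho_hat = np.clip(Z.mean(axis=1), _KL_EPS, 1 - _KL_EPS)
    rho = p.hyper.rho

    delta2 = (H - X) * H * (1 - H)  # input x samples
    gW2 = delta2 @ Z.T / n + p.hyper.lambda_ * p.W2
    gb2 = delta2.mean(axis=1)

    kl_grad = -rho / rho_hat + (1 - rho) / (1 - rho_hat)
    delta1 = (p.W2.T @ delta2 + p.hyper.beta * kl_grad[:, None]) * Z * (1 - Z)
    gW1 = delta1 @ X.T / n + p.hyper.lambda_ * p.W1
    gb1 = delta1.mean(axis=1)
    return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


def train_sae(
    X: np.ndarray,
    n_hidden: int,
    hyper: SAEHyperParams = SAEHyperParams(),
    seed: int = 0,
) -> Tuple[SAEParams, List[float]]:
    """Full-batch gradient descent on the sparse-autoencoder objective.

    ``X`` is features x samples in [0, 1].  Deterministic given ``seed``.
    Raises if the objective diverges to NaN.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (features x samples)")
    rng = np.random.default_rng(seed)
    p = init_sae(X.shape[0], n_hidden, rng, hyper)
    history: List[float] = []
    for epoch in range(hyper.epochs):
        cost, _ = sae_cost(p, X)
        if not np.isfinite(cost):
            raise FloatingPointError(
                f"SAE training diverged at epoch {epoch} (cost={cost})"
            )
        history.append(cost)
        g = sae_gradient(p, X)
        p.W1 -= hyper.epsilon * g["W1"]
        p.b1 -= hyper.epsilon * g["b1"]
        p.W2 -= hyper.epsilon * g["W2"]
        p.b2 -= hyper.epsilon * g["b2"]
    history.append(sae_cost(p, X)[0])
    return p, history


def pretrain_stack(
    X: np.ndarray,
    hidden_sizes: Sequence[int] = (30, 10),
    hyper: SAEHyperParams = SAEHyperParams(),
    seed: int = 0,
) -> Tuple[List[SAEParams], List[List[float]]]:
    """Greedy layer-wise pretraining.

    Layer k is trained to reconstruct the hidden activations of layer k-1
    (layer 1 reconstructs the inputs).  Returns the trained layers and their
    loss histories.
    """
    layers: List[SAEParams] = []
    histories: List[List[float]] = []
    current = np.asarray(X, dtype=np.float64)
    for k, h in enumerate(hidden_sizes):
        p, hist = train_sae(current, h, hyper, seed=seed + k)
        layers.append(p)
        histories.append(hist)
        current = encode(p, current)
    return layers, histories


def softmax_probs(W: np.ndarray, b: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Column-wise softmax of W H + b; columns sum to one."""
    logits = W @ H + b[:, None]
    logits = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=0, keepdims=True)


@dataclass
class SSAEModel:
    """Stacked encoder, softmax head, and the training record."""

    layers: List[SAEParams]
    softmax_W: np.ndarray
    softmax_b: np.ndarray
    seed: int = 0
    training_log: Dict[str, List[float]] = field(default_factory=dict)

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Top-layer representation for features x samples input."""
        H = np.asarray(X, dtype=np.float64)
        for layer in self.layers:
            H = encode(layer, H)
        return H

    def predict_proba(self, X_rows: np.ndarray) -> np.ndarray:
        """Class probabilities, rows-are-samples in and out (n x 2)."""
        H = self.hidden(np.asarray(X_rows, dtype=np.float64).T)
        return softmax_probs(self.softmax_W, self.softmax_b, H).T

    def predict(self, X_rows: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X_rows), axis=1)

    def decision_scores(self, X_rows: np.ndarray) -> np.ndarray:
        """Probability of the positive (labor) class, for ROC analysis."""
        return self.predict_proba(X_rows)[:, 1]

    # --- serialization ------------------------------------------------
    def to_json(self, path) -> None:
        bundle = {
            "format": "ehgkit-ssae",
            "version": 1,
            "seed": self.seed,
            "layers": [
                {
                    "W1": lay.W1.tolist(),
                    "b1": lay.b1.tolist(),
                    "W2": lay.W2.tolist(),
                    "b2": lay.b2.tolist(),
                    "hyper": {
                        "rho": lay.hyper.rho,
                        "beta": lay.hyper.beta,
                        "lambda_": lay.hyper.lambda_,
                        "epsilon": lay.hyper.epsilon,
                        "epochs": lay.hyper.epochs,
                    },
                }
                for lay in self.layers
            ],
            "softmax_W": self.softmax_W.tolist(),
            "softmax_b": self.softmax_b.tolist(),
            "training_log": self.training_log,
        }
        Path(path).write_text(json.dumps(bundle))

    @classmethod
    def from_json(cls, path) -> "SSAEModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "ehgkit-ssae":
            raise ValueError(f"{path} is not an SSAE model bundle")
        layers = [
            SAEParams(
                W1=np.array(lay["W1"]),
                b1=np.array(lay["b1"]),
                W2=np.array(lay["W2"]),
                b2=np.array(lay["b2"]),
                hyper=SAEHyperParams(**lay["hyper"]),
            )
            for lay in d["layers"]
        ]
        return cls(
            layers=layers,
            softmax_W=np.array(d["softmax_W"]),
            softmax_b=np.array(d["softmax_b"]),
            seed=d["seed"],
            training_log=d.get("training_log", {}),
        )


def _one_hot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, np.arange(n_classes)).all():
        raise ValueError(f"labels must be integers in [0, {n_classes})")
    Y = np.zeros((n_classes, y.size))
    Y[y, np.arange(y.size)] = 1.0
    return Y


def _cross_entropy(P: np.ndarray, Y: np.ndarray) -> float:
    return float(-np.sum(Y * np.log(np.clip(P, 1e-300, None))) / Y.shape[1])


def train_softmax(
    H: np.ndarray,
    y: np.ndarray,
    epochs: int = 200,
    lr: float = 0.5,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, List[float]]:
    """Multinomial logistic head on frozen representations (features x samples)."""
    rng = np.random.default_rng(seed)
    n_classes = 2
    limit = np.sqrt(6.0 / (H.shape[0] + n_classes))
    W = rng.uniform(-limit, limit, size=(n_classes, H.shape[0]))
    b = np.zeros(n_classes)
    Y = _one_hot(y, n_classes)
    history: List[float] = []
    n = H.shape[1]
    for _ in range(epochs):
        P = softmax_probs(W, b, H)
        history.append(_cross_entropy(P, Y))
        delta = (P - Y) / n
        W -= lr * (delta @ H.T)
        b -= lr * delta.sum(axis=1)
    return W, b, history


def fine_tune(
    model: SSAEModel,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 200,
    lr: float = 0.5,
    X_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
) -> SSAEModel:
    """Joint supervised backpropagation through encoders and softmax head.

    ``X`` is features x samples; ``y`` integer labels {0, 1}.  Minimises
    cross-entropy by full-batch gradient descent; per-epoch training (and
    optional validation) loss is appended to ``model.training_log``.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = _one_hot(np.asarray(y))
    n = X.shape[1]
    train_loss: List[float] = []
    val_loss: List[float] = []
    for _ in range(epochs):
        # forward
        activations = [X]
        for layer in model.layers:
            activations.append(encode(layer, activations[-1]))
        H = activations[-1]
        P = softmax_probs(model.softmax_W, model.softmax_b, H)
        train_loss.append(_cross_entropy(P, Y))
        if X_val is not None and y_val is not None:
            Pv = model.predict_proba(np.asarray(X_val, dtype=np.float64).T).T
            val_loss.append(_cross_entropy(Pv, _one_hot(np.asarray(y_val))))
        # backward
        delta = (P - Y) / n  # classes x samples
        gW = delta @ H.T
        gb = delta.sum(axis=1)
        back = model.softmax_W.T @ delta
        model.softmax_W -= lr * gW
        model.softmax_b -= lr * gb
        for layer, A_in, A_out in zip(
            reversed(model.layers), reversed(activations[:-1]), reversed(activations[1:])
        ):
            d = back * A_out * (1 - A_out)
            back = layer.W1.T @ d
            layer.W1 -= lr * (d @ A_in.T)
            layer.b1 -= lr * d.sum(axis=1)
    model.training_log.setdefault("fine_tune_train", []).extend(train_loss)
    if val_loss:
        model.training_log.setdefault("fine_tune_val", []).extend(val_loss)
    return model


def train_ssae(
    X_rows: np.ndarray,
    y: np.ndarray,
    hidden_sizes: Sequence[int] = (30, 10),
    hyper: SAEHyperParams = SAEHyperParams(),
    fine_tune_epochs: int = 200,
    fine_tune_lr: float = 0.5,
    softmax_epochs: int = 200,
    seed: int = 0,
    do_fine_tune: bool = True,
) -> SSAEModel:
    """End-to-end SSAE training from a rows-are-samples feature matrix.

    Greedy unsupervised pretraining of the encoder stack, softmax-head
    fitting on the frozen top representation, then (optionally) supervised
    fine-tuning of the whole network.
    """
    X = np.asarray(X_rows, dtype=np.float64).T  # to column-per-sample
    y = np.asarray(y)
    layers, histories = pretrain_stack(X, hidden_sizes, hyper, seed=seed)
    H = X
    for layer in layers:
        H = encode(layer, H)
    W, b, sm_hist = train_softmax(H, y, epochs=softmax_epochs, seed=seed + 100)
    model = SSAEModel(
        layers=layers,
        softmax_W=W,
        softmax_b=b,
        seed=seed,
        training_log={
            **{f"pretrain_layer{i + 1}": h for i, h in enumerate(histories)},
            "softmax": sm_hist,
        },
    )
    if do_fine_tune:
        fine_tune(model, X, y, epochs=fine_tune_epochs, lr=fine_tune_lr)
    return model
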
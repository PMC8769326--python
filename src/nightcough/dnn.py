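"""Small fully connected cough/non-cough network with LLR scoring.

Architecture: input -> FC(100, ReLU) -> dropout 0.5 -> FC(100, ReLU)
-> FC(2, softmax). Trained with Adam on class-weighted cross-entropy
(default learning rate 5e-6, batch size 32, 250 epochs). For 31 input
features the network has 13,502 learnable parameters. Scores are
``log(S_cough) - log(S_non_cough)``; the default operating threshold is
-2.22. Implemented directly in numpy so training is deterministic and
bit-reproducible for a fixed seed on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_THRESHOLD = -2.22
_PROB_CLIP = 1e-12

__all__ = [
    "NetworkSpec", "TrainingConfig", "NetworkModel",
    "build_network", "count_parameters", "train_dnn", "dnn_llr",
    "DEFAULT_THRESHOLD",
]


@dataclass
class NetworkSpec:
    """Layer sizes and regularization of the 2-class network."""

    input_dim: int
    hidden: tuple[int, ...] = (100, 100)
    dropout: float = 0.5      # applied between the two hidden layers
    output_dim: int = 2

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden, self.output_dim]
        return list(zip(dims[:-1], dims[1:]))


@dataclass
class TrainingConfig:
    learning_rate: float = 5e-6
    batch_size: int = 32
    epochs: int = 250
    class_weights: tuple[float, float] | None = None   # None = inverse frequency
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def build_network(input_dim: int) -> NetworkSpec:
    """Construct the standard 2-hidden-layer spec for ``input_dim`` features."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    return NetworkSpec(input_dim=input_dim)


def count_parameters(spec: NetworkSpec) -> int:
    """Exact learnable-parameter count: sum of fan_in*fan_out + fan_out."""
    return sum(fi * fo + fo for fi, fo in spec.layer_dims)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_params(spec: NetworkSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Glorot-uniform weights, zero biases; flat [W1, b1, W2, b2, W3, b3]."""
    params = []
    for fi, fo in spec.layer_dims:
        limit = np.sqrt(6.0 / (fi + fo))
        params.append(rng.uniform(-limit, limit, size=(fi, fo)))
        params.append(np.zeros(fo))
    return params


def _forward(params, X, spec: NetworkSpec, rng=None):
    """Returns (probs, cache). Dropout is active iff ``rng`` is given."""
    W1, b1, W2, b2, W3, b3 = params
    h1 = np.maximum(X @ W1 + b1, 0.0)
    if rng is not None and spec.dropout > 0:
        mask = (rng.random(h1.shape) >= spec.dropout) / (1.0 - spec.dropout)
        h1d = h1 * mask
    else:
        mask = None
        h1d = h1
    h2 = np.maximum(h1d @ W2 + b2, 0.0)
    probs = _softmax(h2 @ W3 + b3)
    return probs, (X, h1, mask, h1d, h2)


@dataclass
class NetworkModel:
    """A trained network plus its normalization statistics and threshold."""

    spec: NetworkSpec
    params: list[np.ndarray] = field(repr=False)
    mean: np.ndarray
    std: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0),
                                     repr=False)

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) softmax outputs [S_cough, S_non_cough]; dropout off."""
        Z = (np.atleast_2d(X) - self.mean) / self.std
        probs, _ = _forward(self.params, Z, self.spec, rng=None)
        return probs

    def llr(self, X: np.ndarray) -> np.ndarray:
        return dnn_llr(self, X)

    def predict(self, X: np.ndarray, threshold: float | None = None) -> np.ndarray:
        th = self.threshold if threshold is None else threshold
        return np.where(self.llr(X) > th, "cough", "non-cough")

    def save(self, path: str | Path) -> None:
        payload = {
            "input_dim": self.spec.input_dim,
            "hidden": list(self.spec.hidden),
            "dropout": self.spec.dropout,
            "params": [p.tolist() for p in self.params],
            "mean": self.mean.tolist(), "std": self.std.tolist(),
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkModel":
        d = json.loads(Path(path).read_text())
        spec = NetworkSpec(input_dim=d["input_dim"], hidden=tuple(d["hidden"]),
                           dropout=d["dropout"])
        return cls(spec=spec, params=[np.asarray(p) for p in d["params"]],
                   mean=np.asarray(d["mean"]), std=np.asarray(d["std"]),
                   threshold=float(d["threshold"]))


def _weighted_ce(probs: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], _PROB_CLIP, 1.0)
    return float(np.mean(w[y] * -np.log(p)))


def train_dnn(spec: NetworkSpec, X: np.ndarray, y: np.ndarray,
              cfg: TrainingConfig | None = None) -> NetworkModel:
    """Train on binary labels (cough = positive class).

    ``y`` may be strings ("cough" / anything else) or {0, 1} with 1 =
    cough. Features are z-scored with training statistics. Class weights
    default to n_total / (2 * n_class). Dropout is active only here.
    """
    cfg = cfg or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype.kind in "US":
        y_idx = np.where(y == "cough", 0, 1)   # row 0 = cough = S_1
    else:
        y_idx = np.where(y.astype(int) == 1, 0, 1)
    if len(np.unique(y_idx)) < 2:
        raise ValueError("training set must contain both classes")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std

    if cfg.class_weights is None:
        counts = np.bincount(y_idx, minlength=2)
        w = len(y_idx) / (2.0 * counts)
    else:
        w = np.asarray(cfg.class_weights, dtype=float)

    rng = np.random.default_rng(cfg.rng_seed)
    params = _init_params(spec, rng)
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(Z)
    losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = Z[idx], y_idx[idx]
            probs, cache = _forward(params, xb, spec, rng=rng)
            epoch_loss += _weighted_ce(probs, yb, w) * len(idx)
            grads = _backward(params, probs, yb, w, cache, spec)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for i, g in enumerate(grads):
                m_t[i] = beta1 * m_t[i] + (1 - beta1) * g
                v_t[i] = beta2 * v_t[i] + (1 - beta2) * g * g
                params[i] -= lr_t * m_t[i] / (np.sqrt(v_t[i]) + eps)
        losses.append(epoch_loss / n)

    return NetworkModel(spec=spec, params=params, mean=mean, std=std,
                        loss_history=np.asarray(losses))


def _backward(params, probs, y_idx, w, cache, spec: NetworkSpec):
    W1, b1, W2, b2, W3, b3 = params
    X, h1, mask, h1d, h2 = cache
    n = len(y_idx)
    wn = w[y_idx] / n
    dz3 = probs.copy()
    dz3[np.arange(n), y_idx] -= 1.0
    dz3 *= wn[:, None]
    gW3 = h2.T @ dz3
    gb3 = dz3.sum(axis=0)
    dh2 = dz3 @ W3.T
    dz2 = dh2 * (h2 > 0)
    gW2 = h1d.T @ dz2
    gb2 = dz2.sum(axis=0)
    dh1d = dz2 @ W2.T
    if mask is not None:
        dh1d = dh1d * mask
    dz1 = dh1d * (h1 > 0)
    gW1 = X.T @ dz1
    gb1 = dz1.sum(axis=0)
    return [gW1, gb1, gW2, gb2, gW3, gb3]


def dnn_llr(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    """log(S_1) - log(S_2) with probabilities clipped to [1e-12, 1]."""
    probs = np.clip(model.probabilities(X), _PROB_CLIP, 1.0)
    return np.log(probs[:, 0]) - np.log(probs[:, 1])
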
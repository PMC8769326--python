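"""Per-class diagonal Gaussian mixtures and log-likelihood-ratio scoring.

Three mixtures (cough, snore, noise) are EM-fitted on z-scored features;
an event's score is ``log(S_cough / max(S_snore, S_noise))``, computed in
the log domain. The paper-default model orders are (1, 1, 16) and the
paper-default operating threshold is 1.17.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

VARIANCE_FLOOR = 1e-6
DEFAULT_ORDERS = (1, 1, 16)
DEFAULT_THRESHOLD = 1.17
CLASS_ORDER = ("cough", "snore", "noise")

__all__ = [
    "GaussianMixtureModel", "GMMClassifier", "LLRScore",
    "fit_gmm", "gmm_likelihood", "gmm_log_likelihood", "gmm_llr",
    "select_orders", "DEFAULT_ORDERS", "DEFAULT_THRESHOLD",
]


@dataclass
class GaussianMixtureModel:
    """A diagonal-covariance Gaussian mixture for one event class."""

    weights: np.ndarray          # (m,), positive, sums to 1
    means: np.ndarray            # (m, D)
    variances: np.ndarray        # (m, D), floored
    label: str = ""
    log_likelihood_history: np.ndarray = field(
        default_factory=lambda: np.empty(0), repr=False)
    converged: bool = True

    @property
    def order(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "means": self.means.tolist(),
                "variances": self.variances.tolist(), "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianMixtureModel":
        return cls(weights=np.asarray(d["weights"]), means=np.asarray(d["means"]),
                   variances=np.asarray(d["variances"]), label=d.get("label", ""))


@dataclass
class LLRScore:
    value: float
    class_log_scores: dict[str, float]


def _component_log_densities(model: GaussianMixtureModel, X: np.ndarray) -> np.ndarray:
    """(n, m) log of weight_i * N(x; mu_i, diag(var_i))."""
    D = model.dim
    diff = X[:, None, :] - model.means[None, :, :]        # (n, m, D)
    quad = np.sum(diff * diff / model.variances[None, :, :], axis=2)
    logdet = np.sum(np.log(model.variances), axis=1)      # (m,)
    return (np.log(model.weights)[None, :]
            - 0.5 * (D * np.log(2 * np.pi) + logdet[None, :] + quad))


def gmm_log_likelihood(model: GaussianMixtureModel, X: np.ndarray) -> np.ndarray:
    """Per-row log mixture density log S = log sum_i w_i N(x; mu_i, S_i)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.dim:
        raise ValueError(f"feature dimension {X.shape[1]} != model dim {model.dim}")
    return logsumexp(_component_log_densities(model, X), axis=1)


def gmm_likelihood(model: GaussianMixtureModel, beta: np.ndarray) -> float:
    """Linear-domain mixture density for one feature vector."""
    return float(np.exp(gmm_log_likelihood(model, np.atleast_2d(beta))[0]))


def fit_gmm(X: np.ndarray, order: int, rng: np.random.Generator | int | None = None,
            *, n_restarts: int = 5, max_iter: int = 200, tol: float = 1e-6,
            label: str = "") -> GaussianMixtureModel:
    """EM-fit a diagonal mixture with k-means initialization and restarts.

    The training log-likelihood is non-decreasing across EM iterations;
    the best of ``n_restarts`` differently-seeded runs is returned.
    Collapsing components are caught by a variance floor.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (events x features)")
    n, D = X.shape
    if order > n:
        raise ValueError(f"order {order} exceeds {n} training rows")
    rng = np.random.default_rng(rng)

    best: GaussianMixtureModel | None = None
    best_ll = -np.inf
    for restart in range(n_restarts):
        seed = int(rng.integers(0, 2**31 - 1))
        model = _fit_once(X, order, seed, max_iter, tol, label)
        final = model.log_likelihood_history[-1]
        if final > best_ll:
            best_ll = final
            best = model
    assert best is not None
    return best


def _fit_once(X, order, seed, max_iter, tol, label):
    n, D = X.shape
    if order == 1:
        means = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=order, n_init=1, random_state=seed).fit(X)
        means = km.cluster_centers_
    variances = np.tile(np.maximum(X.var(axis=0), VARIANCE_FLOOR), (order, 1))
    weights = np.full(order, 1.0 / order)
    model = GaussianMixtureModel(weights, means, variances, label)

    history = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        log_comp = _component_log_densities(model, X)
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.mean())
        history.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])       # (n, m)
        nk = resp.sum(axis=0) + 1e-12
        model.weights = nk / n
        model.means = (resp.T @ X) / nk[:, None]
        diff2 = (X[:, None, :] - model.means[None, :, :]) ** 2
        var = np.einsum("nm,nmd->md", resp, diff2) / nk[:, None]
        model.variances = np.maximum(var, VARIANCE_FLOOR)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
    model.log_likelihood_history = np.asarray(history)
    model.converged = converged
    return model


def gmm_llr(models: dict[str, GaussianMixtureModel], X: np.ndarray) -> np.ndarray:
    """log(S_cough / max(S_snore, S_noise)) per row, in the log domain."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    log_s = {c: gmm_log_likelihood(models[c], X) for c in CLASS_ORDER}
    return log_s["cough"] - np.maximum(log_s["snore"], log_s["noise"])


def gmm_llr_single(models: dict[str, GaussianMixtureModel],
                   beta: np.ndarray) -> LLRScore:
    X = np.atleast_2d(beta)
    log_s = {c: float(gmm_log_likelihood(models[c], X)[0]) for c in CLASS_ORDER}
    value = log_s["cough"] - max(log_s["snore"], log_s["noise"])
    return LLRScore(value=value, class_log_scores=log_s)


@dataclass
class GMMClassifier:
    """Three per-class mixtures plus the training z-score statistics."""

    models: dict[str, GaussianMixtureModel]
    mean: np.ndarray
    std: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    orders: tuple[int, int, int] = DEFAULT_ORDERS

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray,
            orders: tuple[int, int, int] = DEFAULT_ORDERS,
            rng: np.random.Generator | int | None = None,
            threshold: float = DEFAULT_THRESHOLD) -> "GMMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(rng)
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        Z = (X - mean) / std
        models = {}
        for cls_name, order in zip(CLASS_ORDER, orders):
            rows = Z[y == cls_name]
            if len(rows) == 0:
                raise ValueError(f"no training rows for class {cls_name!r}")
            models[cls_name] = fit_gmm(rows, min(order, len(rows)), rng,
                                       label=cls_name)
        return cls(models=models, mean=mean, std=std, threshold=threshold,
                   orders=orders)

    def llr(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - self.mean) / self.std
        return gmm_llr(self.models, Z)

    def predict(self, X: np.ndarray, threshold: float | None = None) -> np.ndarray:
        th = self.threshold if threshold is None else threshold
        return np.where(self.llr(X) > th, "cough", "non-cough")

    def save(self, path: str | Path) -> None:
        payload = {
            "models": {c: m.to_dict() for c, m in self.models.items()},
            "mean": self.mean.tolist(), "std": self.std.tolist(),
            "threshold": self.threshold, "orders": list(self.orders),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GMMClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            models={c: GaussianMixtureModel.from_dict(m)
                    for c, m in d["models"].items()},
            mean=np.asarray(d["mean"]), std=np.asarray(d["std"]),
            threshold=float(d["threshold"]), orders=tuple(d["orders"]))


def select_orders(train_X, train_y, dev_X, dev_y, max_order: int = 20,
                  rng: np.random.Generator | int | None = None,
                  n_sweeps: int = 2) -> tuple[int, int, int]:
    """Pick per-class mixture orders (capped at ``max_order``) maximizing
    the dev-set selection criterion J at the J-optimal threshold.

    Coordinate ascent over the three orders, starting from (1, 1, 1).
    """
    from .evaluate import best_j_threshold  # deferred: avoids cycle

    rng = np.random.default_rng(rng)
    orders = [1, 1, 1]
    dev_pos = np.asarray(dev_y) == "cough"

    def score(trial: list[int]) -> float:
        clf = GMMClassifier.fit(train_X, train_y, orders=tuple(trial), rng=1234)
        scores = clf.llr(dev_X)
        _, j = best_j_threshold(scores, dev_pos)
        return j

    best_j = score(orders)
    for _ in range(n_sweeps):
        improved = False
        for ci in range(3):
            for m in range(1, max_order + 1):
                if m == orders[ci]:
                    continue
                trial = orders.copy()
                trial[ci] = m
                try:
                    j = score(trial)
                except ValueError:
                    continue
                if j > best_j + 1e-12:
                    best_j = j
                    orders = trial
                    improved = True
        if not improved:
            break
    return tuple(orders)  # type: ignore[return-value]
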
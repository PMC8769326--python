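"""Sequential Forward Selection wrapped around the GMM classifier.

At each step the feature maximizing J = (sensitivity + PPV) / 2 —
evaluated on a development split at the dev-optimal LLR threshold — is
added; the returned subset is the prefix of the greedy path with the
highest criterion value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluate import best_j_threshold
from .features import FEATURE_NAMES
from .gmm import DEFAULT_ORDERS, GMMClassifier

#: Feature mask matching the published 31-of-34 subset: kurtosis and
#: skewness dropped, and one part-1 MFCC (the highest-order one) dropped.
PAPER_FEATURE_MASK: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES if n not in ("kurtosis", "skewness", "mfcc1_12"))

__all__ = ["SelectionResult", "criterion_J", "sfs_select",
           "PAPER_FEATURE_MASK", "resolve_feature_mask"]


@dataclass
class SelectionResult:
    selected: list[str]              # full greedy path, in selection order
    criterion_trajectory: list[float]
    best_subset_size: int

    @property
    def best_subset(self) -> list[str]:
        return self.selected[:self.best_subset_size]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "selected": self.selected,
            "criterion_trajectory": self.criterion_trajectory,
            "best_subset_size": self.best_subset_size,
        }, indent=2))


def criterion_J(sensitivity: float, ppv: float) -> float:
    """J = (sensitivity + PPV) / 2."""
    if not (0 <= sensitivity <= 1 and 0 <= ppv <= 1):
        raise ValueError("sensitivity and PPV must be in [0, 1]")
    return 0.5 * sensitivity + 0.5 * ppv


def _evaluate_subset(cols, train_X, train_y, dev_X, dev_y, orders, seed) -> float:
    clf = GMMClassifier.fit(train_X[:, cols], train_y, orders=orders, rng=seed)
    scores = clf.llr(dev_X[:, cols])
    _, j = best_j_threshold(scores, dev_y == "cough")
    return j


def sfs_select(train_X, train_y, dev_X, dev_y,
               feature_names: list[str] | None = None,
               max_features: int | None = None,
               orders: tuple[int, int, int] = DEFAULT_ORDERS,
               seed: int = 1234) -> SelectionResult:
    """Greedy forward selection of feature columns.

    ``train`` and ``dev`` must come from disjoint subjects. The GMM
    orders are held fixed during the search (full order selection is only
    run for the final model). Candidates whose GMM training fails are
    skipped with a warning.
    """
    train_X = np.asarray(train_X, dtype=float)
    dev_X = np.asarray(dev_X, dtype=float)
    train_y = np.asarray(train_y)
    dev_y = np.asarray(dev_y)
    n_feat = train_X.shape[1]
    names = list(feature_names) if feature_names is not None else \
        [f"f{i}" for i in range(n_feat)]
    if len(names) != n_feat:
        raise ValueError("feature_names length mismatch")
    max_features = max_features or n_feat

    chosen: list[int] = []
    trajectory: list[float] = []
    remaining = list(range(n_feat))
    while remaining and len(chosen) < max_features:
        best_j, best_c = -np.inf, None
        for c in remaining:
            cols = chosen + [c]
            try:
                j = _evaluate_subset(cols, train_X, train_y, dev_X, dev_y,
                                     orders, seed)
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"skipping candidate {names[c]!r}: {exc}",
                              RuntimeWarning, stacklevel=2)
                continue
            if j > best_j:
                best_j, best_c = j, c
        if best_c is None:
            break
        chosen.append(best_c)
        remaining.remove(best_c)
        trajectory.append(best_j)

    best_size = int(np.argmax(trajectory)) + 1 if trajectory else 0
    return SelectionResult(selected=[names[c] for c in chosen],
                           criterion_trajectory=trajectory,
                           best_subset_size=best_size)


def resolve_feature_mask(mask: str) -> tuple[str, ...]:
    """Map the --feature-mask config value to a tuple of feature names."""
    if mask == "all":
        return FEATURE_NAMES
    if mask == "paper":
        return PAPER_FEATURE_MASK
    raise ValueError(f"unknown feature mask {mask!r}; use 'all', 'paper' or "
                     "run SFS explicitly")
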
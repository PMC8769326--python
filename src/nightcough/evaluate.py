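"""Confusion-matrix metrics, ROC/PR curves, thresholding and k-fold CV.

Cough is the positive class throughout. Metrics with a zero denominator
are reported as None (undefined), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix", "MetricsReport", "metrics_from_confusion",
    "confusion_from_predictions", "roc_pr_curves", "choose_threshold",
    "best_j_threshold", "kfold_cv",
]


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    kappa: float | None
    roc_auc: float | None = None
    pr_auc: float | None = None


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV and Cohen's kappa.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    total = cm.total
    p_o = (tp + tn) / total
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / total**2
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else None
    return MetricsReport(
        accuracy=p_o,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        kappa=kappa,
    )


def confusion_from_predictions(pred_positive: np.ndarray,
                               true_positive: np.ndarray) -> ConfusionMatrix:
    pred = np.asarray(pred_positive, dtype=bool)
    true = np.asarray(true_positive, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(pred & true)), fn=int(np.sum(~pred & true)),
        fp=int(np.sum(pred & ~true)), tn=int(np.sum(~pred & ~true)))


def _curve_points(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP counts at each distinct threshold (descending).

    Classification rule is ``score > threshold``; tied scores are grouped.
    Returns (thresholds, tp, fp, n_pos, n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    l = labels[order]
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(l)[idx]
    fp = np.cumsum(~l)[idx]
    return s[idx], tp, fp, n_pos, n_neg


def roc_pr_curves(scores: np.ndarray, labels: np.ndarray) -> dict:
    """ROC (sensitivity vs specificity) and PR (sensitivity vs PPV) curves.

    AUCs by the trapezoid rule; tied scores are collapsed to one point.
    Returns a dict with thresholds, sensitivity, specificity, ppv,
    roc_auc and pr_auc.
    """
    th, tp, fp, n_pos, n_neg = _curve_points(scores, labels)
    sens = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    roc_auc = float(np.trapezoid(sens, fpr))
    with np.errstate(invalid="ignore"):
        prec = tp / np.maximum(tp + fp, 1)
    recall = np.r_[0.0, tp / n_pos]
    precision = np.r_[1.0 if len(prec) == 0 else prec[0], prec]
    pr_auc = float(np.trapezoid(precision, recall))
    return {
        "thresholds": th,
        "sensitivity": tp / n_pos,
        "specificity": 1.0 - fp / n_neg,
        "ppv": prec,
        "roc_auc": roc_auc,
        "pr_auc": pr_auc,
    }


def choose_threshold(scores: np.ndarray, labels: np.ndarray,
                     target_sensitivity: float) -> float:
    """Largest candidate threshold whose sensitivity (rule: score > th)
    reaches ``target_sensitivity`` on this split."""
    if not (0 < target_sensitivity <= 1):
        raise ValueError("target_sensitivity must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    if len(pos) == 0:
        raise ValueError("no positive examples")
    candidates = np.unique(scores)[::-1]
    candidates = np.r_[candidates, candidates[-1] - 1.0]
    for th in candidates:
        if np.mean(pos > th) >= target_sensitivity:
            return float(th)
    raise ValueError(f"sensitivity {target_sensitivity} is unattainable")


def best_j_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing J = (sensitivity + PPV) / 2; returns (th, J).

    Candidate thresholds are midpoints below each distinct score so every
    achievable (sensitivity, PPV) operating point is reachable with the
    strict ``score > threshold`` rule.
    """
    th, tp, fp, n_pos, _ = _curve_points(scores, labels)
    sens = tp / n_pos
    with np.errstate(invalid="ignore"):
        ppv = tp / np.maximum(tp + fp, 1)
    j = 0.5 * sens + 0.5 * ppv
    k = int(np.argmax(j))
    eps = 1e-9 * max(1.0, abs(th[k]))
    return float(th[k] - eps), float(j[k])


def kfold_cv(subject_ids, X, y, k: int, fit_score_fn,
             rng: np.random.Generator | int | None = None):
    """Subject-disjoint k-fold cross-validation.

    Folds are balanced greedily on per-subject cough counts. For each
    fold, ``fit_score_fn(X_train, y_train, X_test) -> (scores_train,
    scores_test)`` is called and metrics are computed at the train-side
    J-optimal threshold.
    Returns (list of per-fold MetricsReport, summary dict mean/sd).
    """
    subject_ids = np.asarray(subject_ids)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subjects = np.unique(subject_ids)
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds {len(subjects)} subjects")
    rng = np.random.default_rng(rng)

    counts = {s: int(np.sum((subject_ids == s) & (y == "cough")))
              for s in subjects}
    shuffled = list(subjects[rng.permutation(len(subjects))])
    shuffled.sort(key=lambda s: -counts[s])
    folds: list[list] = [[] for _ in range(k)]
    fold_counts = np.zeros(k)
    fold_sizes = np.zeros(k, dtype=int)
    for s in shuffled:
        i = int(np.lexsort((fold_sizes, fold_counts))[0])
        folds[i].append(s)
        fold_counts[i] += counts[s]
        fold_sizes[i] += 1

    reports: list[MetricsReport] = []
    for fold in folds:
        test_mask = np.isin(subject_ids, fold)
        X_tr, y_tr = X[~test_mask], y[~test_mask]
        X_te, y_te = X[test_mask], y[test_mask]
        if "cough" not in y_te or "cough" not in y_tr:
            continue
        scores_tr, scores_te = fit_score_fn(X_tr, y_tr, X_te)
        th, _ = best_j_threshold(scores_tr, y_tr == "cough")
        cm = confusion_from_predictions(scores_te > th, y_te == "cough")
        rep = metrics_from_confusion(cm)
        curves = roc_pr_curves(scores_te, y_te == "cough")
        rep.roc_auc = curves["roc_auc"]
        rep.pr_auc = curves["pr_auc"]
        reports.append(rep)

    summary = {}
    for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv",
                 "kappa", "roc_auc", "pr_auc"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if vals:
            summary[name] = (float(np.mean(vals)), float(np.std(vals)))
    return reports, summary
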
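"""Hypnogram alignment, stage-normalized cough rates and statistics.

Events are assigned to the 30 s epoch containing their onset (epochs are
half-open). Rates are counts divided by stage hours; stages with zero
duration get an undefined (None) rate. Includes a two-sided Wilcoxon
rank-sum test (exact permutation enumeration for small samples,
tie-corrected normal approximation otherwise), Pearson/Spearman/partial
correlation, and post-cough stage-transition tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synth import Hypnogram, STAGES

EXACT_MAX_N = 8   # exact rank-sum enumeration when both groups are this small

__all__ = [
    "SubjectMetadata", "CoughRateTable", "assign_stage", "cough_rate_by_stage",
    "rank_sum_test", "correlate", "transition_after_cough",
    "read_hypnogram_tsv",
]


@dataclass
class SubjectMetadata:
    subject_id: str
    age: float
    bmi: float
    ahi: float
    gender: str
    smoker: bool = False

    def __post_init__(self) -> None:
        if min(self.age, self.bmi, self.ahi) < 0:
            raise ValueError("age, BMI and AHI must be non-negative")


@dataclass
class CoughRateTable:
    """Per-stage cough counts, stage hours and rates (coughs/hour)."""

    counts: dict[str, int]
    hours: dict[str, float]

    @property
    def rates(self) -> dict[str, float | None]:
        return {s: (self.counts[s] / self.hours[s] if self.hours[s] > 0 else None)
                for s in STAGES}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stage": list(STAGES),
            "count": [self.counts[s] for s in STAGES],
            "hours": [self.hours[s] for s in STAGES],
            "rate_per_hour": [self.rates[s] for s in STAGES],
        })


def _onset_of(event) -> float:
    return event.start_s if hasattr(event, "start_s") else float(event)


def assign_stage(event, hyp: Hypnogram) -> str:
    """Stage of the epoch containing the event onset (half-open epochs)."""
    return hyp.stage_at(_onset_of(event))


def cough_rate_by_stage(events, hyp: Hypnogram,
                        lights: tuple[float, float] | None = None) -> CoughRateTable:
    """Stage-wise cough counts normalized by stage duration in hours.

    ``lights`` restricts both the events and the epochs to the
    [lights_off, lights_on) window; the default is the full hypnogram.
    """
    if lights is None:
        t0, t1 = hyp.start_time, hyp.span
    else:
        t0, t1 = lights
    counts = {s: 0 for s in STAGES}
    hours = {s: 0.0 for s in STAGES}
    for i, stage in enumerate(hyp.stages):
        e0 = hyp.start_time + i * hyp.epoch_length
        e1 = e0 + hyp.epoch_length
        overlap = max(0.0, min(e1, t1) - max(e0, t0))
        hours[stage] += overlap / 3600.0
    for ev in events:
        t = _onset_of(ev)
        if t0 <= t < t1:
            counts[assign_stage(ev, hyp)] += 1
    return CoughRateTable(counts=counts, hours=hours)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided p by full enumeration of all C(n1+n2, n1) rank splits."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / len(pooled)
    d_obs = abs(w_obs - mu)
    n_total = comb(len(pooled), n1)
    hits = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= d_obs - 1e-12:
            hits += 1
    return float(w_obs), hits / n_total


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum statistic, p).

    Exact permutation enumeration when both samples have <= 8 values;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return _exact_rank_sum_p(x, y)
    return _approx_rank_sum_p(x, y)


def _approx_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(w), 1.0
    d = abs(w - mu)
    z = max(0.0, d - 0.5) / np.sqrt(sigma2)   # continuity correction
    p = 2.0 * stats.norm.sf(z)
    return float(w), float(min(p, 1.0))


def correlate(x, y, method: str = "pearson", controls=None) -> tuple[float, float]:
    """Correlation coefficient and p-value.

    ``pearson`` on values; ``spearman`` = Pearson on (average) ranks;
    ``partial`` = Pearson on the residuals of x and y after OLS-regressing
    out ``controls``, with the t-test run on n - 2 - n_controls degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")

    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
        return float(r), float(p)
    if method == "partial":
        if controls is None:
            raise ValueError("partial correlation requires controls")
        C = np.atleast_2d(np.asarray(controls, dtype=float))
        if C.shape[0] == len(x) and C.ndim == 2:
            Z = C
        else:
            Z = C.T
        if Z.shape[0] != len(x):
            raise ValueError("controls length mismatch")
        design = np.column_stack([np.ones(len(x)), Z])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        r = float(np.corrcoef(rx, ry)[0, 1])
        df = len(x) - 2 - Z.shape[1]
        if df <= 0:
            raise ValueError("not enough samples for partial correlation")
        t = r * np.sqrt(df / max(1e-12, 1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
        return r, float(p)
    raise ValueError(f"unknown method {method!r}")


def transition_after_cough(events, hyp: Hypnogram) -> tuple[pd.DataFrame, int]:
    """Stage-to-next-epoch-stage percentages for epochs containing coughs.

    Returns (table, n_excluded): ``table`` has one row per origin stage
    with percentage columns per destination stage; coughs in the final
    epoch cannot have a next stage and are counted in ``n_excluded``.
    """
    counts = {s: {t: 0 for t in STAGES} for s in STAGES}
    excluded = 0
    for ev in events:
        t = _onset_of(ev)
        idx = int((t - hyp.start_time) // hyp.epoch_length)
        if not (0 <= idx < len(hyp.stages)):
            raise ValueError(f"event onset {t} s outside hypnogram span")
        if idx + 1 >= len(hyp.stages):
            excluded += 1
            continue
        counts[hyp.stages[idx]][hyp.stages[idx + 1]] += 1
    rows = []
    for s in STAGES:
        total = sum(counts[s].values())
        row = {"from_stage": s, "n": total}
        for t in STAGES:
            row[f"to_{t}_pct"] = 100.0 * counts[s][t] / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows), excluded


def read_hypnogram_tsv(path: str | Path) -> Hypnogram:
    """Read a hypnogram TSV (epoch_index<TAB>stage, or one stage per line)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    stages = []
    for ln in lines:
        parts = ln.split("\t")
        token = parts[-1]
        if token == "stage":   # header row
            continue
        stages.append(token)
    return Hypnogram(stages=stages)
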
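"""ROC analysis, Youden cutoffs, confusion metrics and contingency summaries.

AUC is computed as the Mann-Whitney pair statistic (ties count one half) and
its 95% confidence interval by the DeLong structural-component estimator; a
percentile bootstrap is available as a cross-check.  Candidate cutoffs are
the midpoints between adjacent sorted unique scores, with higher score
meaning tumor throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "MetricSet",
    "roc_analysis",
    "youden_optimal_cutoff",
    "confusion_metrics",
    "metrics_from_rates",
    "compare_roc_paired",
    "contingency_summary",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray  # candidate cutoffs, ascending
    sensitivity: np.ndarray  # P(score > cutoff | positive) per cutoff
    specificity: np.ndarray  # P(score <= cutoff | negative) per cutoff
    auc: float
    ci: tuple[float, float]
    youden_cutoff: float
    n_pos: int
    n_neg: int
    auc_variance: float = field(default=float("nan"))

    @property
    def youden_index(self) -> float:
        j = self.sensitivity + self.specificity - 1.0
        return float(np.max(j))


@dataclass
class MetricSet:
    """Confusion-matrix counts and the four diagnostic rates.

    Counts may be fractional when derived from rounded published rates via
    :func:`metrics_from_rates`.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def _validate_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("degenerate labels: exactly two classes required")
    return y


def _binarize(labels, positive_label=None) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if positive_label is None:
        if set(classes.tolist()) <= {0, 1, True, False}:
            return y.astype(int)
        raise ValueError(f"positive_label required for labels {classes.tolist()}")
    return (y == positive_label).astype(int)


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components: per-positive and per-negative placement
    values, plus the AUC (their common mean)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    # midranks over the pooled sample handle ties with half credit
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    r_pos = ranks[:m]
    r_neg = ranks[m:]
    auc = (r_pos.sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (r_pos - stats.rankdata(pos)) / n  # V10 components
    v_neg = 1.0 - (r_neg - stats.rankdata(neg)) / m  # V01 components
    return v_pos, v_neg, float(auc)


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    if u.size < 2:
        return u.copy()
    return (u[:-1] + u[1:]) / 2.0


def _operating_points(scores, y, cutoffs):
    pos = scores[y == 1]
    neg = scores[y == 0]
    sens = np.array([(pos > c).mean() for c in cutoffs])
    spec = np.array([(neg <= c).mean() for c in cutoffs])
    return sens, spec


def _best_youden(cutoffs, sens, spec) -> float:
    j = sens + spec - 1.0
    best = np.max(j)
    mask = np.isclose(j, best)
    # ties broken toward higher sensitivity, then lower cutoff
    cand_sens = sens[mask]
    cand_cut = cutoffs[mask]
    top = np.isclose(cand_sens, cand_sens.max())
    return float(np.min(cand_cut[top]))


def roc_analysis(
    scores,
    labels,
    positive_label=None,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> ROCResult:
    """ROC analysis with AUC, 95% CI and the Youden-optimal cutoff.

    Scores are oriented so that higher values indicate the positive (tumor)
    class.  ``ci_method`` is ``"delong"`` (default) or ``"bootstrap"``
    (percentile, ``n_boot`` resamples).
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = _binarize(_validate_binary(labels), positive_label)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("degenerate labels: both classes must be present")

    v_pos, v_neg, auc = _placements(scores, y)
    m, n = v_pos.size, v_neg.size
    var = float("nan")
    if ci_method == "delong":
        s10 = v_pos.var(ddof=1) if m > 1 else 0.0
        s01 = v_neg.var(ddof=1) if n > 1 else 0.0
        var = s10 / m + s01 / n
        half = stats.norm.ppf(0.975) * math.sqrt(max(var, 0.0))
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(idx_pos, size=m, replace=True)
            bn = rng.choice(idx_neg, size=n, replace=True)
            bs = np.concatenate([scores[bp], scores[bn]])
            by = np.concatenate([np.ones(m, int), np.zeros(n, int)])
            aucs[b] = _placements(bs, by)[2]
        ci = (float(np.quantile(aucs, 0.025)), float(np.quantile(aucs, 0.975)))
        var = float(np.var(aucs, ddof=1))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    cutoffs = _candidate_cutoffs(scores)
    sens, spec = _operating_points(scores, y, cutoffs)
    youden = _best_youden(cutoffs, sens, spec) if cutoffs.size else float(np.unique(scores)[0])
    return ROCResult(
        thresholds=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci=ci,
        youden_cutoff=youden,
        n_pos=m,
        n_neg=n,
        auc_variance=var,
    )


def youden_optimal_cutoff(roc: ROCResult) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1 over the candidate
    set, ties broken toward higher sensitivity then lower cutoff."""
    if roc.thresholds.size == 0:
        raise ValueError("ROC result has no candidate cutoffs")
    return _best_youden(roc.thresholds, roc.sensitivity, roc.specificity)


def confusion_metrics(labels, predictions, positive_label=None) -> MetricSet:
    """Sensitivity, specificity, PPV and NPV from paired labels/predictions."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("length mismatch between labels and predictions")
    y = _binarize(labels, positive_label)
    p = _binarize(predictions, positive_label)
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))

    def rate(num, den):
        return num / den if den else float("nan")

    return MetricSet(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        ppv=rate(tp, tp + fp),
        npv=rate(tn, tn + fn),
    )


def metrics_from_rates(sensitivity: float, specificity: float, n_pos: int, n_neg: int) -> MetricSet:
    """Recover PPV/NPV from published sensitivity/specificity and class sizes.

    PPV = se*n_pos / (se*n_pos + (1-sp)*n_neg);
    NPV = sp*n_neg / (sp*n_neg + (1-se)*n_pos).
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    tp = sensitivity * n_pos
    fn = (1.0 - sensitivity) * n_pos
    tn = specificity * n_neg
    fp = (1.0 - specificity) * n_neg
    if tp + fp == 0 or tn + fn == 0:
        raise ValueError("undefined predictive value")
    return MetricSet(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=tp / (tp + fp),
        npv=tn / (tn + fn),
    )


def compare_roc_paired(scores_a, scores_b, labels, positive_label=None):
    """DeLong paired test comparing two AUCs on the same samples.

    Returns ``(auc_a, auc_b, p_value)``; symmetric in the two score vectors.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have the same length")
    y = _binarize(_validate_binary(labels), positive_label)
    va_p, va_n, auc_a = _placements(scores_a, y)
    vb_p, vb_n, auc_b = _placements(scores_b, y)
    m, n = va_p.size, va_n.size
    if m > 1:
        s10 = np.cov(np.vstack([va_p, vb_p]))
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([va_n, vb_n]))
    else:
        s01 = np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / math.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, min(max(p, np.finfo(float).tiny), 1.0)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def contingency_summary(samples: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Trajectory x histology count and percent tables.

    Percentages are within-column (per trajectory, plus overall), rounded
    half-up to integers as in the published layout.  Returns a dict with
    ``counts`` (including an ``overall`` column and a ``total`` row) and
    ``percent``.
    """
    if len(samples) == 0:
        raise ValueError("samples table is empty")
    counts = pd.crosstab(samples["histology"], samples["trajectory"])
    counts.insert(0, "overall", counts.sum(axis=1))
    counts.loc["total"] = counts.sum(axis=0)
    percent = counts.drop(index="total").copy()
    for col in percent.columns:
        total = counts.loc["total", col]
        percent[col] = [
            _round_half_up(100.0 * v / total) if total else 0 for v in percent[col]
        ]
    return {"counts": counts, "percent": percent}
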
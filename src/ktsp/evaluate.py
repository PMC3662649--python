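"""Validation metrics: confusion statistics, ROC/AUC, Kaplan-Meier, log-rank.

Poor prognosis is the positive class everywhere: sensitivity is the
fraction of poor-prognosis samples called poor, specificity the
fraction of good-prognosis samples called good.

Two independent AUC routes are exposed on purpose.  The trapezoidal
area under the threshold-enumerated ROC computed here must agree (to
numerical identity) with the Mann-Whitney form in
:func:`ktsp.builder.resubstitution_auc`; the test suite asserts the
identity on random inputs.

The survival estimators are the textbook forms: the product-limit
(Kaplan-Meier) estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i) over
event times, and the two-group log-rank statistic (O - E)^2 / V with
hypergeometric variance, referred to chi-square with one degree of
freedom.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2

from .core import (
    GOOD,
    POOR,
    AlignmentError,
    DegenerateInputError,
    PerformanceReport,
    SurvivalRecords,
)
from .builder import resubstitution_auc


def confusion_metrics(
    predicted: Sequence[str], truth: Sequence[str]
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with poor as the positive class."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise AlignmentError(
            f"{len(predicted)} predictions for {len(truth)} true labels"
        )
    pos = truth == POOR
    neg = truth == GOOD
    if not np.all(pos | neg):
        raise ValueError("true labels must be 'poor' or 'good'")
    if pos.sum() == 0 or neg.sum() == 0:
        raise DegenerateInputError("both classes needed for sensitivity/specificity")
    tp = int(((predicted == POOR) & pos).sum())
    tn = int(((predicted == GOOD) & neg).sum())
    sens = tp / int(pos.sum())
    spec = tn / int(neg.sum())
    acc = (tp + tn) / len(truth)
    return sens, spec, acc


def roc_points(
    scores: np.ndarray, labels: np.ndarray
) -> list[tuple[float, float, float]]:
    """ROC over all integer vote thresholds, as (threshold, tpr, fpr).

    Thresholds run from max(score)+1 down to 0, so the curve starts at
    (0, 0) and ends at (1, 1); a sample is called poor when its score
    is >= the threshold.
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels, dtype=object)
    pos = labels == POOR
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("ROC needs both classes present")
    pts = []
    for tau in range(int(scores.max()) + 1, -1, -1):
        call = scores >= tau
        tpr = float(call[pos].sum() / n_pos)
        fpr = float(call[~pos].sum() / n_neg)
        pts.append((float(tau), tpr, fpr))
    return pts


def roc_and_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC point list and its trapezoidal area."""
    pts = roc_points(scores, labels)
    tpr = np.array([p[1] for p in pts])
    fpr = np.array([p[2] for p in pts])
    auc = float(np.trapezoid(tpr, fpr))
    return pts, auc


def auc_bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, stratified by class.

    Each replicate resamples the poor and good samples separately with
    replacement (keeping both class sizes fixed) and recomputes the
    Mann-Whitney AUC.  Deterministic given ``seed``.
    """
    if not (0 < level < 1):
        raise ValueError("confidence level must lie in (0, 1)")
    if seed is None:
        raise ValueError("a seed is required so the interval is reproducible")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos_idx = np.flatnonzero(labels == POOR)
    neg_idx = np.flatnonzero(labels == GOOD)
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise DegenerateInputError("bootstrap CI needs >= 2 samples per class")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        g = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([p, g])
        stats[b] = resubstitution_auc(scores[idx], labels[idx])
    alpha = 1 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def kaplan_meier(records: SurvivalRecords) -> list[tuple[float, float]]:
    """Product-limit survival estimate for one group.

    Returns the right-continuous step function as (event time, S(t))
    pairs at each distinct event time; S is 1 before the first event.
    Censored times shrink the risk set without producing a step.
    """
    time = records.time
    event = records.event
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    steps: list[tuple[float, float]] = []
    s = 1.0
    for t in np.unique(time[event == 1]):
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_at_risk
        steps.append((float(t), s))
    return steps


def logrank_test(
    records: SurvivalRecords, groups: Sequence[str]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    At each distinct event time the observed number of group-1 events
    is compared with its hypergeometric expectation given the risk
    sets; the squared standardised sum is referred to chi-square with
    one degree of freedom.
    """
    groups = np.asarray(groups, dtype=object)
    if groups.shape != records.time.shape:
        raise AlignmentError("group labels not aligned with survival records")
    names = sorted(set(groups))
    if len(names) != 2:
        raise DegenerateInputError(f"log-rank needs exactly two groups, got {names}")
    in1 = groups == names[0]
    time, event = records.time, records.event
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        d1 = int((dead & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, df=1))


def evaluate_predictions(
    scores: np.ndarray,
    predicted: Sequence[str],
    truth: Sequence[str],
    survival: Optional[SurvivalRecords] = None,
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
) -> PerformanceReport:
    """Assemble a full performance report for one validation run.

    The log-rank comparison, when survival records are given, contrasts
    the *predicted* poor and good groups — the clinically relevant
    question of whether the classifier separates survival curves.
    The bootstrap CI is attached only when a seed is supplied.
    """
    sens, spec, acc = confusion_metrics(predicted, truth)
    pts, auc = roc_and_auc(np.asarray(scores), np.asarray(truth, dtype=object))
    ci = None
    if seed is not None:
        ci = auc_bootstrap_ci(scores, np.asarray(truth, dtype=object),
                              level=ci_level, n_boot=n_boot, seed=seed)
    lr = None
    if survival is not None:
        lr = logrank_test(survival, predicted)
    return PerformanceReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        roc=pts,
        auc=auc,
        auc_ci=ci,
        auc_ci_level=ci_level if ci is not None else None,
        logrank=lr,
    )
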
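"""Greedy K-TSP construction and data-driven choice of K and the vote threshold.

The builder selects K gene-disjoint top-scoring pairs greedily: take
the top-ranked pair, remove its two genes from the candidate set, take
the top pair among the remaining genes, and so on.  Because a pair's
delta and gamma depend only on its own two genes, removing genes never
re-scores surviving pairs, so the greedy walk down the ranked list is
exactly equivalent to re-scoring after each removal.

K and the integer vote threshold tau are chosen by resubstitution on
the training cohort: among all candidate K in a configured window and
all tau with training sensitivity exactly 100% (every poor-prognosis
sample scores >= tau), pick the combination that maximises training
specificity.  Resubstitution is used for model selection only — the
vote scores are sums of binary comparisons, leaving little room to
overfit — and never as a performance claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import (
    POOR,
    CapacityError,
    DegenerateInputError,
    ExpressionMatrix,
    KTSPModel,
    LabeledCohort,
    ModelSelectionError,
    ScoredPair,
)
from .scoring import score_all_pairs


def select_disjoint_pairs(cohort: LabeledCohort, k_max: int) -> list[ScoredPair]:
    """Pick the first ``k_max`` gene-disjoint pairs in ranked order.

    Pair i+1 is the top-ranked pair once all genes of pairs 1..i are
    removed from the candidate set.
    """
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    if 2 * k_max > cohort.matrix.n_genes:
        raise CapacityError(
            f"{k_max} disjoint pairs need {2 * k_max} genes; "
            f"matrix has {cohort.matrix.n_genes}"
        )
    ranked = score_all_pairs(cohort)
    chosen: list[ScoredPair] = []
    used: set[str] = set()
    for pair in ranked:
        if pair.genes & used:
            continue
        chosen.append(pair)
        used |= pair.genes
        if len(chosen) == k_max:
            break
    return chosen


def prognostic_scores(
    data: LabeledCohort | ExpressionMatrix, pairs: Sequence[ScoredPair]
) -> np.ndarray:
    """Per-sample vote count: number of pairs matching their poor orientation."""
    matrix = data.matrix if isinstance(data, LabeledCohort) else data
    scores = np.zeros(matrix.n_samples, dtype=int)
    for pair in pairs:
        a = matrix.gene_row(pair.gene_a)
        b = matrix.gene_row(pair.gene_b)
        if pair.orientation == "lt":
            scores += (a < b).astype(int)
        elif pair.orientation == "gt":
            scores += (a > b).astype(int)
        # "none": the pair never votes poor
    return scores


def resubstitution_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC of integer vote scores via the normalised Mann-Whitney statistic.

    Equals the probability that a random poor sample scores above a
    random good one, counting ties one-half; identical to the area
    under the ROC curve enumerated over all integer thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    poor = labels == POOR
    n_pos = int(poor.sum())
    n_neg = int((~poor).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("AUC needs both classes present")
    ranks = rankdata(scores, method="average")
    u = ranks[poor].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auc_curve(
    cohort: LabeledCohort, k_values: Iterable[int] = range(1, 16)
) -> list[tuple[int, float]]:
    """Resubstitution AUC of the first K disjoint pairs for each K.

    The curve typically rises with K, peaks, then decays as weak pairs
    dilute the vote; it is exported for inspection of the peak region
    and plays no direct part in model selection.
    """
    ks = sorted(set(int(k) for k in k_values))
    pairs = select_disjoint_pairs(cohort, max(ks))
    out = []
    for k in ks:
        scores = prognostic_scores(cohort, pairs[:k])
        out.append((k, resubstitution_auc(scores, cohort.labels)))
    return out


@dataclass
class SelectionDiagnostics:
    """Per-candidate grid of the (K, tau) search, for reporting failures."""

    k_values: list[int]
    min_poor_score: dict[int, int]  # K -> lowest vote score among poor samples

    def __str__(self) -> str:
        rows = ", ".join(
            f"K={k}: min poor score {self.min_poor_score[k]}" for k in self.k_values
        )
        return f"no threshold reaches 100% sensitivity ({rows})"


def select_k_and_threshold(
    cohort: LabeledCohort,
    k_range: tuple[int, int] = (6, 10),
    metadata: dict | None = None,
) -> KTSPModel:
    """Choose (K, tau) maximising specificity at 100% training sensitivity.

    For each K in the inclusive window ``k_range`` the training cohort
    is scored with the first K disjoint pairs; thresholds tau in
    [1, K] are admissible when every poor sample scores >= tau.  Among
    admissible candidates the pair (K, tau) with the highest training
    specificity wins; ties prefer the smallest K (parsimony), then the
    largest tau.

    Raises
    ------
    ModelSelectionError
        If some poor-prognosis sample scores zero for every K, so no
        threshold can reach 100% sensitivity; the message carries the
        per-K minimum poor score for diagnosis.
    """
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if not (1 <= k_min <= k_max):
        raise ValueError(f"invalid k_range {k_range}")
    cohort.require_both_classes()
    pairs = select_disjoint_pairs(cohort, k_max)
    poor = cohort.poor_mask
    best: tuple[float, int, int] | None = None  # (specificity, -K... ) handled below
    min_poor: dict[int, int] = {}
    for k in range(k_min, k_max + 1):
        scores = prognostic_scores(cohort, pairs[:k])
        lo = int(scores[poor].min())
        min_poor[k] = lo
        if lo < 1:
            continue  # no tau in [1, k] keeps sensitivity at 1.0
        for tau in range(1, min(lo, k) + 1):
            spec = float((scores[~poor] < tau).mean())
            cand = (spec, -k, tau)
            if best is None or cand > best:
                best = cand
    if best is None:
        raise ModelSelectionError(
            str(SelectionDiagnostics(list(range(k_min, k_max + 1)), min_poor))
        )
    spec, neg_k, tau = best
    k = -neg_k
    meta = dict(metadata or {})
    meta.setdefault("k_range", [k_min, k_max])
    meta["training_specificity"] = spec
    return KTSPModel(pairs=pairs[:k], threshold=tau, metadata=meta)
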
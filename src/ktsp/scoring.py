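"""Pair scoring: how consistently a gene pair switches ordering between classes.

For a pair (a, b) the switch score is

    delta(a, b) = | P(expr(a) < expr(b) | poor) - P(expr(a) < expr(b) | good) |

with empirical class-conditional proportions and strict comparison, so a
tie between the two expression values counts as "not less than".  The
score reads only the within-sample ordering of the two genes, which is
what makes the resulting classifier invariant to any preprocessing that
preserves the ordering of expression levels within each sample profile.

Ties in delta are broken by a secondary rank score gamma — the absolute
between-class difference of the mean within-sample rank difference of
the two genes — and finally lexicographically by gene identifiers, so
the ranked pair list is a deterministic total order.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .core import (
    DegenerateInputError,
    LabeledCohort,
    Orientation,
    ScoredPair,
)


def ordering_counts(
    cohort: LabeledCohort, gene_a: str, gene_b: str
) -> tuple[int, int, int, int]:
    """Count strict orderings expr(gene_a) < expr(gene_b) per class.

    Returns ``(n_lt_poor, n_poor, n_lt_good, n_good)``: the number of
    poor-class samples in which gene_a is expressed strictly below
    gene_b, the poor class size, and the same two quantities for the
    good class.  Tied values are not counted as "less than".
    """
    cohort.require_both_classes()
    a = cohort.matrix.gene_row(gene_a)
    b = cohort.matrix.gene_row(gene_b)
    lt = a < b
    poor = cohort.poor_mask
    return (
        int(lt[poor].sum()),
        int(poor.sum()),
        int(lt[~poor].sum()),
        int((~poor).sum()),
    )


def pair_delta(counts: tuple[int, int, int, int]) -> float:
    """Switch score from ordering counts: |p_poor - p_good|, in [0, 1]."""
    n_lt_poor, n_poor, n_lt_good, n_good = counts
    if n_poor == 0 or n_good == 0:
        raise DegenerateInputError("both class totals must be positive")
    return abs(n_lt_poor / n_poor - n_lt_good / n_good)


def _sample_ranks(values: np.ndarray) -> np.ndarray:
    """Rank each sample's profile (column), average ranks for ties."""
    return rankdata(values, method="average", axis=0)


def pair_gamma(cohort: LabeledCohort, gene_a: str, gene_b: str) -> float:
    """Secondary rank score: between-class shift of the pair's rank gap.

    Within every sample the full profile is ranked (average ranks on
    ties); gamma is |E_poor[rank(a) - rank(b)] - E_good[rank(a) - rank(b)]|.
    Larger gamma means the pair's rank separation moves more between
    classes; it is used only to break exact delta ties.
    """
    cohort.require_both_classes()
    ia, ib = cohort.matrix.gene_indices([gene_a, gene_b])
    ranks = _sample_ranks(cohort.matrix.values)
    diff = ranks[ia] - ranks[ib]
    poor = cohort.poor_mask
    return float(abs(diff[poor].mean() - diff[~poor].mean()))


def _orientation_from_props(p_poor: float, p_good: float) -> Orientation:
    # The ordering observed more often in the poor class (relative to the
    # good class) votes poor; at exact equality the pair never votes poor.
    if p_poor > p_good:
        return "lt"
    if p_poor < p_good:
        return "gt"
    return "none"


def delta_gamma_matrices(cohort: LabeledCohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised delta, gamma and P(row < col | poor) - P(row < col | good).

    Returns ``(delta, gamma, signed)`` arrays of shape (G, G);
    ``signed[i, j]`` keeps the sign so callers can derive orientations.
    Intended for internal use by :func:`score_all_pairs` and the greedy
    pair selector.
    """
    cohort.require_both_classes()
    x = cohort.matrix.values
    poor = cohort.poor_mask
    # lt[i, j, n] == 1 where gene i < gene j in sample n
    lt = (x[:, None, :] < x[None, :, :]).astype(float)
    p_poor = lt[:, :, poor].mean(axis=2)
    p_good = lt[:, :, ~poor].mean(axis=2)
    signed = p_poor - p_good
    ranks = _sample_ranks(x)
    # rank sums are multiples of 0.5 and hence exact in floating point;
    # summing before dividing keeps gamma independent of evaluation order
    sum_poor = ranks[:, poor].sum(axis=1)
    sum_good = ranks[:, ~poor].sum(axis=1)
    n_poor, n_good = int(poor.sum()), int((~poor).sum())
    gamma = np.abs(
        (sum_poor[:, None] - sum_poor[None, :]) / n_poor
        - (sum_good[:, None] - sum_good[None, :]) / n_good
    )
    return np.abs(signed), gamma, signed


def score_all_pairs(cohort: LabeledCohort) -> list[ScoredPair]:
    """Score every unordered gene pair and rank them.

    The returned list has one :class:`ScoredPair` per unordered pair,
    sorted by delta (descending), then gamma (descending), then
    lexicographically by gene identifiers.  Each pair's orientation is
    set so that the ordering more frequent in the poor class votes poor.
    """
    if cohort.matrix.n_genes < 2:
        raise DegenerateInputError("need at least two genes to form a pair")
    delta, gamma, signed = delta_gamma_matrices(cohort)
    genes = cohort.matrix.gene_ids
    order = sorted(range(len(genes)), key=lambda i: genes[i])
    pairs: list[ScoredPair] = []
    for ii in range(len(order)):
        for jj in range(ii + 1, len(order)):
            i, j = order[ii], order[jj]  # genes[i] < genes[j] lexicographically
            pairs.append(
                ScoredPair(
                    gene_a=genes[i],
                    gene_b=genes[j],
                    delta=float(delta[i, j]),
                    gamma=float(gamma[i, j]),
                    orientation=_orientation_from_props(float(signed[i, j]), 0.0),
                )
            )
    pairs.sort(key=lambda p: (-p.delta, -p.gamma, p.gene_a, p.gene_b))
    return pairs
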
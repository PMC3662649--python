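"""Synthetic two-class expression cohorts with planted switching pairs.

The generator emulates the structure the pair-scoring pipeline is built
for: a modest signature-sized gene set (default 70 genes) measured in a
few dozen samples per prognosis class.  Background genes are drawn
i.i.d. from a common continuous distribution, so every background pair
is exchangeable and has expected switch score zero.  A *planted* pair
occupies two reserved gene slots and has its within-sample ordering
forced per sample: with probability ``p_poor`` (in poor samples) or
``p_good`` (in good samples) the first gene is placed below the second.
The two values themselves are drawn from the background distribution
and merely swapped to realise the sampled ordering, so the marginal
value distribution is untouched — only the ordering carries signal,
exactly the feature the classifier reads.

What this does NOT emulate: array intensity scales, probe effects,
between-gene correlation of real transcriptomes, or class-imbalanced
mean shifts.  Passing tests on these cohorts demonstrates algorithmic
correctness, not clinical performance.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import (
    GOOD,
    POOR,
    CapacityError,
    ExpressionMatrix,
    LabeledCohort,
    SurvivalRecords,
)

#: (pair slot, P(a<b | poor), P(a<b | good)); slot i uses genes 2i and 2i+1.
PlantedPair = tuple[int, float, float]


def generate_cohort(
    n_genes: int = 70,
    n_poor: int = 40,
    n_good: int = 40,
    planted: Sequence[PlantedPair] = (),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> LabeledCohort:
    """Simulate a labelled two-class cohort with optional planted pairs.

    Parameters
    ----------
    n_genes, n_poor, n_good:
        Matrix dimensions; defaults mirror a signature-scale study
        (70 genes, 40 samples per class).
    planted:
        Triples ``(slot, p_poor, p_good)``; the pair at slot ``i``
        occupies genes ``2i`` and ``2i + 1`` and its ordering is forced
        per sample at the given class-conditional probabilities.
    noise_sd:
        Standard deviation of extra Gaussian jitter added to background
        (non-planted) genes on top of the standard-normal draw.
    seed:
        Seed for :func:`numpy.random.default_rng`; the same seed yields
        a bit-identical cohort.
    """
    if n_poor < 1 or n_good < 1:
        raise ValueError("each class needs at least one sample")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    slots = [int(s) for s, _, _ in planted]
    if len(set(slots)) != len(slots):
        raise CapacityError("planted pair slots must be distinct")
    for s, pp, pg in planted:
        if 2 * (s + 1) > n_genes:
            raise CapacityError(
                f"planted slot {s} needs gene {2 * s + 1}; matrix has {n_genes} genes"
            )
        if not (0 <= pp <= 1 and 0 <= pg <= 1):
            raise ValueError("planting probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_poor + n_good
    values = rng.standard_normal((n_genes, n))
    poor_mask = np.zeros(n, dtype=bool)
    poor_mask[:n_poor] = True
    planted_rows: set[int] = set()
    for s, pp, pg in planted:
        ia, ib = 2 * s, 2 * s + 1
        planted_rows.update((ia, ib))
        p = np.where(poor_mask, pp, pg)
        want_lt = rng.random(n) < p
        lo = np.minimum(values[ia], values[ib])
        hi = np.maximum(values[ia], values[ib])
        values[ia] = np.where(want_lt, lo, hi)
        values[ib] = np.where(want_lt, hi, lo)
    if noise_sd > 0:
        background = np.array(
            [i for i in range(n_genes) if i not in planted_rows], dtype=int
        )
        if background.size:
            values[background] += rng.normal(
                0.0, noise_sd, size=(background.size, n)
            )
    width = len(str(n_genes))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    sample_ids = [f"S{j:03d}" for j in range(1, n + 1)]
    labels = np.where(poor_mask, POOR, GOOD).astype(object)
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    return LabeledCohort(matrix=matrix, labels=labels)


def planted_gene_ids(n_genes: int, slot: int) -> tuple[str, str]:
    """Gene identifiers occupied by the planted pair at ``slot``."""
    width = len(str(n_genes))
    return f"G{2 * slot + 1:0{width}d}", f"G{2 * slot + 2:0{width}d}"


def generate_survival(
    labels: Sequence[str],
    hazard_ratio: float = 3.0,
    baseline_rate: float = 0.006,
    censor_rate: float = 0.003,
    seed: int | None = None,
) -> SurvivalRecords:
    """Exponential event times with a class-dependent hazard.

    Good-prognosis samples have hazard ``baseline_rate`` (per month;
    the default 0.006 corresponds to a ~10-year median time to event),
    poor-prognosis samples ``baseline_rate * hazard_ratio``.  An
    independent exponential censoring time at ``censor_rate`` is drawn
    per sample; ``censor_rate = 0`` means no censoring, so every event
    is observed.
    """
    if hazard_ratio <= 0 or baseline_rate <= 0:
        raise ValueError("hazard_ratio and baseline_rate must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be non-negative")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    hazard = np.where(labels == POOR, baseline_rate * hazard_ratio, baseline_rate)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=len(labels))
    else:
        censor_time = np.full(len(labels), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return SurvivalRecords(time=time, event=event)
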
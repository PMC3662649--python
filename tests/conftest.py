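import numpy as np
import pytest

from ktsp import ExpressionMatrix, LabeledCohort


@pytest.fixture
def toy_cohort() -> LabeledCohort:
    """Six samples (3 poor, 3 good), four genes with hand-set values.

    For the pair (gA, gB): gA < gB in all poor samples and in exactly
    one good sample, so n_lt = (3, 3, 1, 3) and delta = 2/3.
    gC ties gB in sample S4 to exercise strict-comparison behaviour.
    """
    genes = ["gA", "gB", "gC", "gD"]
    samples = ["S1", "S2", "S3", "S4", "S5", "S6"]
    values = np.array(
        [
            # S1   S2   S3   S4   S5   S6
            [1.0, 2.0, 0.5, 5.0, 4.0, 3.0],  # gA
            [3.0, 4.0, 2.5, 2.0, 6.0, 1.0],  # gB
            [2.0, 1.0, 3.0, 2.0, 5.0, 2.0],  # gC
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],  # gD
        ]
    )
    labels = np.array(["poor", "poor", "poor", "good", "good", "good"], dtype=object)
    return LabeledCohort(ExpressionMatrix(genes, samples, values), labels)


def brute_force_scores(cohort: LabeledCohort) -> dict[tuple[str, str], tuple[float, float, str]]:
    """Independent O(G^2 * N) pair scorer: explicit loops over samples.

    Returns {(gene_a, gene_b) with gene_a < gene_b: (delta, gamma, orientation)}.
    Ranks are recomputed per sample with a naive average-tie rule.
    """
    from scipy.stats import rankdata

    m = cohort.matrix
    poor = cohort.poor_mask
    ranks = np.column_stack(
        [rankdata(m.values[:, j], method="average") for j in range(m.n_samples)]
    )
    out = {}
    for i, ga in enumerate(m.gene_ids):
        for k, gb in enumerate(m.gene_ids):
            if ga >= gb:
                continue
            lt_poor = lt_good = 0
            for j in range(m.n_samples):
                if m.values[i, j] < m.values[k, j]:
                    if poor[j]:
                        lt_poor += 1
                    else:
                        lt_good += 1
            p_poor = lt_poor / poor.sum()
            p_good = lt_good / (~poor).sum()
            delta = abs(p_poor - p_good)
            diff = ranks[i] - ranks[k]
            gamma = abs(diff[poor].mean() - diff[~poor].mean())
            if p_poor > p_good:
                orient = "lt"
            elif p_poor < p_good:
                orient = "gt"
            else:
                orient = "none"
            out[(ga, gb)] = (delta, gamma, orient)
    return out


def brute_force_ranked(cohort: LabeledCohort) -> list[tuple[str, str]]:
    """Ranked pair list from the brute-force scorer, spec tie-break order."""
    scored = brute_force_scores(cohort)
    return sorted(scored, key=lambda p: (-scored[p][0], -scored[p][1], p[0], p[1]))


def random_cohort(rng: np.random.Generator, n_genes: int, n_samples: int) -> LabeledCohort:
    """Small random cohort with at least one sample per class."""
    values = rng.normal(size=(n_genes, n_samples))
    n_poor = int(rng.integers(1, n_samples))
    labels = np.array(
        ["poor"] * n_poor + ["good"] * (n_samples - n_poor), dtype=object
    )
    genes = [f"g{i:02d}" for i in range(n_genes)]
    samples = [f"s{j:02d}" for j in range(n_samples)]
    return LabeledCohort(ExpressionMatrix(genes, samples, values), labels)
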
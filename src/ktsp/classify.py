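"""Apply a trained K-TSP model to new expression profiles.

Each pair casts one vote by comparing its two genes within the sample;
the sample is called poor prognosis when the number of poor votes
reaches the model's threshold.  Only within-sample orderings are read,
so predictions are invariant to any strictly increasing transformation
of a sample's profile (rescaling, log, rank normalisation, ...).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    GOOD,
    POOR,
    ExpressionMatrix,
    IdentifierError,
    KTSPModel,
    LabeledCohort,
    ScoredPair,
)
from .builder import prognostic_scores


def pair_vote(profile: Mapping[str, float], pair: ScoredPair) -> str:
    """Vote of one pair on one sample profile: ``"poor"`` or ``"good"``.

    The vote is poor iff the observed strict ordering of the two genes
    matches the pair's poor orientation; a tie always votes good.
    """
    try:
        a = profile[pair.gene_a]
        b = profile[pair.gene_b]
    except KeyError as exc:
        raise IdentifierError(f"profile is missing gene {exc.args[0]!r}") from None
    if pair.orientation == "lt":
        return POOR if a < b else GOOD
    if pair.orientation == "gt":
        return POOR if a > b else GOOD
    return GOOD


def predict(
    data: ExpressionMatrix | LabeledCohort, model: KTSPModel
) -> pd.DataFrame:
    """Score and classify every sample of an expression matrix.

    The matrix may contain genes beyond the model's (real assay exports
    carry the full signature); rows are matched by gene identifier and
    every model gene must be present.  Returns a DataFrame indexed by
    sample id with integer ``score`` in [0, K] and ``label`` equal to
    ``"poor"`` iff score >= the model threshold.
    """
    matrix = data.matrix if isinstance(data, LabeledCohort) else data
    matrix.gene_indices(model.genes)  # fail early, listing absent genes
    scores = prognostic_scores(matrix, model.pairs)
    labels = np.where(scores >= model.threshold, POOR, GOOD)
    return pd.DataFrame(
        {"score": scores, "label": labels},
        index=pd.Index(matrix.sample_ids, name="sample_id"),
    )
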
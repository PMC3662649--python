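"""Core domain types for K-TSP classifier development.

The K-TSP (K top-scoring pairs) method builds a prognostic classifier
from an expression matrix by selecting gene pairs whose within-sample
expression ordering switches between two outcome classes.  The types
here carry the data through the pipeline: an :class:`ExpressionMatrix`,
a :class:`LabeledCohort` used for training and validation, the
:class:`ScoredPair` produced by pair scoring, the trained
:class:`KTSPModel` and a :class:`PerformanceReport` summarising
validation results.

Conventions used throughout the package:

* the positive class is ``"poor"`` prognosis (recurrence within five
  years) and the negative class is ``"good"``;
* expression values must be finite; missing values are a load-time
  error, never imputed, because imputation would silently alter
  within-sample rankings;
* all comparisons between two expression values are strict (``<``), so
  tied values never produce a poor-prognosis vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

POOR = "poor"
GOOD = "good"

#: How a pair votes: ``"lt"`` means observing expr(gene_a) < expr(gene_b)
#: votes poor; ``"gt"`` means the reverse ordering votes poor; ``"none"``
#: (only possible at delta == 0) means the pair never votes poor.
Orientation = Literal["lt", "gt", "none"]


class KTSPError(Exception):
    """Base class for all package errors."""


class IdentifierError(KTSPError):
    """An unknown or duplicated gene/sample identifier."""


class DegenerateInputError(KTSPError):
    """Input that makes the requested statistic undefined (e.g. an empty class)."""


class CapacityError(KTSPError):
    """Not enough genes to satisfy the request (e.g. 2*k_max > n_genes)."""


class AlignmentError(KTSPError):
    """Phenotype and expression sample sets do not match."""


class ParseError(KTSPError):
    """A malformed input file; message includes the offending line where known."""


class ModelFormatError(KTSPError):
    """A model file violating the expected JSON schema."""


class ModelSelectionError(KTSPError):
    """No (K, tau) candidate satisfies the 100%-sensitivity constraint."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise IdentifierError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of real-valued expression measurements.

    Parameters
    ----------
    gene_ids:
        Unique gene identifiers (row labels).
    sample_ids:
        Unique sample identifiers (column labels).
    values:
        Array of shape ``(len(gene_ids), len(sample_ids))``; every entry
        must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}; "
                "missing values must be resolved before loading"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene_id: str) -> np.ndarray:
        """Expression of one gene across all samples."""
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise IdentifierError(f"unknown gene identifier: {gene_id!r}") from None

    def gene_indices(self, gene_ids: Sequence[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self._gene_index]
        if missing:
            raise IdentifierError(
                "genes absent from expression matrix: " + ", ".join(sorted(missing))
            )
        return np.array([self._gene_index[g] for g in gene_ids], dtype=int)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame with genes as the index, samples as columns."""
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SurvivalRecords:
    """Right-censored follow-up per sample: time in months and event flag."""

    time: np.ndarray  # months, >= 0
    event: np.ndarray  # 1 = recurrence/death observed, 0 = censored

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have the same length")
        if np.any(self.time < 0):
            raise ValueError("survival times must be non-negative")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")


@dataclass
class LabeledCohort:
    """An expression matrix with per-sample prognosis labels.

    ``labels`` is aligned with ``matrix.sample_ids`` and holds the
    literal strings ``"poor"`` / ``"good"``.  Optional survival records
    (also sample-aligned) enable Kaplan-Meier / log-rank validation.
    """

    matrix: ExpressionMatrix
    labels: np.ndarray
    survival: Optional[SurvivalRecords] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.matrix.n_samples,):
            raise AlignmentError(
                f"{len(self.labels)} labels for {self.matrix.n_samples} samples"
            )
        bad = sorted({l for l in self.labels} - {POOR, GOOD})
        if bad:
            raise ValueError(f"labels must be 'poor' or 'good'; got {bad}")
        if self.survival is not None and len(self.survival.time) != self.matrix.n_samples:
            raise AlignmentError("survival records not aligned with samples")

    @property
    def poor_mask(self) -> np.ndarray:
        return self.labels == POOR

    @property
    def n_poor(self) -> int:
        return int(self.poor_mask.sum())

    @property
    def n_good(self) -> int:
        return int((~self.poor_mask).sum())

    def require_both_classes(self) -> None:
        if self.n_poor == 0 or self.n_good == 0:
            raise DegenerateInputError(
                f"both classes required: {self.n_poor} poor, {self.n_good} good"
            )


@dataclass(frozen=True)
class ScoredPair:
    """An unordered gene pair with its switch score and vote orientation.

    ``delta`` is the switch score |P(a<b | poor) - P(a<b | good)| with
    empirical class-conditional proportions; ``gamma`` is the secondary
    rank-difference score used only to break delta ties.  The pair is
    stored with ``gene_a < gene_b`` lexicographically.
    """

    gene_a: str
    gene_b: str
    delta: float
    gamma: float
    orientation: Orientation

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a pair must consist of two distinct genes")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"delta must lie in [0, 1]; got {self.delta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative; got {self.gamma}")
        if self.orientation not in ("lt", "gt", "none"):
            raise ValueError(f"invalid orientation: {self.orientation!r}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class KTSPModel:
    """A trained K-TSP classifier: K gene-disjoint pairs and a vote threshold.

    A sample's prognostic score is the number of pairs whose observed
    ordering matches their poor orientation; the sample is called poor
    prognosis when score >= ``threshold``.
    """

    pairs: list[ScoredPair]
    threshold: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        used: set[str] = set()
        for p in self.pairs:
            overlap = used & p.genes
            if overlap:
                raise ValueError(
                    "pairs must be gene-disjoint; repeated gene(s): "
                    + ", ".join(sorted(overlap))
                )
            used |= p.genes
        if not (1 <= self.threshold <= max(len(self.pairs), 1)):
            raise ValueError(
                f"threshold must lie in [1, {len(self.pairs)}]; got {self.threshold}"
            )

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        """The 2K distinct genes of the model, in pair order."""
        out: list[str] = []
        for p in self.pairs:
            out.extend((p.gene_a, p.gene_b))
        return out


@dataclass
class PerformanceReport:
    """Validation summary: confusion metrics, ROC/AUC and optional survival test."""

    sensitivity: float
    specificity: float
    accuracy: float
    roc: list[tuple[float, float, float]]  # (threshold, tpr, fpr)
    auc: float
    auc_ci: Optional[tuple[float, float]] = None
    auc_ci_level: Optional[float] = None
    logrank: Optional[tuple[float, float]] = None  # (chi-square, p-value)

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "roc": [list(p) for p in self.roc],
        }
        if self.auc_ci is not None:
            d["auc_ci"] = list(self.auc_ci)
            d["auc_ci_level"] = self.auc_ci_level
        if self.logrank is not None:
            d["logrank_chisq"] = self.logrank[0]
            d["logrank_p"] = self.logrank[1]
        return d

    def to_text(self) -> str:
        lines = [
            "Performance report (positive class = poor prognosis)",
            f"  sensitivity : {self.sensitivity:.3f}",
            f"  specificity : {self.specificity:.3f}",
            f"  accuracy    : {self.accuracy:.3f}",
            f"  AUC         : {self.auc:.3f}",
        ]
        if self.auc_ci is not None:
            lo, hi = self.auc_ci
            lines.append(
                f"  AUC {100 * (self.auc_ci_level or 0.95):.0f}% CI  : ({lo:.3f}, {hi:.3f})"
            )
        if self.logrank is not None:
            chisq, p = self.logrank
            lines.append(f"  log-rank    : chi2 = {chisq:.3f}, p = {p:.3g}")
        return "\n".join(lines)
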
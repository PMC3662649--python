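"""File formats: tab-delimited expression matrices, CSV phenotypes, JSON models.

Formats are deliberately plain text so every artefact of a study —
inputs, trained model, report — is human-auditable and diff-able:

* expression matrix: tab-delimited, first column gene ids, header row
  of sample ids, numeric body (genes as rows, the transcriptomics
  convention);
* phenotypes: CSV with columns ``sample_id``, ``label`` (the literal
  strings ``poor`` / ``good``) and optional ``time_months``, ``event``;
* model: JSON listing the ordered pairs with their orientations and
  scores, K, the vote threshold, and training metadata.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    GOOD,
    POOR,
    AlignmentError,
    ExpressionMatrix,
    IdentifierError,
    KTSPModel,
    LabeledCohort,
    ModelFormatError,
    ParseError,
    PerformanceReport,
    ScoredPair,
    SurvivalRecords,
)

MODEL_SCHEMA_VERSION = 1


def read_expression_matrix(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited genes x samples matrix.

    Set ``transpose=True`` for samples-as-rows files.  Malformed input
    (ragged rows, non-numeric cells, duplicate identifiers) raises
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if len(rows) < 2:
        raise ParseError(f"{path}: expected a header line and at least one data row")
    header = rows[0]
    sample_ids = [c.strip() for c in header[1:]]
    gene_ids: list[str] = []
    values: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(header):
            raise ParseError(
                f"{path}, line {lineno}: {len(row)} fields, expected {len(header)}"
            )
        gene_ids.append(row[0].strip())
        parsed = []
        for col, cell in enumerate(row[1:], start=2):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}, field {col}: "
                    f"non-numeric value {cell!r}"
                ) from None
        values.append(parsed)
    try:
        matrix = ExpressionMatrix(gene_ids, sample_ids, np.array(values))
    except (IdentifierError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    if transpose:
        matrix = ExpressionMatrix(
            gene_ids=matrix.sample_ids,
            sample_ids=matrix.gene_ids,
            values=matrix.values.T,
        )
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix in the same tab-delimited layout, full precision."""
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_phenotypes(
    path: str | Path,
) -> tuple[pd.Series, Optional[pd.DataFrame]]:
    """Read the phenotype CSV.

    Returns ``(labels, survival)``: a Series of 'poor'/'good' indexed
    by sample id, and a DataFrame with ``time_months``/``event``
    columns or None when the file has no survival columns.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype={"sample_id": str})
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from None
    required = {"sample_id", "label"}
    if not required <= set(table.columns):
        raise ParseError(
            f"{path}: phenotype file needs columns sample_id,label; "
            f"found {list(table.columns)}"
        )
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    bad = sorted(set(table["label"]) - {POOR, GOOD})
    if bad:
        raise ParseError(
            f"{path}: unknown label token(s) {bad}; labels must be "
            f"'{POOR}' or '{GOOD}'"
        )
    labels = pd.Series(
        table["label"].to_numpy(dtype=object),
        index=pd.Index(table["sample_id"], name="sample_id"),
    )
    survival = None
    if {"time_months", "event"} <= set(table.columns):
        survival = table.set_index("sample_id")[["time_months", "event"]].astype(float)
    return labels, survival


def assemble_cohort(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    survival: Optional[pd.DataFrame] = None,
) -> LabeledCohort:
    """Align phenotype rows to the matrix's sample order and build a cohort.

    Samples present in only one of the two inputs raise
    :class:`AlignmentError` listing the offending identifiers.
    """
    matrix_samples = set(matrix.sample_ids)
    pheno_samples = set(labels.index)
    missing = sorted(matrix_samples - pheno_samples)
    extra = sorted(pheno_samples - matrix_samples)
    if missing or extra:
        parts = []
        if missing:
            parts.append("samples without phenotype: " + ", ".join(missing))
        if extra:
            parts.append("phenotype samples absent from matrix: " + ", ".join(extra))
        raise AlignmentError("; ".join(parts))
    aligned = labels.reindex(matrix.sample_ids)
    records = None
    if survival is not None:
        surv = survival.reindex(matrix.sample_ids)
        records = SurvivalRecords(
            time=surv["time_months"].to_numpy(dtype=float),
            event=surv["event"].to_numpy(dtype=int),
        )
    return LabeledCohort(matrix=matrix, labels=aligned.to_numpy(dtype=object),
                         survival=records)


def write_phenotypes(
    cohort: LabeledCohort, path: str | Path
) -> None:
    table = pd.DataFrame(
        {"sample_id": cohort.matrix.sample_ids, "label": cohort.labels}
    )
    if cohort.survival is not None:
        table["time_months"] = cohort.survival.time
        table["event"] = cohort.survival.event
    table.to_csv(path, index=False)


def write_model(model: KTSPModel, path: str | Path) -> None:
    """Serialise a model to JSON (pairs in selection order, K, threshold)."""
    doc = {
        "format": "ktsp-model",
        "schema_version": MODEL_SCHEMA_VERSION,
        "software_version": __version__,
        "k": model.k,
        "threshold": model.threshold,
        "pairs": [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "delta": p.delta,
                "gamma": p.gamma,
                "orientation": p.orientation,
            }
            for p in model.pairs
        ],
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_model(path: str | Path) -> KTSPModel:
    """Load a model JSON; schema violations raise :class:`ModelFormatError`."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: invalid JSON ({exc})") from None
    if not isinstance(doc, dict) or doc.get("format") != "ktsp-model":
        raise ModelFormatError(f"{path}: not a ktsp-model file")
    for key in ("k", "threshold", "pairs"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing required field {key!r}")
    try:
        pairs = [
            ScoredPair(
                gene_a=str(p["gene_a"]),
                gene_b=str(p["gene_b"]),
                delta=float(p["delta"]),
                gamma=float(p["gamma"]),
                orientation=p["orientation"],
            )
            for p in doc["pairs"]
        ]
        model = KTSPModel(
            pairs=pairs,
            threshold=int(doc["threshold"]),
            metadata=dict(doc.get("metadata", {})),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: malformed model ({exc})") from None
    if model.k != int(doc["k"]):
        raise ModelFormatError(
            f"{path}: k = {doc['k']} but {model.k} pairs listed"
        )
    return model


def write_report(
    report: PerformanceReport,
    json_path: str | Path | None = None,
    text_path: str | Path | None = None,
    roc_csv_path: str | Path | None = None,
) -> None:
    """Emit a report as JSON and/or a text table, optionally ROC points as CSV."""
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    if text_path is not None:
        Path(text_path).write_text(report.to_text() + "\n")
    if roc_csv_path is not None:
        pd.DataFrame(report.roc, columns=["threshold", "tpr", "fpr"]).to_csv(
            roc_csv_path, index=False
        )
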
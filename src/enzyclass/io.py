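"""Readers and writers: FASTA input, annotation tables, prediction TSV output."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .ec import ECNumber, parse_ec
from .records import PredictionResult, ProteinRecord, sanitize_sequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
    "write_annotation_table",
    "write_predictions_tsv",
]

PREDICTION_COLUMNS = [
    "protein_id",
    "main_class",
    "subclass",
    "sub_subclass",
    "substrate_class",
    "label",
    "confidence",
]


def read_fasta(path: str | Path, *, policy: str = "mask") -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    The record id is the first whitespace-delimited token of the header.
    Non-canonical residues are handled per ``policy`` (see
    :func:`~enzyclass.records.sanitize_sequence`).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ValueError(f"{path}: line 1: malformed FASTA (expected '>')")
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = sanitize_sequence(str(entry.seq), policy=policy, name=entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_annotation_table(
    path: str | Path, records: list[ProteinRecord] | None = None
) -> list[ProteinRecord] | pd.DataFrame:
    """Read a protein annotation table (TSV).

    Columns: ``protein_id``, ``ec`` (comma-separated EC strings, empty for
    non-enzymes), ``annotation_score`` (1-5, may be empty), ``is_enzyme``
    (0/1, may be empty = unknown).  If ``records`` is given, annotations are
    attached in place (matching on id) and the updated list is returned;
    otherwise the raw DataFrame is returned.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "ec": str})
    required = {"protein_id", "ec", "annotation_score", "is_enzyme"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if records is None:
        return df
    by_id = {r.id: r for r in records}
    for row in df.itertuples(index=False):
        rec = by_id.get(row.protein_id)
        if rec is None:
            continue
        ecs: set[ECNumber] = set()
        if isinstance(row.ec, str) and row.ec.strip():
            for tok in row.ec.split(","):
                ecs.add(parse_ec(tok))
        rec.ec_annotations = ecs
        if not pd.isna(row.annotation_score):
            rec.annotation_score = int(row.annotation_score)
        if not pd.isna(row.is_enzyme):
            rec.is_enzyme = bool(int(row.is_enzyme))
    return records


def write_annotation_table(records: Iterable[ProteinRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "protein_id": rec.id,
                "ec": ",".join(str(e) for e in sorted(rec.ec_annotations)),
                "annotation_score": rec.annotation_score,
                "is_enzyme": None if rec.is_enzyme is None else int(rec.is_enzyme),
            }
        )
    pd.DataFrame(rows, columns=["protein_id", "ec", "annotation_score", "is_enzyme"]).to_csv(
        path, sep="\t", index=False
    )


def write_predictions_tsv(
    results: Iterable[PredictionResult], path: str | Path, *, soft_limit: int = 20
) -> None:
    """Write prediction results as a TSV.

    One row per query: protein id, the four EC components of the predicted
    path ("-" where unspecified or non-enzyme), the final label, and the
    ensemble confidence.  Header always present.
    """
    results = list(results)
    if len(results) > soft_limit:
        warnings.warn(
            f"writing {len(results)} predictions (legacy tools capped input at "
            f"{soft_limit} sequences per file; no limit is enforced here)"
        )
    rows = []
    for res in results:
        ec = res.predicted_ec
        comps = ["-"] * 4
        if ec is not None:
            for i, c in enumerate(ec.components):
                comps[i] = "-" if c is None else str(c)
        rows.append(
            {
                "protein_id": res.protein_id,
                "main_class": comps[0],
                "subclass": comps[1],
                "sub_subclass": comps[2],
                "substrate_class": comps[3],
                "label": res.label,
                "confidence": f"{res.confidence:.4f}",
            }
        )
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> dict[str, ECNumber | None]:
    """Read an annotation table as an evaluation truth map.

    Returns id -> ECNumber (deepest annotation) for enzymes, id -> None for
    non-enzymes.  Multi-EC proteins map to an arbitrary-but-deterministic
    (sorted-first) annotation; the dataset builder discards them before
    training, but they may still appear in test sets.
    """
    df = read_annotation_table(path)
    truth: dict[str, ECNumber | None] = {}
    for row in df.itertuples(index=False):
        if isinstance(row.ec, str) and row.ec.strip():
            ecs = sorted(parse_ec(tok) for tok in row.ec.split(","))
            truth[row.protein_id] = ecs[-1]
        else:
            truth[row.protein_id] = None
    return truth
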
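"""FASTA and TSV ingest/export.

FASTA parsing goes through Biopython's ``SeqIO``; any ``>id [description]``
header convention is accepted and only the first whitespace-delimited token is
used as the identifier. Abundance tables are tab-delimited with a header row,
UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import os
from typing import Optional, Union

import pandas as pd
from Bio import SeqIO

from .records import QuerySet, SeqRecord, normalize_sequence

PathLike = Union[str, os.PathLike]


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


def read_fasta(path: PathLike, name: Optional[str] = None) -> QuerySet:
    """Read a FASTA file into a :class:`QuerySet` of normalized records.

    Sequences are normalized (uppercase, U→T, non-ACGT→N); ids must be unique.
    A sequence line appearing before any ``>`` header is a parse error.
    """
    # Biopython silently skips leading junk; enforce header-first ourselves.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            break
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(SeqRecord(id=entry.id, seq=normalize_sequence(str(entry.seq))))
    label = name if name is not None else os.path.splitext(os.path.basename(str(path)))[0]
    return QuerySet(label, records)


def write_fasta(queryset: QuerySet, path: PathLike, width: int = 70) -> None:
    """Write a QuerySet as wrapped multi-record FASTA."""
    with open(path, "w") as fh:
        for rec in queryset:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_abundance_table(path: PathLike, name: Optional[str] = None) -> QuerySet:
    """Read a TSV of (id, sequence[, rpm][, detected_in]) into a QuerySet.

    Raises
    ------
    ValueError
        On a non-numeric or negative rpm (the row number is named), or on a
        missing required column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "sequence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        rpm: Optional[float] = None
        detected: Optional[int] = None
        if "rpm" in df.columns:
            raw = getattr(row, "rpm")
            if raw != "":
                try:
                    rpm = float(raw)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: row {i}: non-numeric rpm {raw!r}"
                    ) from exc
                if rpm < 0:
                    raise ValueError(f"{path}: row {i}: rpm must be >= 0, got {rpm}")
        if "detected_in" in df.columns:
            raw = getattr(row, "detected_in")
            if raw != "":
                try:
                    detected = int(float(raw))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: row {i}: non-numeric detected_in {raw!r}"
                    ) from exc
        records.append(
            SeqRecord(
                id=row.id,
                seq=normalize_sequence(row.sequence),
                rpm=rpm,
                detected_in=detected,
            )
        )
    label = name if name is not None else os.path.splitext(os.path.basename(str(path)))[0]
    return QuerySet(label, records)


def write_abundance_table(queryset: QuerySet, path: PathLike) -> None:
    rows = [
        {
            "id": r.id,
            "sequence": r.seq,
            "rpm": "" if r.rpm is None else r.rpm,
            "detected_in": "" if r.detected_in is None else r.detected_in,
        }
        for r in queryset
    ]
    pd.DataFrame(rows, columns=["id", "sequence", "rpm", "detected_in"]).to_csv(
        path, sep="\t", index=False
    )
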
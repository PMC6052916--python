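"""Per-sequence alternative annotation and abundance-threshold summaries.

Each candidate piRNA receives one of three categories:

* ``ncRNA_fragment`` — the matcher placed it inside a reference ncRNA (or a
  supplied annotation label names an ncRNA class, for datasets annotated
  offline);
* a provided label — an externally supplied annotation the matcher does not
  compute (piRNA-cluster membership, CDS hits);
* ``unannotated`` — neither.

A provided label never overrides a matcher-found ncRNA fragment.

The packaged plasma table (25 circulating piRNAs with mean RPM over 40
individuals and their alternative annotations) ships as a TSV fixture so the
abundance-cutoff contamination summaries are computable offline: only the
``ncRNA_fragment`` category counts as contamination; piRNA-cluster and CDS
labels do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import pandas as pd

from .matcher import MatchHit, MatchParams, ReferenceSet, best_hit
from .records import NCRNA_CLASSES, QuerySet, SeqRecord

CATEGORY_NCRNA = "ncRNA_fragment"
CATEGORY_UNANNOTATED = "unannotated"

# Prefix → ncRNA class for provided annotation labels; longest prefixes first
# so MT_tRNA wins over tRNA and snoRNA over snRNA.
_LABEL_PREFIXES: tuple[tuple[str, str], ...] = (
    ("MT_TRNA", "m_tRNA"),
    ("MT-TRNA", "m_tRNA"),
    ("MT_RRNA", "m_rRNA"),
    ("MT-RRNA", "m_rRNA"),
    ("SNORNA", "snoRNA"),
    ("SNRNA", "snRNA"),
    ("TRNA", "tRNA"),
    ("RRNA", "rRNA"),
    ("RNAY", "YRNA"),
    ("RNY", "YRNA"),
    ("YRNA", "YRNA"),
    ("MIRNA", "miRNA"),
    ("MIR", "miRNA"),
    ("LET-7", "miRNA"),
)


def classify_label(label: Optional[str]) -> Optional[str]:
    """Map a free-text annotation label to an ncRNA class, or None.

    ``RNAY4`` → YRNA, ``MT_tRNA-Val`` → m_tRNA, ``rRNA_28S`` → rRNA, …;
    piRNACluster/CDS labels (and anything unrecognized) return None.
    """
    if not label:
        return None
    up = label.strip().upper()
    for prefix, cls in _LABEL_PREFIXES:
        if up.startswith(prefix):
            return cls
    return None


@dataclass
class AnnotationRecord:
    """One query with its best alternative annotation."""

    query: SeqRecord
    best_hit: Optional[MatchHit] = None
    ncrna_class: Optional[str] = None
    provided_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.best_hit is not None:
            self.ncrna_class = self.best_hit.ncrna_class
        if self.ncrna_class is not None and self.ncrna_class not in NCRNA_CLASSES:
            raise ValueError(f"unknown ncRNA class {self.ncrna_class!r}")

    @property
    def is_ncrna_fragment(self) -> bool:
        return self.ncrna_class is not None

    @property
    def category(self) -> str:
        if self.is_ncrna_fragment:
            return CATEGORY_NCRNA
        if self.provided_label:
            return self.provided_label
        return CATEGORY_UNANNOTATED


def annotate_queries(
    queries: QuerySet,
    refsets: list[ReferenceSet],
    params: MatchParams = MatchParams(),
    provided: Optional[Mapping[str, str]] = None,
) -> list[AnnotationRecord]:
    """Annotate every query with its best ncRNA hit or a provided label.

    The matcher is consulted first; a query with no hit falls back to its
    provided label (which, if it names an ncRNA class, still yields the
    ncRNA_fragment category — annotations imported from an offline analysis).
    """
    provided = provided or {}
    out: list[AnnotationRecord] = []
    for query in queries:
        hit = best_hit(query, refsets, params) if refsets else None
        if hit is not None:
            out.append(AnnotationRecord(query=query, best_hit=hit))
            continue
        label = provided.get(query.id)
        out.append(
            AnnotationRecord(
                query=query,
                ncrna_class=classify_label(label),
                provided_label=label,
            )
        )
    return out


@dataclass
class ContaminationSummary:
    """Fraction of sequences above an abundance cutoff that are ncRNA fragments."""

    rpm_cutoff: float
    n_total: int
    n_ncrna: int

    @property
    def defined(self) -> bool:
        return self.n_total > 0

    @property
    def percent_ncrna(self) -> float:
        if not self.defined:
            return math.nan
        return 100.0 * self.n_ncrna / self.n_total

    def to_dict(self) -> dict:
        return {
            "cutoff": self.rpm_cutoff,
            "n_total": self.n_total,
            "n_ncRNA": self.n_ncrna,
            "percent": self.percent_ncrna,
            "defined": self.defined,
        }

    def __str__(self) -> str:  # console rendering: nearest-integer percent
        if not self.defined:
            return f">= {self.rpm_cutoff:g} RPM: no sequences (percent undefined)"
        return (
            f">= {self.rpm_cutoff:g} RPM: {self.n_ncrna}/{self.n_total} "
            f"ncRNA fragments ({round(self.percent_ncrna)}%)"
        )


def contamination_summary(
    records: list[AnnotationRecord], rpm_cutoff: float
) -> ContaminationSummary:
    """ncRNA-fragment fraction among records with rpm >= cutoff.

    Raises
    ------
    ValueError
        If any record lacks rpm (offending ids are listed).
    """
    missing = [r.query.id for r in records if r.query.rpm is None]
    if missing:
        raise ValueError(f"records lack rpm: {missing}")
    above = [r for r in records if r.query.rpm >= rpm_cutoff]
    n_ncrna = sum(1 for r in above if r.is_ncrna_fragment)
    return ContaminationSummary(rpm_cutoff, len(above), n_ncrna)


def load_plasma_table() -> list[AnnotationRecord]:
    """The packaged 25-row circulating-piRNA table as annotation records.

    Sequences, mean RPM, detection counts and alternative annotation labels
    are bundled with the package; labels naming an ncRNA class become
    ncRNA_fragment annotations, piRNACluster/CDS labels stay provided labels.
    """
    with resources.files("pirnascreen.data").joinpath("plasma_pirnas.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        rec = SeqRecord(
            id=row.id,
            seq=row.sequence,
            rpm=float(row.rpm),
            detected_in=int(row.detected_in),
        )
        label = row.alternative
        out.append(
            AnnotationRecord(
                query=rec,
                ncrna_class=classify_label(label),
                provided_label=label,
            )
        )
    return out


ANNOTATION_COLUMNS = (
    "id",
    "sequence",
    "length",
    "best_class",
    "reference_id",
    "ref_start",
    "strand",
    "mismatches",
    "category",
)


def write_annotation_table(records: list[AnnotationRecord], path) -> None:
    """Serialize annotation records as TSV, input order preserved.

    ``ref_start`` is rendered 1-based inclusive (human-readable convention);
    hit fields are empty for queries without a matcher hit.
    """
    rows = []
    for r in records:
        hit = r.best_hit
        rows.append(
            {
                "id": r.query.id,
                "sequence": r.query.seq,
                "length": r.query.length,
                "best_class": r.ncrna_class or "",
                "reference_id": hit.reference_id if hit else "",
                "ref_start": hit.ref_start_1based if hit else "",
                "strand": hit.strand if hit else "",
                "mismatches": hit.mismatches if hit else "",
                "category": r.category,
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> pd.DataFrame:
    """Read an annotation TSV back as a DataFrame (all columns as strings)."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
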
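"""Mismatch-tolerant ungapped matching of candidate piRNAs against ncRNA references.

The screening question is whether a 18–40 nt candidate piRNA is in fact a
fragment of a longer structural ncRNA (tRNA, rRNA, YRNA, snRNA, snoRNA, miRNA
hairpin, mitochondrial tRNA/rRNA). A candidate counts as ambiguous when it has
an ungapped placement inside a reference covering at least ``min_coverage`` of
the candidate's length at ``min_identity`` sequence identity (defaults 0.94 /
0.94 with a 19 nt exact seed), or — for mismatch-allowance (MM) tables — at
most ``max_mismatches`` substitutions.

Two routes compute the same answer:

* :func:`find_hits` — a k-mer seed index proposes candidate diagonals, which
  are then evaluated exhaustively over all permitted end-trimmings.
* :func:`brute_force_hits` — evaluates *every* diagonal of every reference.
  It is the verification oracle; the two agree whenever the aligned region
  retains at least one exact ``seed_len``-mer (the documented seed-sensitivity
  contract), and ``find_hits`` is always a subset of the oracle.

Coverage below 1.0 is achieved solely by trimming bases from the query ends
(all trim splits are enumerated); gaps are never opened. At one substitution
over a 24–35 nt query, gapped and ungapped optima coincide except in
pathological cases, and the ungapped model keeps the oracle exact.

Positions are 0-based half-open internally; human-readable reports render
1-based inclusive starts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .records import (
    CLASS_PRIORITY,
    QuerySet,
    SeqRecord,
    reverse_complement,
)


class ConfigurationError(ValueError):
    """Raised for inconsistent screening configuration (e.g. duplicate classes)."""


@dataclass(frozen=True)
class MatchParams:
    """Thresholds governing what counts as a match.

    ``max_mismatches``, when set, replaces the identity rule with a flat
    substitution allowance (the MM=0/MM=1 rows of overlap tables); coverage
    end-trimming still applies.
    """

    seed_len: int = 19
    min_coverage: float = 0.94
    min_identity: float = 0.94
    max_mismatches: Optional[int] = None
    strand_mode: str = "sense_only"  # or "both"

    def __post_init__(self) -> None:
        if self.seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.max_mismatches is not None and self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0 when set")
        if self.strand_mode not in ("sense_only", "both"):
            raise ValueError("strand_mode must be 'sense_only' or 'both'")

    def allowed_mismatches(self, aligned_len: int) -> int:
        if self.max_mismatches is not None:
            return self.max_mismatches
        return math.floor((1.0 - self.min_identity) * aligned_len)


@dataclass
class ReferenceSet:
    """Class-labelled ncRNA reference sequences with an optional k-mer seed index.

    ``seed_index`` maps each ``seed_len``-mer to its (record index, offset)
    occurrences; k-mers containing N are excluded. References shorter than the
    seed length are left out of the index (``unindexed``) but remain searchable
    by the exhaustive path.
    """

    ncrna_class: str
    records: list[SeqRecord] = field(default_factory=list)
    seed_index: Optional[dict[str, list[tuple[int, int]]]] = None
    seed_len: Optional[int] = None
    unindexed: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True, order=True)
class MatchHit:
    """One ungapped placement of a query inside a reference.

    ``mismatch_positions`` are 0-based positions in the query's original
    orientation. ``coverage`` is aligned length over query length.
    """

    query_id: str
    ncrna_class: str
    reference_id: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str
    mismatches: int
    coverage: float
    mismatch_positions: tuple[int, ...] = ()

    @property
    def aligned_length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def ref_start_1based(self) -> int:
        return self.ref_start + 1


def build_seed_index(refset: ReferenceSet, seed_len: int = 19) -> ReferenceSet:
    """Populate ``refset.seed_index`` with every seed_len-mer occurrence.

    References shorter than ``seed_len`` trigger a warning and are recorded in
    ``unindexed`` (they are still scanned exhaustively during search).
    """
    index: dict[str, list[tuple[int, int]]] = {}
    unindexed: list[int] = []
    for ri, rec in enumerate(refset.records):
        if rec.length < seed_len:
            warnings.warn(
                f"reference {rec.id!r} ({rec.length} nt) shorter than seed "
                f"length {seed_len}; excluded from index",
                stacklevel=2,
            )
            unindexed.append(ri)
            continue
        seq = rec.seq
        for off in range(rec.length - seed_len + 1):
            kmer = seq[off : off + seed_len]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((ri, off))
    refset.seed_index = index
    refset.seed_len = seed_len
    refset.unindexed = unindexed
    return refset


def _windows(qlen: int, min_coverage: float) -> Iterable[tuple[int, int]]:
    """All (left-trim, aligned-length) pairs meeting the coverage threshold."""
    min_len = math.ceil(min_coverage * qlen)
    for L in range(qlen, min_len - 1, -1):
        for t in range(0, qlen - L + 1):
            yield t, L


def _count_mismatches(
    qseq: str, qoff: int, rseq: str, roff: int, length: int, allowed: int
) -> Optional[list[int]]:
    """Positions of mismatches, or None once the allowance is exceeded.

    N on either side never matches.
    """
    positions: list[int] = []
    for i in range(length):
        a = qseq[qoff + i]
        b = rseq[roff + i]
        if a != b or a == "N":
            positions.append(qoff + i)
            if len(positions) > allowed:
                return None
    return positions


def _best_on_diagonal(
    qseq: str, rseq: str, d: int, params: MatchParams
) -> Optional[tuple[int, int, list[int]]]:
    """Best passing window on diagonal ``d`` (ref_pos = query_pos + d).

    Returns (left-trim, aligned-length, mismatch positions in aligned-sequence
    coordinates), preferring fewest mismatches, then longest alignment, then
    smallest left trim. None when no window passes.
    """
    qlen, rlen = len(qseq), len(rseq)
    best_key: Optional[tuple[int, int, int]] = None
    best: Optional[tuple[int, int, list[int]]] = None
    for t, L in _windows(qlen, params.min_coverage):
        rs = d + t
        if rs < 0 or rs + L > rlen:
            continue
        allowed = params.allowed_mismatches(L)
        pos = _count_mismatches(qseq, t, rseq, rs, L, allowed)
        if pos is None:
            continue
        key = (len(pos), -L, t)
        if best_key is None or key < best_key:
            best_key = key
            best = (t, L, pos)
    return best


def _hits_for_oriented_query(
    query_id: str,
    oriented_seq: str,
    strand: str,
    qlen: int,
    refset: ReferenceSet,
    params: MatchParams,
    diagonals_by_ref: dict[int, Iterable[int]],
) -> list[MatchHit]:
    hits = []
    for ri, diags in diagonals_by_ref.items():
        rec = refset.records[ri]
        for d in diags:
            best = _best_on_diagonal(oriented_seq, rec.seq, d, params)
            if best is None:
                continue
            t, L, pos = best
            if strand == "+":
                q_start, q_end = t, t + L
                mm_pos = tuple(pos)
            else:
                # map aligned-sequence (revcomp) coordinates back to the query
                q_start, q_end = qlen - (t + L), qlen - t
                mm_pos = tuple(sorted(qlen - 1 - p for p in pos))
            hits.append(
                MatchHit(
                    query_id=query_id,
                    ncrna_class=refset.ncrna_class,
                    reference_id=rec.id,
                    ref_start=d + t,
                    ref_end=d + t + L,
                    query_start=q_start,
                    query_end=q_end,
                    strand=strand,
                    mismatches=len(pos),
                    coverage=L / qlen,
                    mismatch_positions=mm_pos,
                )
            )
    return hits


def _sort_hits(hits: list[MatchHit]) -> list[MatchHit]:
    return sorted(
        hits, key=lambda h: (h.mismatches, -h.coverage, h.reference_id, h.ref_start)
    )


def _all_diagonals(qlen: int, rlen: int) -> range:
    return range(-(qlen - 1), rlen)


def find_hits(
    query: SeqRecord, refset: ReferenceSet, params: MatchParams = MatchParams()
) -> list[MatchHit]:
    """Seed-and-extend search of ``query`` against one reference class.

    Query k-mers hitting the seed index propose diagonals; each proposed
    diagonal is then evaluated over every permitted end-trimming. Queries
    shorter than the seed length, and references excluded from the index,
    fall back to the exhaustive diagonal scan (correctness over speed).
    Hits are sorted by (mismatches asc, coverage desc, reference_id, ref_start).
    """
    if refset.seed_index is None or refset.seed_len != params.seed_len:
        build_seed_index(refset, params.seed_len)
    assert refset.seed_index is not None
    k = params.seed_len
    qlen = query.length
    orientations = [("+", query.seq)]
    if params.strand_mode == "both":
        orientations.append(("-", reverse_complement(query.seq)))

    hits: list[MatchHit] = []
    for strand, seq in orientations:
        diagonals: dict[int, set[int]] = {}
        if qlen >= k:
            for s in range(qlen - k + 1):
                kmer = seq[s : s + k]
                for ri, off in refset.seed_index.get(kmer, ()):
                    diagonals.setdefault(ri, set()).add(off - s)
            scan_exhaustively = refset.unindexed
        else:
            scan_exhaustively = range(len(refset.records))
        for ri in scan_exhaustively:
            diagonals[ri] = set(_all_diagonals(qlen, refset.records[ri].length))
        hits.extend(
            _hits_for_oriented_query(
                query.id,
                seq,
                strand,
                qlen,
                refset,
                params,
                {ri: sorted(ds) for ri, ds in diagonals.items()},
            )
        )
    return _sort_hits(hits)


def brute_force_hits(
    query: SeqRecord, refset: ReferenceSet, params: MatchParams = MatchParams()
) -> list[MatchHit]:
    """Exhaustive oracle: evaluate every diagonal of every reference.

    Same per-diagonal evaluation and tie-breaks as :func:`find_hits`, so the
    outputs are identical whenever the aligned region retains an exact
    ``seed_len``-mer; ``find_hits`` output is a subset in all cases.
    """
    qlen = query.length
    orientations = [("+", query.seq)]
    if params.strand_mode == "both":
        orientations.append(("-", reverse_complement(query.seq)))
    hits: list[MatchHit] = []
    for strand, seq in orientations:
        diagonals = {
            ri: _all_diagonals(qlen, rec.length)
            for ri, rec in enumerate(refset.records)
        }
        hits.extend(
            _hits_for_oriented_query(query.id, seq, strand, qlen, refset, params, diagonals)
        )
    return _sort_hits(hits)


def best_hits_by_class(
    query: SeqRecord, refsets: list[ReferenceSet], params: MatchParams
) -> dict[str, MatchHit]:
    """Best hit per ncRNA class (first hit of the sorted per-class list)."""
    out: dict[str, MatchHit] = {}
    for refset in refsets:
        found = find_hits(query, refset, params)
        if found:
            out[refset.ncrna_class] = found[0]
    return out


def best_hit(
    query: SeqRecord, refsets: list[ReferenceSet], params: MatchParams
) -> Optional[MatchHit]:
    """Single best hit across classes.

    Ranked by (mismatches asc, coverage desc, fixed class priority
    rRNA > tRNA > miRNA > snRNA > snoRNA > YRNA > m_tRNA > m_rRNA).
    """
    per_class = best_hits_by_class(query, refsets, params)
    if not per_class:
        return None
    return min(
        per_class.values(),
        key=lambda h: (h.mismatches, -h.coverage, CLASS_PRIORITY[h.ncrna_class]),
    )


def percent_overlap(n_matched: int, n_total: int) -> float:
    """Overlap-table percentage: matched / total × 100, rendered to 2 decimals."""
    if n_total <= 0:
        return 0.0
    return round(100.0 * n_matched / n_total, 2)


@dataclass
class OverlapTable:
    """Per-class counts of queries attributed to ncRNA references.

    Under single attribution (default) each query with at least one hit is
    counted once, in its best class, so TOTAL equals the column sum. In
    multi-count mode each class column counts every query hitting that class
    (no deduplication); TOTAL still counts distinct queries.
    """

    database: str
    n_queries: int
    counts: dict[str, int]
    total: int
    params: Optional[MatchParams] = None
    multi_count: bool = False

    @property
    def percent(self) -> float:
        return percent_overlap(self.total, self.n_queries)

    def to_frame(self) -> pd.DataFrame:
        row = {"database": self.database, "n_queries": self.n_queries}
        row.update(self.counts)
        row["TOTAL"] = self.total
        row["percent"] = f"{self.percent:.2f}"
        return pd.DataFrame([row])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def screen_database(
    queries: QuerySet,
    refsets: list[ReferenceSet],
    params: MatchParams = MatchParams(),
    multi_count: bool = False,
) -> OverlapTable:
    """Screen a candidate piRNA database against all reference classes.

    Raises
    ------
    ConfigurationError
        If two reference sets share a class label.
    """
    classes = [r.ncrna_class for r in refsets]
    if len(set(classes)) != len(classes):
        raise ConfigurationError(f"duplicate ncRNA class labels: {classes}")
    counts = {c: 0 for c in classes}
    total = 0
    for query in queries:
        per_class = best_hits_by_class(query, refsets, params)
        if not per_class:
            continue
        total += 1
        if multi_count:
            for c in per_class:
                counts[c] += 1
        else:
            chosen = min(
                per_class.values(),
                key=lambda h: (h.mismatches, -h.coverage, CLASS_PRIORITY[h.ncrna_class]),
            )
            counts[chosen.ncrna_class] += 1
    return OverlapTable(
        database=queries.name,
        n_queries=len(queries),
        counts=counts,
        total=total,
        params=params,
        multi_count=multi_count,
    )
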
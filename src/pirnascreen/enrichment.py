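"""Enrichment Score over two-way category partitions.

A sequence set is split into two mutually exclusive categories: A holds the
piRNA-like sequences (starting with 5' uridine, or having no ncRNA match) and
B the complement (non-U start, or matching an ncRNA). The Enrichment Score of
a query set against a reference set is the ratio of ratios

    ES = (query_B / query_A) / (ref_B / ref_A)

so ES > 1 means category B is over-represented in the query relative to the
reference database. The score can alternatively be weighted by sequencing
abundance (summed RPM per category). A degenerate query (A empty, B occupied)
yields +inf with an explicit flag; an optional Haldane-style pseudocount (0.5
added to all four cells) is available instead.

An upper-tail hypergeometric probability is provided as the canonical test of
whether an observed query/class overlap exceeds chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from scipy import stats

from .records import QuerySet


@dataclass
class CategoryPartition:
    """Counts (and optional summed weights) of a two-way A/B split."""

    label_A: str
    label_B: str
    count_A: int
    count_B: int
    weight_A: Optional[float] = None
    weight_B: Optional[float] = None

    def __post_init__(self) -> None:
        if self.count_A < 0 or self.count_B < 0:
            raise ValueError("category counts must be non-negative")
        for w in (self.weight_A, self.weight_B):
            if w is not None and w < 0:
                raise ValueError("category weights must be non-negative")

    @property
    def n(self) -> int:
        return self.count_A + self.count_B

    def to_dict(self) -> dict:
        return {
            "label_A": self.label_A,
            "label_B": self.label_B,
            "count_A": self.count_A,
            "count_B": self.count_B,
            "weight_A": self.weight_A,
            "weight_B": self.weight_B,
        }


PREDICATES = ("starts_with_U", "matches_ncRNA")


def partition(
    queries: QuerySet,
    predicate: str,
    annotations: Optional[Mapping[str, bool]] = None,
) -> CategoryPartition:
    """Split a query set into categories A/B under one of the two predicates.

    ``starts_with_U``: A = sequences starting with T (U in RNA), B = the rest.
    ``matches_ncRNA``: A = sequences with no ncRNA match, B = matching ones;
    requires ``annotations`` mapping every query id to a bool (True = matches
    an ncRNA).

    Weights are the summed rpm of each category when any record carries rpm.

    Raises
    ------
    ValueError
        On an empty query set, an unknown predicate, or (for matches_ncRNA)
        ids missing from ``annotations`` (the ids are listed).
    """
    if len(queries) == 0:
        raise ValueError("cannot partition an empty query set")
    if predicate == "starts_with_U":
        in_A = {r.id: r.seq.startswith("T") for r in queries}
        labels = ("5'U", "non-U")
    elif predicate == "matches_ncRNA":
        if annotations is None:
            raise ValueError("matches_ncRNA predicate requires annotations")
        missing = [r.id for r in queries if r.id not in annotations]
        if missing:
            raise ValueError(f"missing annotations for ids: {missing}")
        in_A = {r.id: not annotations[r.id] for r in queries}
        labels = ("no ncRNA match", "matches ncRNA")
    else:
        raise ValueError(f"unknown predicate {predicate!r}; choose from {PREDICATES}")

    count_A = sum(1 for v in in_A.values() if v)
    count_B = len(queries) - count_A
    weight_A = weight_B = None
    if any(r.rpm is not None for r in queries):
        weight_A = sum(r.rpm for r in queries if r.rpm is not None and in_A[r.id])
        weight_B = sum(r.rpm for r in queries if r.rpm is not None and not in_A[r.id])
    return CategoryPartition(labels[0], labels[1], count_A, count_B, weight_A, weight_B)


@dataclass
class EnrichmentResult:
    es_by_count: float
    es_by_weight: Optional[float]
    ref_partition: CategoryPartition
    query_partition: CategoryPartition
    flags: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "es_by_count": self.es_by_count,
            "es_by_weight": self.es_by_weight,
            "ref": self.ref_partition.to_dict(),
            "query": self.query_partition.to_dict(),
            "flags": list(self.flags),
        }


def _ratio_of_ratios(
    ref_A: float, ref_B: float, q_A: float, q_B: float, pseudocount: float
) -> tuple[float, list[str]]:
    flags: list[str] = []
    if pseudocount > 0:
        ref_A += pseudocount
        ref_B += pseudocount
        q_A += pseudocount
        q_B += pseudocount
    if ref_A <= 0 or ref_B <= 0:
        raise ValueError("reference categories must both be non-empty")
    if q_B == 0:
        return 0.0, flags
    if q_A == 0:
        flags.append("query_A_empty")
        return math.inf, flags
    return (q_B / q_A) / (ref_B / ref_A), flags


def enrichment_score(
    ref: CategoryPartition,
    query: CategoryPartition,
    use_weights: bool = False,
    pseudocount: float = 0.0,
) -> EnrichmentResult:
    """ES of a query partition against a reference partition.

    The count-based ES is always computed; the weighted variant substitutes
    summed weights for counts and is computed when ``use_weights`` is set and
    both partitions carry weights.

    Raises
    ------
    ValueError
        If a reference category is empty (reference ratio undefined), or
        weights are requested but absent.
    """
    es_count, flags = _ratio_of_ratios(
        ref.count_A, ref.count_B, query.count_A, query.count_B, pseudocount
    )
    es_weight: Optional[float] = None
    if use_weights:
        if None in (ref.weight_A, ref.weight_B, query.weight_A, query.weight_B):
            raise ValueError("weighted ES requested but a partition lacks weights")
        es_weight, wflags = _ratio_of_ratios(
            ref.weight_A, ref.weight_B, query.weight_A, query.weight_B, pseudocount
        )
        flags += [f"weighted_{f}" for f in wflags]
    return EnrichmentResult(es_count, es_weight, ref, query, tuple(flags))


def overlap_pvalue(
    universe_size: int,
    n_class_in_universe: int,
    n_query: int,
    n_query_in_class: int,
) -> float:
    """Upper-tail hypergeometric P(X >= n_query_in_class).

    Probability of drawing at least the observed number of class members in a
    size-``n_query`` sample from a universe containing
    ``n_class_in_universe`` class members.

    Raises
    ------
    ValueError
        On inconsistent arguments.
    """
    args = (universe_size, n_class_in_universe, n_query, n_query_in_class)
    if any(a < 0 for a in args):
        raise ValueError(f"all arguments must be >= 0, got {args}")
    if n_class_in_universe > universe_size or n_query > universe_size:
        raise ValueError("class/query size exceeds universe size")
    if n_query_in_class > min(n_class_in_universe, n_query):
        raise ValueError("overlap exceeds class or query size")
    return float(
        stats.hypergeom.sf(
            n_query_in_class - 1, universe_size, n_class_in_universe, n_query
        )
    )
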
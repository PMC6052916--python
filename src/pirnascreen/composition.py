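"""Positional base composition and length statistics.

Bona fide primary piRNAs carry a strong uridine bias at position 1 (rendered T
in DNA-alphabet databases) and — for ping-pong secondary piRNAs — adenine at
position 10. ncRNA fragments mis-annotated as piRNAs lack both signatures and
skew longer. This module quantifies those signals: per-position base counts
and information content (the numeric backbone of a sequence logo), positional
base fractions, and length-distribution summaries with a Welch two-sample
*t*-test comparator.

Positions are 1-based in the public API, matching logo conventions. Position
*p* is tallied over the sequences of length >= *p* only (ragged right edge,
no padding); N bases are excluded from both numerator and denominator of the
logo frequencies but remain in the denominator of :func:`base_fraction_at`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .records import QuerySet

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PositionalCompositionMatrix:
    """Per-position base counts, frequencies and information content (bits)."""

    n_positions: int
    n_seqs: int
    counts: np.ndarray  # (n_positions, 4) int
    freqs: np.ndarray  # (n_positions, 4) float; NaN where no coverage
    info_bits: np.ndarray  # (n_positions,) float; NaN where no coverage
    denominators: np.ndarray  # (n_positions,) int non-N coverage

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": np.arange(1, self.n_positions + 1),
                **{f"count_{b}": self.counts[:, i] for b, i in _BASE_IDX.items()},
                **{f"freq_{b}": self.freqs[:, i] for b, i in _BASE_IDX.items()},
                "n": self.denominators,
                "info_bits": self.info_bits,
            }
        )
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def positional_composition(
    queries: QuerySet, n_positions: int = 15
) -> PositionalCompositionMatrix:
    """Base composition over the first ``n_positions`` positions.

    info_bits(p) = 2 + sum_b f_b log2 f_b (0·log 0 = 0), so a single-base
    column scores 2 bits and a uniform column 0 bits.

    Raises
    ------
    ValueError
        If ``queries`` is empty (no composition defined) or n_positions < 1.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    if len(queries) == 0:
        raise ValueError("cannot compute composition of an empty query set")
    counts = np.zeros((n_positions, 4), dtype=np.int64)
    for rec in queries:
        upto = min(rec.length, n_positions)
        for p in range(upto):
            b = rec.seq[p]
            if b != "N":
                counts[p, _BASE_IDX[b]] += 1
    denom = counts.sum(axis=1)
    freqs = np.full((n_positions, 4), np.nan)
    info = np.full(n_positions, np.nan)
    covered = denom > 0
    freqs[covered] = counts[covered] / denom[covered, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs[covered] > 0, freqs[covered] * np.log2(freqs[covered]), 0.0)
    info[covered] = np.clip(2.0 + plogp.sum(axis=1), 0.0, 2.0)
    return PositionalCompositionMatrix(
        n_positions=n_positions,
        n_seqs=len(queries),
        counts=counts,
        freqs=freqs,
        info_bits=info,
        denominators=denom,
    )


class BaseFraction(NamedTuple):
    fraction: float
    denominator: int


def base_fraction_at(queries: QuerySet, position: int, base: str) -> BaseFraction:
    """Fraction of sequences with ``base`` at a 1-based ``position``.

    Computed over the sequences of length >= position; ``U`` is accepted as an
    alias of ``T``.

    Raises
    ------
    ValueError
        If no sequence reaches the position, or position < 1.
    """
    if position < 1:
        raise ValueError("position is 1-based and must be >= 1")
    base = base.upper().replace("U", "T")
    if base not in BASES:
        raise ValueError(f"base must be one of {BASES} (or U), got {base!r}")
    eligible = [r for r in queries if r.length >= position]
    if not eligible:
        raise ValueError(f"no sequence reaches position {position}")
    hits = sum(1 for r in eligible if r.seq[position - 1] == base)
    return BaseFraction(hits / len(eligible), len(eligible))


@dataclass
class LengthStats:
    """Summary of a length distribution; mean/sd are NaN when n < 1 (or n < 2 for sd)."""

    n: int
    mean: float
    sd: float
    frac_ge_threshold: float
    threshold: int

    @property
    def defined(self) -> bool:
        return self.n > 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            f"frac_ge_{self.threshold}": self.frac_ge_threshold,
            "defined": self.defined,
        }


def length_stats(queries: QuerySet, threshold: int = 30) -> LengthStats:
    """Length distribution summary with the fraction of sequences >= threshold nt."""
    lengths = np.array([r.length for r in queries], dtype=float)
    n = len(lengths)
    if n == 0:
        return LengthStats(0, math.nan, math.nan, math.nan, threshold)
    mean = float(lengths.mean())
    sd = float(lengths.std(ddof=1)) if n > 1 else math.nan
    frac = float((lengths >= threshold).mean())
    return LengthStats(n, mean, sd, frac, threshold)


class LengthComparison(NamedTuple):
    statistic: float
    df: float
    pvalue: float


def compare_lengths(a: QuerySet, b: QuerySet) -> LengthComparison:
    """Welch's unequal-variance two-sample t-test on per-sequence lengths.

    Raises
    ------
    ValueError
        If either set has n < 2 or zero length variance (the offending set is
        named).
    """
    for label, qs in (("a", a), ("b", b)):
        lengths = [r.length for r in qs]
        if len(lengths) < 2:
            raise ValueError(f"set {label!r} ({qs.name}): need n >= 2, got {len(lengths)}")
        if len(set(lengths)) == 1:
            raise ValueError(f"set {label!r} ({qs.name}): zero length variance")
    la = np.array([r.length for r in a], dtype=float)
    lb = np.array([r.length for r in b], dtype=float)
    res = stats.ttest_ind(la, lb, equal_var=False)
    return LengthComparison(float(res.statistic), float(res.df), float(res.pvalue))
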
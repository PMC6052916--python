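"""Synthetic reference ncRNAs and contaminated piRNA databases with ground truth.

The generator emulates the study design end to end without any database
download: per-class reference ncRNAs (i.i.d. uniform bases within realistic
per-class length ranges), a candidate piRNA database mixing "genuine" piRNAs
(26–31 nt, tunable 1U/10A bias, rejection-sampled so they share no 19-mer
with any reference — false-positive matches are impossible by construction)
with planted reference-window contaminants (tunable count, length and
substitution load), and log-normal RPM abundances independent of
contamination status by default.

A single seed drives all stages; a complete truth table records which
database entries are planted and from where, so recall/precision of the
screen are exact, not probabilistic.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .matcher import ReferenceSet
from .records import NCRNA_CLASSES, QuerySet, SeqRecord
from .seqio import write_abundance_table, write_fasta

_BASES = np.array(list("ACGT"))

#: Realistic per-class reference lengths (nt).
DEFAULT_REF_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "tRNA": (70, 90),
    "YRNA": (90, 115),
    "snoRNA": (60, 150),
    "snRNA": (100, 200),
    "rRNA": (1500, 2000),
    "miRNA": (60, 90),
    "m_tRNA": (60, 75),
    "m_rRNA": (950, 1600),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the screened databases: p_1U = 0.866 (the 5'U fraction of
    the large piRNA compendium, 148,557/171,551), genuine lengths 26–31 nt,
    contaminants 26–35 nt (ncRNA fragments skew longer), substitution-free
    contaminants unless a mutation rate or an exact substitution count is set.
    """

    seed: int = 0
    n_refs_per_class: int = 5
    classes: tuple[str, ...] = NCRNA_CLASSES
    ref_length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REF_LENGTH_RANGES)
    )
    n_genuine: int = 1000
    p_1U: float = 0.866
    p_10A: float = 0.3
    genuine_length_range: tuple[int, int] = (26, 31)
    n_contaminants: int = 40
    contaminant_length_range: tuple[int, int] = (26, 35)
    contaminant_mutation_rate: float = 0.0
    #: When set, each contaminant receives exactly this many substitutions,
    #: placed so that an exact seed_len-mer survives and no coverage-trim at
    #: ``coverage_guard`` can excise them.
    contaminant_n_substitutions: Optional[int] = None
    rpm_lognormal_mu_sigma: tuple[float, float] = (1.0, 1.5)
    #: Additive log-scale RPM shift for contaminants (0 = abundance
    #: independent of status; > 0 pushes contaminants into the high tail).
    contaminant_rpm_log_shift: float = 0.0
    seed_len: int = 19
    coverage_guard: float = 0.94
    max_rejection_tries: int = 1000

    def __post_init__(self) -> None:
        for p in (self.p_1U, self.p_10A, self.contaminant_mutation_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for lo, hi in (self.genuine_length_range, self.contaminant_length_range):
            if lo > hi or lo < 1:
                raise ValueError(f"empty length range ({lo}, {hi})")
        for cls in self.classes:
            lo, hi = self.ref_length_ranges[cls]
            if lo > hi or lo < 1:
                raise ValueError(f"empty length range for {cls}: ({lo}, {hi})")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated database entry."""

    id: str
    is_contaminant: bool
    source_class: Optional[str] = None
    source_reference_id: Optional[str] = None
    source_offset: Optional[int] = None
    n_mutations: int = 0


def _rng_for(config: SyntheticConfig, stage: int) -> np.random.Generator:
    # one seed drives all stages; each stage gets an independent stream so
    # simulate_references/simulate_database are deterministic regardless of
    # call order
    return np.random.default_rng([config.seed, stage])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_references(config: SyntheticConfig) -> list[ReferenceSet]:
    """One ReferenceSet per configured class; deterministic under the seed."""
    rng = _rng_for(config, 0)
    refsets = []
    for cls in config.classes:
        lo, hi = config.ref_length_ranges[cls]
        records = []
        for i in range(config.n_refs_per_class):
            length = int(rng.integers(lo, hi + 1))
            records.append(SeqRecord(id=f"{cls}_{i + 1}", seq=_random_seq(rng, length)))
        refsets.append(ReferenceSet(ncrna_class=cls, records=records))
    return refsets


def _reference_kmers(refsets: list[ReferenceSet], k: int) -> set[str]:
    kmers: set[str] = set()
    for refset in refsets:
        for rec in refset.records:
            for off in range(rec.length - k + 1):
                kmers.add(rec.seq[off : off + k])
    return kmers


def _shares_kmer(seq: str, kmers: set[str], k: int) -> bool:
    return any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1))


def _genuine_seq(rng: np.random.Generator, config: SyntheticConfig) -> str:
    lo, hi = config.genuine_length_range
    length = int(rng.integers(lo, hi + 1))
    bases = list(_random_seq(rng, length))
    # position-1 1U (T) bias; non-T starts uniform over the other bases
    if rng.random() < config.p_1U:
        bases[0] = "T"
    else:
        bases[0] = str(rng.choice([b for b in "ACG"]))
    if length >= 10:
        if rng.random() < config.p_10A:
            bases[9] = "A"
        else:
            bases[9] = str(rng.choice([b for b in "CGT"]))
    return "".join(bases)


def _substitution_positions(
    rng: np.random.Generator, length: int, k: int, n_subs: int, coverage_guard: float
) -> np.ndarray:
    # positions where a substitution (a) cannot be excised by end-trimming at
    # the coverage guard and (b) leaves at least one exact k-mer intact
    trim = length - math.ceil(coverage_guard * length)
    candidates = [
        p
        for p in range(length)
        if trim <= p <= length - 1 - trim and (p >= k or length - 1 - p >= k)
    ]
    if len(candidates) < n_subs:
        raise ValueError(
            f"cannot place {n_subs} guarded substitutions in a {length} nt window"
        )
    return rng.choice(candidates, size=n_subs, replace=False)


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    bases = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != bases[p]]
        bases[p] = str(rng.choice(alternatives))
    return "".join(bases)


def simulate_database(
    config: SyntheticConfig, refsets: list[ReferenceSet]
) -> tuple[QuerySet, list[TruthRecord]]:
    """Simulate a contaminated candidate piRNA database with full ground truth.

    Raises
    ------
    RuntimeError
        If rejection sampling of a genuine sequence exceeds the retry bound
        (enlarge the reference space or shorten the seed).
    """
    rng = _rng_for(config, 1)
    k = config.seed_len
    ref_kmers = _reference_kmers(refsets, k)

    entries: list[tuple[str, TruthRecord]] = []  # (seq, truth sans id)
    for _ in range(config.n_genuine):
        for _try in range(config.max_rejection_tries):
            seq = _genuine_seq(rng, config)
            if not _shares_kmer(seq, ref_kmers, k):
                break
        else:
            raise RuntimeError(
                "rejection sampling failed: every candidate genuine sequence "
                "shares a seed k-mer with the references; enlarge the "
                "reference space or lower n_genuine"
            )
        entries.append((seq, TruthRecord(id="", is_contaminant=False)))

    usable = [rs for rs in refsets if rs.records]
    for _ in range(config.n_contaminants):
        refset = usable[int(rng.integers(0, len(usable)))]
        rec = refset.records[int(rng.integers(0, len(refset.records)))]
        lo, hi = config.contaminant_length_range
        hi = min(hi, rec.length)
        lo = min(lo, hi)
        length = int(rng.integers(lo, hi + 1))
        offset = int(rng.integers(0, rec.length - length + 1))
        window = rec.seq[offset : offset + length]
        if config.contaminant_n_substitutions is not None:
            positions = _substitution_positions(
                rng, length, k, config.contaminant_n_substitutions, config.coverage_guard
            )
        elif config.contaminant_mutation_rate > 0:
            mask = rng.random(length) < config.contaminant_mutation_rate
            positions = np.flatnonzero(mask)
        else:
            positions = np.array([], dtype=int)
        seq = _mutate(rng, window, positions) if len(positions) else window
        entries.append(
            (
                seq,
                TruthRecord(
                    id="",
                    is_contaminant=True,
                    source_class=refset.ncrna_class,
                    source_reference_id=rec.id,
                    source_offset=offset,
                    n_mutations=int(len(positions)),
                ),
            )
        )

    # shuffle so record order carries no truth signal, then assign ids and RPM
    order = rng.permutation(len(entries))
    mu, sigma = config.rpm_lognormal_mu_sigma
    records: list[SeqRecord] = []
    truth: list[TruthRecord] = []
    width = len(str(len(entries)))
    for rank, idx in enumerate(order, start=1):
        seq, t = entries[idx]
        sid = f"sim{rank:0{width}d}"
        shift = config.contaminant_rpm_log_shift if t.is_contaminant else 0.0
        rpm = float(rng.lognormal(mean=mu + shift, sigma=sigma))
        detected = int(max(1, rng.binomial(40, rpm / (rpm + 10.0))))
        records.append(SeqRecord(id=sid, seq=seq, rpm=round(rpm, 3), detected_in=detected))
        truth.append(dataclasses.replace(t, id=sid))
    return QuerySet("synthetic", records), truth


def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": t.id,
                "is_contaminant": int(t.is_contaminant),
                "source_class": t.source_class or "",
                "source_reference_id": t.source_reference_id or "",
                "source_offset": "" if t.source_offset is None else t.source_offset,
                "n_mutations": t.n_mutations,
            }
            for t in truth
        ]
    )


def write_dataset(
    config: SyntheticConfig,
    outdir,
    refsets: Optional[list[ReferenceSet]] = None,
) -> dict[str, str]:
    """Simulate and write references, database, abundances, truth, and config.

    Returns the mapping of artifact name → path. Byte-identical across runs
    with the same config.
    """
    os.makedirs(outdir, exist_ok=True)
    if refsets is None:
        refsets = simulate_references(config)
    database, truth = simulate_database(config, refsets)
    paths = {}
    for refset in refsets:
        p = os.path.join(outdir, f"ref_{refset.ncrna_class}.fasta")
        write_fasta(QuerySet(refset.ncrna_class, refset.records), p)
        paths[f"ref_{refset.ncrna_class}"] = p
    paths["database"] = os.path.join(outdir, "database.fasta")
    write_fasta(database, paths["database"])
    paths["abundances"] = os.path.join(outdir, "abundances.tsv")
    write_abundance_table(database, paths["abundances"])
    paths["truth"] = os.path.join(outdir, "truth.tsv")
    truth_to_frame(truth).to_csv(paths["truth"], sep="\t", index=False)
    paths["config"] = os.path.join(outdir, "config.json")
    with open(paths["config"], "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
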
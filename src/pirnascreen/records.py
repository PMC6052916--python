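"""Core record types shared by every pipeline stage.

Sequences are held in the DNA alphabet internally: candidate piRNA databases
mix RNA- and DNA-alphabet entries and mixed case, so everything is normalized
at ingest (uppercase, U→T, anything else →N). ``N`` never matches any base
during alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

#: The ncRNA classes screened against, in the fixed priority order used to
#: attribute a query that hits more than one class with an equally good match.
NCRNA_CLASSES: tuple[str, ...] = (
    "rRNA",
    "tRNA",
    "miRNA",
    "snRNA",
    "snoRNA",
    "YRNA",
    "m_tRNA",
    "m_rRNA",
)

CLASS_PRIORITY: dict[str, int] = {c: i for i, c in enumerate(NCRNA_CLASSES)}

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(raw: str) -> str:
    """Normalize a raw sequence string to the internal DNA alphabet.

    Uppercases, maps U→T, and replaces any character outside {A,C,G,T} with N.
    Length is preserved. Idempotent.

    Raises
    ------
    ValueError
        If ``raw`` is empty.
    """
    if not raw:
        raise ValueError("cannot normalize an empty sequence")
    out = []
    for c in raw:
        u = c.upper()  # per character: some case-folds expand, which would break length
        if u == "U":
            u = "T"
        out.append(u if u in "ACGT" else "N")
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """One normalized nucleotide sequence with optional abundance metadata.

    Parameters
    ----------
    id : str
        Sequence identifier (unique within a :class:`QuerySet`).
    seq : str
        Uppercase DNA-alphabet sequence (A/C/G/T/N).
    rpm : float, optional
        Mean reads-per-million abundance.
    detected_in : int, optional
        Number of individuals/samples the sequence was detected in.
    """

    id: str
    seq: str
    rpm: Optional[float] = None
    detected_in: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-normalized characters {sorted(bad)}; "
                "run normalize_sequence first"
            )
        if self.rpm is not None and self.rpm < 0:
            raise ValueError(f"record {self.id!r}: rpm must be >= 0, got {self.rpm}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class QuerySet:
    """A named collection of :class:`SeqRecord` with unique ids."""

    name: str
    records: list[SeqRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(
                    f"query set {self.name!r}: duplicate id {rec.id!r}"
                )
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def by_id(self) -> dict[str, SeqRecord]:
        return {r.id: r for r in self.records}

    def subset(self, ids: set[str], name: Optional[str] = None) -> "QuerySet":
        return QuerySet(
            name if name is not None else self.name,
            [r for r in self.records if r.id in ids],
        )
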
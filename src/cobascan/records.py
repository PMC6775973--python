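"""Core record types shared across the pipeline.

All internal coordinates are 0-based half-open. SAM input (1-based) is
converted at the boundary in :mod:`cobascan.io_formats`; GFF3 output is
1-based inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

IUPAC_NT = set("ACGTURYSWKMBDHVN")
# standard amino acids + ambiguity codes accepted by BLOSUM62
IUPAC_AA = set("ACDEFGHIKLMNPQRSTVWYBZX*")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass
class SequenceRecord:
    """One nucleotide or amino-acid sequence, optionally with Phred qualities."""

    id: str
    sequence: str
    description: str = ""
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentRecord:
    """One read-to-genome alignment with edit counts.

    Invariants: ``ref_end - ref_start = matches + mismatches + deletions`` and
    ``aligned_read_bases = matches + mismatches + insertions``.
    """

    read_id: str
    genome_id: str
    ref_start: int
    ref_end: int
    strand: str
    matches: int
    mismatches: int
    insertions: int
    deletions: int
    cigar: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for name in ("matches", "mismatches", "insertions", "deletions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        span = self.ref_end - self.ref_start
        expect = self.matches + self.mismatches + self.deletions
        if span != expect:
            raise ValueError(
                f"{self.read_id}: reference span {span} != "
                f"matches+mismatches+deletions = {expect}"
            )

    @property
    def aligned_read_bases(self) -> int:
        return self.matches + self.mismatches + self.insertions

    @property
    def alignment_columns(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions


@dataclass
class Feature:
    """Annotated interval on a genome (0-based half-open)."""

    kind: str
    start: int
    end: int
    strand: str = "."
    attributes: dict = field(default_factory=dict)

    def shifted(self, offset: int, circumference: int | None = None) -> "Feature":
        s, e = self.start + offset, self.end + offset
        if circumference is not None:
            s %= circumference
            e = s + (self.end - self.start)
        return replace(self, start=s, end=e, attributes=dict(self.attributes))


@dataclass
class AnnotatedGenome:
    """Linear genome sequence plus feature annotations and provenance."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]
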
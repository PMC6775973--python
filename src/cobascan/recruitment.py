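"""Read cleaning, identity-filtered recruitment, presence and abundance.

A phage is called present in a sample when at least 75% of its genome is
covered by reads of at least 90% nucleotide identity, and its relative
abundance is

    aligned bases / genome size (bases) / library size (Gb)

with "library size" the total read bases after cleaning and "aligned bases"
the reference bases covered by passing alignments, multiplicity counted.
Both thresholds are inclusive and configurable; additional identity cutoffs
(e.g. 95% and 100% for enrichment profiling) can be computed in one pass.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seedalign import GenomeIndex, hit_to_alignment
from .records import AlignmentRecord, AnnotatedGenome, SequenceRecord


@dataclass
class CleanParams:
    """Read-cleaning thresholds: end-trim, mean-quality and length filters."""

    end_quality: int = 20
    min_avg_quality: float = 20.0
    min_length: int = 30

    def __post_init__(self) -> None:
        if self.end_quality < 0 or self.min_avg_quality < 0 or self.min_length < 0:
            raise ValueError("cleaning thresholds must be >= 0")


@dataclass
class RecruitParams:
    min_identity: float = 0.90
    min_breadth: float = 0.75
    alt_identities: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_breadth, *self.alt_identities):
            if not 0 < v <= 1:
                raise ValueError("identity/breadth fractions must be in (0,1]")

    @property
    def identity_cutoffs(self) -> list[float]:
        return sorted({self.min_identity, *self.alt_identities})


@dataclass
class CleanStats:
    reads_in: int = 0
    reads_out: int = 0
    bases_in: int = 0
    bases_out: int = 0


def clean_reads(
    reads: list[SequenceRecord], params: CleanParams | None = None
) -> tuple[list[SequenceRecord], CleanStats]:
    """Trim low-quality read ends and drop short/low-quality reads.

    From each end, bases are removed until one with quality >= end_quality is
    met; reads whose mean quality falls below min_avg_quality or whose length
    falls below min_length after trimming are dropped.
    """
    params = params or CleanParams()
    stats = CleanStats()
    out: list[SequenceRecord] = []
    for r in reads:
        stats.reads_in += 1
        stats.bases_in += len(r)
        if r.qualities is None:
            raise ValueError(f"read {r.id} has no qualities; cleaning impossible")
        q = r.qualities
        lo, hi = 0, len(q)
        while lo < hi and q[lo] < params.end_quality:
            lo += 1
        while hi > lo and q[hi - 1] < params.end_quality:
            hi -= 1
        if hi - lo < params.min_length:
            continue
        sub = q[lo:hi]
        if sum(sub) / len(sub) < params.min_avg_quality:
            continue
        out.append(
            SequenceRecord(
                id=r.id,
                sequence=r.sequence[lo:hi],
                description=r.description,
                qualities=list(sub),
            )
        )
        stats.reads_out += 1
        stats.bases_out += hi - lo
    return out, stats


def _as_seq_dict(genomes) -> dict[str, str]:
    if isinstance(genomes, dict):
        return {k: (v.sequence if hasattr(v, "sequence") else v) for k, v in genomes.items()}
    return {g.id: g.sequence for g in genomes}


def align_reads(
    reads: list[SequenceRecord],
    genomes,
    k: int = 15,
    seed_stride: int = 11,
    band: int = 16,
) -> list[AlignmentRecord]:
    """Seed-and-extend alignment of reads against a genome database.

    One primary alignment per read (best edit distance; ties to the
    lexicographically smallest genome id, then leftmost). Reads without a
    confident placement are simply absent from the output.
    """
    index = GenomeIndex(_as_seq_dict(genomes), k=k)
    alignments: list[AlignmentRecord] = []
    for r in reads:
        hit = index.map_sequence(r.sequence, seed_stride=seed_stride, band=band)
        if hit is not None:
            alignments.append(hit_to_alignment(r.id, hit))
    return alignments


def alignment_identity(a: AlignmentRecord) -> float:
    """Percent identity as matches / (matches + mismatches + indel columns)."""
    cols = a.alignment_columns
    if cols == 0:
        raise ValueError(f"alignment for {a.read_id} has zero columns")
    return a.matches / cols


@dataclass
class CoverageProfile:
    genome_id: str
    depth: np.ndarray
    aligned_bases: int = 0
    passing_reads: int = 0

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0


def recruit(
    alignments: list[AlignmentRecord],
    genome_lengths: dict[str, int],
    params: RecruitParams | None = None,
    min_identity: float | None = None,
) -> dict[str, CoverageProfile]:
    """Per-genome coverage from alignments passing the identity filter."""
    params = params or RecruitParams()
    cutoff = params.min_identity if min_identity is None else min_identity
    starts = {g: [] for g in genome_lengths}
    ends = {g: [] for g in genome_lengths}
    npass = {g: 0 for g in genome_lengths}
    for a in alignments:
        if a.genome_id not in genome_lengths:
            raise KeyError(f"alignment references unknown genome {a.genome_id}")
        L = genome_lengths[a.genome_id]
        if a.ref_start < 0 or a.ref_end > L:
            raise ValueError(
                f"alignment {a.read_id} [{a.ref_start},{a.ref_end}) "
                f"outside genome {a.genome_id} of length {L}"
            )
        if alignment_identity(a) < cutoff:
            continue
        starts[a.genome_id].append(a.ref_start)
        ends[a.genome_id].append(a.ref_end)
        npass[a.genome_id] += 1
    profiles = {}
    for gid, L in genome_lengths.items():
        delta = np.zeros(L + 1, dtype=np.int64)
        if starts[gid]:
            np.add.at(delta, np.asarray(starts[gid]), 1)
            np.add.at(delta, np.asarray(ends[gid]), -1)
        depth = np.cumsum(delta[:-1])
        profiles[gid] = CoverageProfile(
            genome_id=gid,
            depth=depth,
            aligned_bases=int(depth.sum()),
            passing_reads=npass[gid],
        )
    return profiles


def breadth(profile: CoverageProfile) -> float:
    """Fraction of genome positions covered by at least one passing read."""
    if len(profile.depth) == 0:
        return 0.0
    return float(np.count_nonzero(profile.depth)) / len(profile.depth)


def call_presence(profile: CoverageProfile, params: RecruitParams | None = None) -> bool:
    """Present iff breadth >= min_breadth (inclusive)."""
    params = params or RecruitParams()
    return breadth(profile) >= params.min_breadth


def relative_abundance(
    profile: CoverageProfile, genome_length: int, library_bases: int
) -> float:
    """Aligned bases / genome length / library size in Gb."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if library_bases <= 0:
        raise ValueError("library_bases must be positive")
    return profile.aligned_bases / genome_length / (library_bases / 1e9)


@dataclass
class RecruitmentReport:
    sample_id: str
    genome_id: str
    identity_cutoff: float
    breadth: float
    mean_depth: float
    abundance_per_gb: float
    abundance_pct_of_library: float
    present: bool
    library_bases: int
    aligned_bases: int = 0
    passing_reads: int = 0


def reports_from_alignments(
    alignments: list[AlignmentRecord],
    genome_lengths: dict[str, int],
    library_bases: int,
    params: RecruitParams | None = None,
    sample_id: str = "sample",
) -> list[RecruitmentReport]:
    """Breadth/presence/abundance for every genome and identity cutoff."""
    params = params or RecruitParams()
    reports = []
    for cutoff in params.identity_cutoffs:
        profiles = recruit(alignments, genome_lengths, params, min_identity=cutoff)
        for gid in sorted(profiles):
            p = profiles[gid]
            b = breadth(p)
            reports.append(
                RecruitmentReport(
                    sample_id=sample_id,
                    genome_id=gid,
                    identity_cutoff=cutoff,
                    breadth=b,
                    mean_depth=p.mean_depth,
                    abundance_per_gb=relative_abundance(p, genome_lengths[gid], library_bases),
                    abundance_pct_of_library=100.0 * p.aligned_bases / library_bases,
                    present=b >= params.min_breadth,
                    library_bases=library_bases,
                    aligned_bases=p.aligned_bases,
                    passing_reads=p.passing_reads,
                )
            )
    return reports


def profile_sample(
    sample_reads: list[SequenceRecord],
    genome_db,
    clean_params: CleanParams | None = None,
    recruit_params: RecruitParams | None = None,
    sample_id: str = "sample",
    skip_cleaning: bool = False,
) -> list[RecruitmentReport]:
    """Full clean -> align -> recruit -> report chain for one sample."""
    recruit_params = recruit_params or RecruitParams()
    if skip_cleaning:
        reads = sample_reads
    else:
        reads, _ = clean_reads(sample_reads, clean_params)
    library_bases = sum(len(r) for r in reads)
    if library_bases == 0:
        raise ValueError("no read bases left after cleaning")
    seqs = _as_seq_dict(genome_db)
    alignments = align_reads(reads, seqs)
    lengths = {gid: len(s) for gid, s in seqs.items()}
    return reports_from_alignments(
        alignments, lengths, library_bases, recruit_params, sample_id=sample_id
    )
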
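"""Readers and writers for FASTA/FASTQ/SAM/TSV/GFF3.

Single source of truth for coordinate conventions: everything in memory is
0-based half-open; SAM POS (1-based) is converted on ingestion, GFF3 output
is written 1-based inclusive. Lowercase (soft-masked) bases are uppercased
on read — masking is irrelevant to every computation downstream.
"""
from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO

from .records import AlignmentRecord, AnnotatedGenome, SequenceRecord


def read_sequences(path, format: str = "fasta") -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file (Phred+33 qualities)."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    for rec in SeqIO.parse(os.fspath(path), format):
        quals = None
        if format == "fastq":
            quals = list(rec.letter_annotations["phred_quality"])
        yield SequenceRecord(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            description=rec.description[len(rec.id):].strip()
            if rec.description.startswith(rec.id)
            else rec.description,
            qualities=quals,
        )


def write_sequences(records: Iterable[SequenceRecord], path, format: str = "fasta") -> int:
    """Write records as FASTA (one line per sequence) or FASTQ. Returns count."""
    n = 0
    with open(path, "w") as fh:
        for r in records:
            header = f"{r.id} {r.description}".rstrip()
            if format == "fasta":
                fh.write(f">{header}\n{r.sequence}\n")
            elif format == "fastq":
                if r.qualities is None:
                    raise ValueError(f"record {r.id} has no qualities")
                qual = "".join(chr(q + 33) for q in r.qualities)
                fh.write(f"@{header}\n{r.sequence}\n+\n{qual}\n")
            else:
                raise ValueError(f"unsupported format {format!r}")
            n += 1
    return n


def _cigar_counts(aln: "pysam.AlignedSegment") -> tuple[int, int, int]:
    """(aligned M/=/X columns, inserted read bases, deleted ref bases)."""
    m = ins = dele = 0
    for op, length in aln.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            m += length
        elif op == 1:  # I
            ins += length
        elif op == 2:  # D
            dele += length
    return m, ins, dele


def read_alignments(path, keep_secondary: bool = False) -> Iterator[AlignmentRecord]:
    """Stream mapped records from a SAM file as AlignmentRecords.

    Requires the NM tag on every mapped record (identity is not computable
    without it; MD parsing is not attempted). Unmapped records are skipped;
    secondary/supplementary records are skipped unless ``keep_secondary``.
    """
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if not keep_secondary and (aln.is_secondary or aln.is_supplementary):
                continue
            if not aln.has_tag("NM"):
                raise ValueError(
                    f"mapped record {aln.query_name} lacks NM tag; "
                    "identity not computable"
                )
            nm = aln.get_tag("NM")
            m, ins, dele = _cigar_counts(aln)
            mismatches = nm - ins - dele
            if mismatches < 0:
                raise ValueError(
                    f"record {aln.query_name}: NM={nm} smaller than indel bases"
                )
            yield AlignmentRecord(
                read_id=aln.query_name,
                genome_id=aln.reference_name,
                ref_start=aln.reference_start,
                ref_end=aln.reference_start + m + dele,
                strand="-" if aln.is_reverse else "+",
                matches=m - mismatches,
                mismatches=mismatches,
                insertions=ins,
                deletions=dele,
                cigar=aln.cigarstring,
            )


def write_sam(
    alignments: Iterable[AlignmentRecord],
    reads: dict[str, SequenceRecord],
    genome_lengths: dict[str, int],
    path,
) -> int:
    """Write alignments as a minimal text SAM with NM tags. Returns count.

    Reads on the minus strand are written reverse-complemented with flag 16,
    matching mapper convention. ``cigar`` on each record is required.
    """
    from .records import reverse_complement

    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for gid in sorted(genome_lengths):
            fh.write(f"@SQ\tSN:{gid}\tLN:{genome_lengths[gid]}\n")
        for a in alignments:
            if a.cigar is None:
                raise ValueError(f"alignment for {a.read_id} carries no CIGAR")
            rec = reads[a.read_id]
            seq = rec.sequence
            qual = (
                "".join(chr(q + 33) for q in rec.qualities)
                if rec.qualities is not None
                else "*"
            )
            if a.strand == "-":
                seq = reverse_complement(seq)
                qual = qual[::-1] if qual != "*" else qual
            flag = 16 if a.strand == "-" else 0
            nm = a.mismatches + a.insertions + a.deletions
            fh.write(
                f"{a.read_id}\t{flag}\t{a.genome_id}\t{a.ref_start + 1}\t60\t"
                f"{a.cigar}\t*\t0\t0\t{seq}\t{qual}\tNM:i:{nm}\n"
            )
            n += 1
    return n


REPORT_COLUMNS = [
    "sample_id",
    "genome_id",
    "identity_cutoff",
    "breadth",
    "mean_depth",
    "abundance_per_gb",
    "abundance_pct_of_library",
    "present",
    "library_bases",
]


def write_report(reports, path) -> pd.DataFrame:
    """Write recruitment reports as a TSV sorted by (sample, genome, cutoff)."""
    rows = [
        {col: getattr(r, col) for col in REPORT_COLUMNS} for r in reports
    ]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["sample_id", "genome_id", "identity_cutoff"]
        ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return df


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gff3(genome: AnnotatedGenome, path, source: str = "cobascan") -> int:
    """Write genome features as GFF3 (1-based inclusive coordinates)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for feat in genome.features:
            attrs = ";".join(f"{k}={v}" for k, v in feat.attributes.items())
            fh.write(
                f"{genome.id}\t{source}\t{feat.kind}\t{feat.start + 1}\t"
                f"{feat.end}\t.\t{feat.strand}\t.\t{attrs or '.'}\n"
            )
            n += 1
    return n
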
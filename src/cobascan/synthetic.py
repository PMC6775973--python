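"""Synthetic phage genomes, diverged relatives, and mixed-community reads.

Everything downstream of assembly is testable without downloads: genomes are
generated with planted ground truth (direct terminal repeats with a GC-rich
5' region, a bidirectional hairpin terminator between the two genomic arms),
and read libraries carry a truth table of error-free placements and edit
counts. Defaults mirror marine podophage genomes: ~40 kb linear genomes at
G+C ~0.47 with 150-250 bp DTRs.

Every operation draws from one seeded NumPy generator per call, so identical
seeds give bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import (
    AlignmentRecord,
    AnnotatedGenome,
    Feature,
    SequenceRecord,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=_base_probs(gc))


@dataclass
class GenomeSpec:
    """Parameters of one simulated phage genome."""

    length: int = 40_000
    gc: float = 0.47
    dtr_length: int = 170
    terminator_offset: float = 0.5
    seed: int = 0
    dtr_gc_boost: float = 0.15
    dtr_gc_region: int = 30
    stem_length: int = 12

    def validate(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0,1)")
        if self.dtr_length < 0 or self.dtr_length >= self.length / 4:
            raise ValueError("dtr_length must satisfy 0 <= dtr_length < length/4")
        if not 0 < self.terminator_offset < 1:
            raise ValueError("terminator_offset must be in (0,1)")
        if self.length < 1000:
            raise ValueError("genome length must be >= 1000")


# cassette layout: A-tract, spacer, stem, loop, revcomp(stem), spacer, T-tract.
# The spacers (CC / AC) cannot base-pair across the hairpin, so stem extension
# stops deterministically at the planted stem; without them the A/T tracts
# pair with each other and shift the detected hairpin start.
_TRACT = 6
_LEFT_SPACER = "CC"
_RIGHT_SPACER = "AC"
_LOOP = "CTTA"


def terminator_cassette(rng: np.random.Generator, stem_length: int = 12) -> tuple[str, int]:
    """Return (cassette sequence, offset of the hairpin stem start within it)."""
    stem = "".join(rng.choice(["G", "C"], size=stem_length))
    cassette = (
        "A" * _TRACT
        + _LEFT_SPACER
        + stem
        + _LOOP
        + reverse_complement(stem)
        + _RIGHT_SPACER
        + "T" * _TRACT
    )
    return cassette, _TRACT + len(_LEFT_SPACER)


def simulate_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Simulate a linear phage genome with planted DTR and terminator.

    The first ``dtr_length`` bases are duplicated exactly at the 3' end; the
    first ``dtr_gc_region`` bases of the repeat are drawn at elevated GC
    (``gc + dtr_gc_boost``, capped at 0.9), emulating the conserved G+C-rich
    region at the 5' end of cobaviral DTRs. A palindromic GC hairpin cassette
    flanked by T-tracts on both strands is planted with its hairpin midpoint
    at ``round(terminator_offset * length)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seq = _random_bases(rng, spec.length, spec.gc)

    features: list[Feature] = []
    d = spec.dtr_length
    if d > 0:
        region = min(spec.dtr_gc_region, d)
        seq[:region] = _random_bases(rng, region, min(spec.gc + spec.dtr_gc_boost, 0.9))
        seq[spec.length - d:] = seq[:d]
        features.append(Feature("direct_terminal_repeat", 0, d, "+", {"copy": "5p"}))
        features.append(
            Feature("direct_terminal_repeat", spec.length - d, spec.length, "+", {"copy": "3p"})
        )

    cassette, stem_off = terminator_cassette(rng, spec.stem_length)
    hairpin_len = 2 * spec.stem_length + len(_LOOP)
    # hairpin midpoint lands on terminator_offset * length
    stem_start = int(round(spec.terminator_offset * spec.length)) - hairpin_len // 2
    cas_start = stem_start - stem_off
    if cas_start < d or cas_start + len(cassette) > spec.length - d:
        raise ValueError("terminator cassette would overlap the terminal repeats")
    seq[cas_start:cas_start + len(cassette)] = np.frombuffer(
        cassette.encode(), dtype="S1"
    )
    hairpin_end = stem_start + 2 * spec.stem_length + len(_LOOP)
    features.append(
        Feature(
            "terminator",
            stem_start,
            hairpin_end,
            ".",
            {
                "cassette_start": cas_start,
                "cassette_end": cas_start + len(cassette),
                "stem_len": spec.stem_length,
                "loop_len": len(_LOOP),
                "bidirectional": True,
            },
        )
    )
    mid = (stem_start + hairpin_end) // 2
    features.append(Feature("arm_boundary", mid, mid, ".", {}))

    return AnnotatedGenome(
        id=f"sim{spec.seed}",
        sequence=seq.tobytes().decode(),
        features=features,
        provenance={
            "generator": "simulate_genome",
            "seed": spec.seed,
            "length": spec.length,
            "gc": spec.gc,
            "dtr_length": spec.dtr_length,
            "terminator_offset": spec.terminator_offset,
        },
    )


def diverge_genome(genome: AnnotatedGenome, subst_rate: float, seed: int = 0) -> AnnotatedGenome:
    """Apply i.i.d. substitutions; expected identity is 1 - subst_rate.

    Annotations are carried over with unchanged coordinates.
    """
    if not 0 <= subst_rate < 0.5:
        raise ValueError("subst_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.sequence.encode(), dtype="S1").copy()
    hit = np.where(rng.random(len(arr)) < subst_rate)[0]
    if len(hit):
        # substitute to one of the three alternative bases
        cur = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=len(hit))
        arr[hit] = _BASES[(cur + shift) % 4]
    return AnnotatedGenome(
        id=f"{genome.id}_div{subst_rate:g}s{seed}",
        sequence=arr.tobytes().decode(),
        features=[replace(f, attributes=dict(f.attributes)) for f in genome.features],
        provenance={
            **genome.provenance,
            "diverged_from": genome.id,
            "subst_rate": subst_rate,
            "diverge_seed": seed,
        },
    )


def _make_qualities(n: int, quality: int, low: int, tail: int) -> list[int]:
    if tail <= 0 or low >= quality:
        return [quality] * n
    quals = [quality] * n
    for i in range(max(0, n - tail), n):
        frac = (i - (n - tail)) / max(1, tail - 1)
        quals[i] = max(2, int(round(quality - frac * (quality - low))))
    return quals


def _simulate_n_reads(
    genome: AnnotatedGenome,
    n_reads: int,
    read_length: int,
    subst_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    quality: int = 37,
    quality_low: int | None = None,
    quality_tail: int = 0,
) -> tuple[list[SequenceRecord], list[AlignmentRecord]]:
    L = len(genome)
    if read_length >= L:
        raise ValueError("read_length must be smaller than the genome")
    arr = np.frombuffer(genome.sequence.encode(), dtype="S1")
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    minus = rng.random(n_reads) < 0.5
    reads: list[SequenceRecord] = []
    truth: list[AlignmentRecord] = []
    low = quality if quality_low is None else quality_low
    for i in range(n_reads):
        start = int(starts[i])
        n_ins = int(rng.binomial(read_length, indel_rate / 2)) if indel_rate else 0
        n_del = int(rng.binomial(read_length, indel_rate / 2)) if indel_rate else 0
        ref_len = min(read_length - n_ins + n_del, L - start)
        n_del = min(n_del, max(0, ref_len - 1))
        seg = arr[start:start + ref_len].copy()
        if n_del:
            keep = np.ones(ref_len, bool)
            keep[rng.choice(ref_len, size=n_del, replace=False)] = False
            seg = seg[keep]
        n_sub = int(rng.binomial(len(seg), subst_rate)) if subst_rate else 0
        if n_sub:
            pos = rng.choice(len(seg), size=n_sub, replace=False)
            cur = np.searchsorted(_BASES, seg[pos])
            seg[pos] = _BASES[(cur + rng.integers(1, 4, size=n_sub)) % 4]
        if n_ins:
            out = np.empty(len(seg) + n_ins, dtype="S1")
            ins_at = np.sort(rng.choice(len(seg) + n_ins, size=n_ins, replace=False))
            mask = np.ones(len(out), bool)
            mask[ins_at] = False
            out[mask] = seg
            out[ins_at] = _random_bases(rng, n_ins, 0.5)
            seg = out
        read_seq = seg.tobytes().decode()
        strand = "-" if minus[i] else "+"
        if strand == "-":
            read_seq = reverse_complement(read_seq)
        rid = f"{genome.id}|r{i:06d}"
        reads.append(
            SequenceRecord(
                id=rid,
                sequence=read_seq,
                qualities=_make_qualities(len(read_seq), quality, low, quality_tail),
            )
        )
        truth.append(
            AlignmentRecord(
                read_id=rid,
                genome_id=genome.id,
                ref_start=start,
                ref_end=start + ref_len,
                strand=strand,
                matches=ref_len - n_del - n_sub,
                mismatches=n_sub,
                insertions=n_ins,
                deletions=n_del,
            )
        )
    return reads, truth


def simulate_reads(
    genome: AnnotatedGenome,
    depth: float,
    read_length: int = 150,
    subst_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    quality: int = 37,
    quality_low: int | None = None,
    quality_tail: int = 0,
) -> tuple[list[SequenceRecord], list[AlignmentRecord]]:
    """Simulate shotgun reads with i.i.d. substitution/indel errors.

    Start positions are uniform over the linear genome, about half the reads
    are reverse-complemented, and the returned truth records hold the
    error-free placement and edit counts of every read. Total read bases are
    ``depth * len(genome)`` to within one read.
    """
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * len(genome) / read_length))
    return _simulate_n_reads(
        genome, n_reads, read_length, subst_rate, indel_rate, rng,
        quality=quality, quality_low=quality_low, quality_tail=quality_tail,
    )


@dataclass
class CommunitySpec:
    """A mixed community of genomes with per-genome abundance weights."""

    members: list[tuple[AnnotatedGenome, float]]
    total_bases: int = 10_000_000
    read_length: int = 150
    subst_rate: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        w = sum(frac for _, frac in self.members)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w}")
        if not self.members:
            raise ValueError("community needs at least one member")


def simulate_community(spec: CommunitySpec) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate a community read library plus a planted-truth table.

    Genome g receives ``weight_g * total_bases`` read bases in expectation
    (reads assigned multinomially). The truth table reports, per genome, the
    planted aligned reference bases and the expected per-Gb abundance
    ``planted_bases / genome_length / (total_bases / 1e9)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_total = int(round(spec.total_bases / spec.read_length))
    weights = np.array([w for _, w in spec.members])
    counts = rng.multinomial(n_total, weights)
    all_reads: list[SequenceRecord] = []
    rows = []
    for (genome, w), n_reads in zip(spec.members, counts):
        reads, truth = _simulate_n_reads(
            genome,
            int(n_reads),
            spec.read_length,
            spec.subst_rate,
            spec.indel_rate,
            rng,
        )
        all_reads.extend(reads)
        planted = sum(t.ref_end - t.ref_start for t in truth)
        rows.append(
            {
                "genome_id": genome.id,
                "weight": w,
                "n_reads": int(n_reads),
                "genome_length": len(genome),
                "planted_bases": planted,
                "planted_abundance_per_gb": planted / len(genome) / (spec.total_bases / 1e9),
            }
        )
    return all_reads, pd.DataFrame(rows)


def dinucleotide_shuffle(sequence: str, seed: int = 0) -> str:
    """Shuffle a sequence preserving exact dinucleotide counts.

    Altschul-Erikson: sample a random last-edge spanning arborescence into the
    terminal vertex, shuffle the remaining edges, and walk the Eulerian path.
    """
    if len(sequence) < 3:
        return sequence
    rng = np.random.default_rng(seed)
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    first, last = sequence[0], sequence[-1]
    vertices = list(edges)
    for _ in range(1000):
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        # last-edge graph must reach `last` from every vertex
        ok = True
        for v in last_edge:
            seen = set()
            u = v
            while u != last and u in last_edge and u not in seen:
                seen.add(u)
                u = last_edge[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")
    pools = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        pools[v] = pool[::-1]  # pop() from the front order
    out = [first]
    v = first
    while pools.get(v):
        nxt = pools[v].pop()
        out.append(nxt)
        v = nxt
    if len(out) != len(sequence):  # pragma: no cover - guarded by retry loop
        raise RuntimeError("Eulerian walk incomplete")
    return "".join(out)
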
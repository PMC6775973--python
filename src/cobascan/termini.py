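"""Direct terminal repeat detection, terminus location and genome reorientation.

Short DTRs (order 150-250 bp) at both ends of a linear phage genome are the
signature of T7-like packaging. This module finds them by end-anchored
comparison of genome prefix and suffix (substitutions only; indels between
the two copies would inflate false repeats), locates a known DTR in related
genomes down to ~70% nucleotide identity, reorders circularly permuted
genomes so the repeat's 5' end defines position zero, and scores read
alignment-start pileups as terminus evidence.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import edlib
import numpy as np

from ._seedalign import cigar_counts
from .records import AnnotatedGenome, Feature, gc_fraction, reverse_complement


@dataclass
class DTRRecord:
    genome_id: str
    length: int
    seq: str
    mismatches: int
    five_prime_interval: tuple[int, int]
    three_prime_interval: tuple[int, int]
    inverted: bool = False


@dataclass
class TerminusEvidence:
    position: int
    start_pileup: int
    zscore: float


def _to_seq(genome) -> tuple[str, str]:
    if hasattr(genome, "sequence"):
        return genome.id, genome.sequence
    return "genome", str(genome).upper()


def _seed_candidate_lengths(seq: str, min_len: int, seed_len: int = 16) -> set[int]:
    """Candidate repeat lengths from prefix seeds found near the 3' end."""
    n = len(seq)
    lengths: set[int] = set()
    half = n // 2
    for off in (0, seed_len, 2 * seed_len, 3 * seed_len):
        seed = seq[off:off + seed_len]
        if len(seed) < seed_len:
            break
        pos = seq.find(seed, half)
        while pos != -1:
            L = n - pos + off
            if min_len <= L <= half:
                lengths.add(L)
            pos = seq.find(seed, pos + 1)
    return lengths


def find_terminal_repeat(
    genome,
    min_len: int = 30,
    max_mismatch_frac: float = 0.02,
    inverted: bool = False,
) -> DTRRecord | None:
    """Longest end-anchored prefix/suffix repeat within the mismatch tolerance.

    With ``inverted=True`` the prefix is compared against the
    reverse-complemented suffix instead (mis-assembly diagnosis); inverted
    repeats are reported but should never drive reorientation.
    """
    gid, seq = _to_seq(genome)
    n = len(seq)
    if n <= 2 * min_len:
        raise ValueError("genome shorter than twice the minimum repeat length")
    arr = np.frombuffer(seq.encode(), dtype="S1")
    if inverted:
        # prefix of genome vs prefix of revcomp(genome): shift-free scan
        rc = np.frombuffer(reverse_complement(seq).encode(), dtype="S1")
        half = n // 2
        mism = np.cumsum(arr[:half] != rc[:half])
        best = None
        for L in range(half, min_len - 1, -1):
            if mism[L - 1] <= max_mismatch_frac * L:
                best = (L, int(mism[L - 1]))
                break
        if best is None:
            return None
        L, mm = best
        return DTRRecord(gid, L, seq[:L], mm, (0, L), (n - L, n), inverted=True)

    best = None
    for L in sorted(_seed_candidate_lengths(seq, min_len), reverse=True):
        mm = int(np.count_nonzero(arr[:L] != arr[n - L:]))
        if mm <= max_mismatch_frac * L:
            best = (L, mm)
            break
    if best is None:
        return None
    L, mm = best
    return DTRRecord(gid, L, seq[:L], mm, (0, L), (n - L, n))


def locate_dtr_by_reference(
    target_genome,
    reference_dtr: str,
    min_identity: float = 0.70,
    min_coverage: float = 0.80,
    max_hits: int = 10,
    circular: bool = False,
) -> list[tuple[tuple[int, int], float]]:
    """All placements of a reference DTR in a target at >= min_identity.

    Related phages carry DTRs at 70-100% nucleotide identity, so a known DTR
    anchors the termini of relatives. Hits are found by repeated semi-global
    alignment with masking, must cover >= min_coverage of the reference, and
    are returned sorted by position (identity = matches / alignment columns).

    With ``circular=True`` the target is treated as a circular permutation:
    the search wraps the origin and a hit may extend past the sequence end
    (its interval end then exceeds the target length).
    """
    if len(reference_dtr) < 30:
        raise ValueError("reference DTR must be at least 30 bp")
    _, target = _to_seq(target_genome)
    query = reference_dtr.upper()
    n = len(target)
    wrap = min(n, len(query) + 20) if circular else 0
    masked = list(target + target[:wrap])
    hits: list[tuple[tuple[int, int], float]] = []
    max_k = max(1, int(len(query) * (1 - min_identity) * 2))
    for _ in range(max_hits):
        res = edlib.align(query, "".join(masked), mode="HW", task="path", k=max_k)
        if res["editDistance"] < 0:
            break
        loc = res["locations"][0]
        m, x, i, d = cigar_counts(res["cigar"])
        cols = m + x + i + d
        identity = m / cols if cols else 0.0
        covered = (m + x + i) / len(query)
        if identity < min_identity or covered < min_coverage:
            break
        start, end = loc[0], loc[1] + 1
        if start < n:  # hits living entirely in the wrap copy are duplicates
            hits.append(((start, end), identity))
        for p in range(start, end):
            masked[p] = "N"
            for twin in (p - n, p + n):  # keep the wrap copy in sync
                if 0 <= twin < len(masked):
                    masked[twin] = "N"
    return sorted(hits)


def reorient_to_dtr(
    genome: AnnotatedGenome, dtr_hit_interval: tuple[int, int],
    max_mismatch_frac: float = 0.02,
) -> AnnotatedGenome:
    """Rotate a circularly permuted genome so the DTR 5' end is position zero.

    The input is treated as one circular permutation of the genome: the
    output starts at the 5' end of the DTR hit and, unless the rotated
    sequence already ends with the repeat, the leading repeat copy is
    appended at the 3' end so both termini carry it. The rotation amount is
    recorded in the provenance.
    """
    s, e = dtr_hit_interval
    n = len(genome)
    # e may exceed n for a hit wrapping the origin of a circular permutation
    if not (0 <= s < e and s < n and e - s <= n):
        raise ValueError(f"hit interval [{s},{e}) out of genome bounds [0,{n})")
    d = e - s
    seq = genome.sequence
    rot = seq[s:] + seq[:s]
    arr0 = np.frombuffer(rot[:d].encode(), dtype="S1")
    arr1 = np.frombuffer(rot[-d:].encode(), dtype="S1")
    has_suffix_copy = np.count_nonzero(arr0 != arr1) <= max_mismatch_frac * d
    out_seq = rot if has_suffix_copy else rot + rot[:d]
    features = []
    for f in genome.features:
        ns = (f.start - s) % n
        ne = ns + (f.end - f.start)
        if ne <= n:  # features wrapping the new origin are dropped
            features.append(replace(f, start=ns, end=ne, attributes=dict(f.attributes)))
    features.append(Feature("direct_terminal_repeat", 0, d, "+", {"copy": "5p"}))
    features.append(
        Feature(
            "direct_terminal_repeat",
            len(out_seq) - d,
            len(out_seq),
            "+",
            {"copy": "3p", "appended": not has_suffix_copy},
        )
    )
    return AnnotatedGenome(
        id=genome.id,
        sequence=out_seq,
        features=features,
        provenance={**genome.provenance, "rotation": s, "reoriented": True},
    )


def termini_from_alignments(
    genome, alignments, z_threshold: float = 6.0, merge_bp: int = 5
) -> list[TerminusEvidence]:
    """Positions whose alignment-start pileup exceeds a uniform-start null.

    Physical genome termini produce an excess of alignments starting exactly
    at the terminus (left-clipped reads pile at position zero). Start counts
    are standardized against the uniform null (mean N/L, Poisson spread);
    positions with z >= z_threshold are reported, merged within ``merge_bp``.
    """
    _, seq = _to_seq(genome)
    L = len(seq)
    starts = [a.ref_start for a in alignments]
    N = len(starts)
    if N < 100:
        raise ValueError(f"need at least 100 alignments, got {N}")
    counts = np.bincount(np.asarray(starts), minlength=L)
    mean = N / L
    sd = np.sqrt(mean)
    z = (counts - mean) / sd
    hot = np.where(z >= z_threshold)[0]
    evidence: list[TerminusEvidence] = []
    for p in hot:
        if evidence and p - evidence[-1].position <= merge_bp:
            if counts[p] > evidence[-1].start_pileup:
                evidence[-1] = TerminusEvidence(int(p), int(counts[p]), float(z[p]))
        else:
            evidence.append(TerminusEvidence(int(p), int(counts[p]), float(z[p])))
    return evidence


def dtr_gc_profile(dtrs: list[DTRRecord], window: int = 20) -> tuple[np.ndarray, int]:
    """Sliding-window GC averaged across DTRs, plus the max-GC window start.

    Windows are tiled from the repeat 5' end with step 1 up to the shortest
    repeat; cobaviral DTRs carry a conserved G+C-rich region at the 5' end,
    which shows up as an argmax near zero.
    """
    if not dtrs:
        raise ValueError("no DTR records given")
    shortest = min(d.length for d in dtrs)
    if shortest < window:
        raise ValueError("all DTRs must be at least one window long")
    n_windows = shortest - window + 1
    profile = np.zeros(n_windows)
    for d in dtrs:
        profile += [gc_fraction(d.seq[i:i + window]) for i in range(n_windows)]
    profile /= len(dtrs)
    return profile, int(np.argmax(profile))
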
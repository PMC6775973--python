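"""Seed-and-extend read/fragment alignment against small genome databases.

Exact k-mer seeds vote for (genome, diagonal) candidates on both strands;
each candidate is verified by a banded semi-global alignment (edlib, free
gaps at the ends of the reference window). One best-scoring location per
query is reported, ties broken by (genome id, leftmost position, + strand).
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .records import AlignmentRecord, reverse_complement

_CIG = re.compile(r"(\d+)([=XID])")


def cigar_counts(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, insertions, deletions) from an extended CIGAR."""
    m = x = i = d = 0
    for num, op in _CIG.findall(cigar):
        n = int(num)
        if op == "=":
            m += n
        elif op == "X":
            x += n
        elif op == "I":
            i += n
        elif op == "D":
            d += n
    return m, x, i, d


@dataclass
class _Hit:
    genome_id: str
    ref_start: int
    ref_end: int
    strand: str
    edit_distance: int
    cigar: str


class GenomeIndex:
    """Exact k-mer index over a set of reference genomes."""

    def __init__(self, genomes: dict[str, str], k: int = 15):
        self.k = k
        self.genomes = {gid: seq.upper() for gid, seq in genomes.items()}
        self.ids = sorted(self.genomes)
        self._index: dict[str, list[tuple[int, int]]] = {}
        for gidx, gid in enumerate(self.ids):
            seq = self.genomes[gid]
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos:pos + k], []).append((gidx, pos))

    def _candidates(self, query: str, seed_stride: int, band: int):
        k = self.k
        offsets = list(range(0, len(query) - k + 1, seed_stride))
        if offsets and offsets[-1] != len(query) - k:
            offsets.append(len(query) - k)
        votes: dict[tuple[int, int], int] = {}
        for off in offsets:
            for gidx, pos in self._index.get(query[off:off + k], ()):
                key = (gidx, (pos - off) // max(band, 1))
                votes[key] = votes.get(key, 0) + 1
        # strongest diagonals first; deterministic tie order
        return sorted(votes, key=lambda kk: (-votes[kk], kk))

    def map_sequence(
        self,
        query: str,
        seed_stride: int = 11,
        band: int = 16,
        max_candidates: int = 4,
        max_edit_frac: float = 0.35,
    ) -> _Hit | None:
        """Best semi-global placement of query (either strand), or None."""
        query = query.upper()
        best: tuple | None = None
        max_k = int(len(query) * max_edit_frac) + 1
        for strand in "+-":
            s = query if strand == "+" else reverse_complement(query)
            for gidx, diag_bucket in self._candidates(s, seed_stride, band)[:max_candidates]:
                gid = self.ids[gidx]
                ref = self.genomes[gid]
                approx = diag_bucket * band
                w0 = max(0, approx - 2 * band)
                w1 = min(len(ref), approx + len(s) + 3 * band)
                res = edlib.align(s, ref[w0:w1], mode="HW", task="path", k=max_k)
                if res["editDistance"] < 0:
                    continue
                loc = res["locations"][0]
                hit = _Hit(
                    genome_id=gid,
                    ref_start=w0 + loc[0],
                    ref_end=w0 + loc[1] + 1,
                    strand=strand,
                    edit_distance=res["editDistance"],
                    cigar=res["cigar"],
                )
                key = (hit.edit_distance, hit.genome_id, hit.ref_start, hit.strand)
                if best is None or key < best[0]:
                    best = (key, hit)
        return best[1] if best else None


def hit_to_alignment(read_id: str, hit: _Hit) -> AlignmentRecord:
    m, x, i, d = cigar_counts(hit.cigar)
    return AlignmentRecord(
        read_id=read_id,
        genome_id=hit.genome_id,
        ref_start=hit.ref_start,
        ref_end=hit.ref_end,
        strand=hit.strand,
        matches=m,
        mismatches=x,
        insertions=i,
        deletions=d,
        cigar=hit.cigar,
    )
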
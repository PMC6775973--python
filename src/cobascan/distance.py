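"""Genome-level similarity and OPTSIL-style threshold clustering.

Completeness filtering (contigs under ~85% of a complete reference genome
length are discarded), fragment-based average nucleotide identity as the
genome similarity surrogate, and agglomerative F-linkage clustering: two
clusters fuse while at least a fraction F of their inter-cluster distances
fall below the threshold. F = 1 reproduces complete linkage cut at the
threshold; F -> 0+ approaches single linkage.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seedalign import GenomeIndex
from .protein_clustering import ClusterSet


def _seq_of(g) -> str:
    return g.sequence if hasattr(g, "sequence") else str(g).upper()


def _id_of(g, fallback: str) -> str:
    return getattr(g, "id", fallback)


def length_filter(contigs, min_len: int = 34_000) -> tuple[list, list]:
    """Split contigs into (retained, discarded) by a completeness cutoff.

    Contigs *smaller than* ``min_len`` are considered incomplete: a contig of
    exactly ``min_len`` bases is retained. Input order is preserved.
    """
    retained, discarded = [], []
    for c in contigs:
        (retained if len(_seq_of(c)) >= min_len else discarded).append(c)
    return retained, discarded


def fragment_identity(
    g1,
    g2,
    frag_len: int = 1020,
    min_frag_identity: float = 0.30,
    k: int = 13,
) -> tuple[float, float]:
    """Fragment-ANI between two genomes: (mean identity, aligned fraction).

    Each genome is tiled into non-overlapping ``frag_len`` windows; every
    fragment is placed in the other genome by seed-and-extend semi-global
    alignment (both strands). Identity is matches / alignment columns per
    aligned fragment; the two directions are averaged. A stand-in for
    BLAST-based intergenomic distances, adequate for ANI-scale comparisons.
    """
    def one_direction(qseq: str, tseq: str) -> tuple[float, float]:
        index = GenomeIndex({"t": tseq}, k=k)
        n_frags = len(qseq) // frag_len
        if n_frags == 0:
            raise ValueError(f"genome shorter than one fragment ({frag_len} bp)")
        idents = []
        for i in range(n_frags):
            frag = qseq[i * frag_len:(i + 1) * frag_len]
            hit = index.map_sequence(frag, seed_stride=frag_len // 8)
            if hit is None:
                continue
            from ._seedalign import cigar_counts

            m, x, ins, dele = cigar_counts(hit.cigar)
            identity = m / (m + x + ins + dele)
            if identity >= min_frag_identity:
                idents.append(identity)
        if not idents:
            return 0.0, 0.0
        return float(np.mean(idents)), len(idents) / n_frags

    i12, f12 = one_direction(_seq_of(g1), _seq_of(g2))
    i21, f21 = one_direction(_seq_of(g2), _seq_of(g1))
    if f12 == 0.0 and f21 == 0.0:
        return 0.0, 0.0
    weights = [f for f in (f12, f21) if f > 0]
    idents = [i for i, f in ((i12, f12), (i21, f21)) if f > 0]
    return float(np.mean(idents)), float((f12 + f21) / 2)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    aligned_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if self.d.min() < 0 or self.d.max() > 1:
            raise ValueError("distances must lie in [0,1]")

    def lookup(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


def distance_matrix(genomes, frag_len: int = 1020) -> DistanceMatrix:
    """Pairwise fragment-ANI distances (d = 1 - identity) for >= 2 genomes."""
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    ids = [_id_of(g, f"g{i}") for i, g in enumerate(genomes)]
    n = len(genomes)
    d = np.zeros((n, n))
    af = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident, frac = fragment_identity(genomes[i], genomes[j], frag_len=frag_len)
            d[i, j] = d[j, i] = 1.0 - ident
            af[i, j] = af[j, i] = frac
    return DistanceMatrix(ids, d, af)


@dataclass
class ClusterParams:
    threshold: float = 0.05
    f_link: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be in [0,1]")
        if not 0 < self.f_link <= 1:
            raise ValueError("f_link must be in (0,1]")


def f_link_cluster(dm: DistanceMatrix, params: ClusterParams) -> ClusterSet:
    """Agglomerative F-linkage clustering of a distance matrix.

    Starting from singletons, repeatedly merge the cluster pair with the
    highest link fraction (share of inter-cluster distances <= threshold)
    while that fraction stays >= f_link. Ties break on the smallest maximum
    inter-cluster distance, then on the lexicographically smallest member id
    — with this order F = 1 coincides exactly with complete linkage cut at
    the threshold.
    """
    link = dm.d <= params.threshold
    clusters: list[list[int]] = [[i] for i in range(len(dm.ids))]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                sub = link[np.ix_(a, b)]
                frac = sub.mean()
                if frac + 1e-12 < params.f_link:
                    continue
                max_d = dm.d[np.ix_(a, b)].max()
                lex = min(dm.ids[a[0]], dm.ids[b[0]])
                key = (-frac, max_d, lex)
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        merged = sorted(clusters[i] + clusters[j], key=lambda x: dm.ids[x])
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    out = sorted(
        (sorted(dm.ids[i] for i in c) for c in clusters), key=lambda c: c[0]
    )
    return ClusterSet(
        out, params={"threshold": params.threshold, "f_link": params.f_link}
    )
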
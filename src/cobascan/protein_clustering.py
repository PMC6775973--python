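"""All-vs-all protein similarity graph and Markov clustering.

Proteins are compared by Smith-Waterman local alignment (BLOSUM62, gap open
11 / extend 1 in BLAST convention); raw scores are converted to bit scores
and e-values with gapped Karlin-Altschul constants (lambda = 0.267,
K = 0.041). Edges passing BOTH an e-value and a bit-score threshold
(defaults 1e-5 and 50) enter an undirected weighted graph, which is
partitioned by Markov clustering at inflation 2 — the classic protein-family
workflow behind "pc" cluster numbering of phage comparative genomics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .records import IUPAC_AA, SequenceRecord

GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041


@dataclass
class SimilarityEdge:
    a: str
    b: str
    raw_score: float
    bitscore: float
    evalue: float


@dataclass
class ClusterSet:
    """A partition of item ids into clusters, with the producing parameters."""

    clusters: list[list[str]]
    params: dict = field(default_factory=dict)
    converged: bool = True

    def membership(self) -> dict[str, int]:
        return {item: ci for ci, cl in enumerate(self.clusters) for item in cl}

    def as_sets(self) -> set[frozenset]:
        return {frozenset(c) for c in self.clusters}


def _aligner(gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST convention: a gap of length g costs open + g * extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def karlin_altschul(raw_score: float, m: int, n: int,
                    lam: float = GAPPED_LAMBDA, k: float = GAPPED_K) -> tuple[float, float]:
    """(bitscore, evalue) for a raw score against an m x n search space."""
    bitscore = (lam * raw_score - math.log(k)) / math.log(2)
    evalue = k * m * n * math.exp(-lam * raw_score)
    return bitscore, evalue


def pairwise_protein_scores(
    proteins: list[SequenceRecord],
    gap_open: int = 11,
    gap_extend: int = 1,
    lam: float = GAPPED_LAMBDA,
    k: float = GAPPED_K,
) -> list[SimilarityEdge]:
    """Smith-Waterman scores for every unordered protein pair."""
    for p in proteins:
        if len(p.sequence) < 10:
            raise ValueError(f"protein {p.id} shorter than 10 residues")
        bad = set(p.sequence) - IUPAC_AA
        if bad:
            raise ValueError(f"protein {p.id} has non-amino-acid characters {bad}")
    aligner = _aligner(gap_open, gap_extend)
    edges: list[SimilarityEdge] = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            a, b = proteins[i], proteins[j]
            raw = float(aligner.score(a.sequence, b.sequence))
            bits, ev = karlin_altschul(raw, len(a), len(b), lam, k)
            edges.append(SimilarityEdge(a.id, b.id, raw, bits, ev))
    return edges


def build_graph(
    edges: list[SimilarityEdge],
    max_evalue: float = 1e-5,
    min_bitscore: float = 50.0,
    all_ids: list[str] | None = None,
) -> nx.Graph:
    """Keep edges passing both thresholds; weight = bitscore.

    Proteins named in ``all_ids`` (or touched by any input edge) are kept as
    nodes even when every incident edge fails, so singletons survive.
    """
    g = nx.Graph()
    for e in edges:
        g.add_node(e.a)
        g.add_node(e.b)
        if e.evalue <= max_evalue and e.bitscore >= min_bitscore and e.a != e.b:
            g.add_edge(e.a, e.b, weight=e.bitscore)
    for node in all_ids or ():
        g.add_node(node)
    return g


def markov_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-12,
) -> ClusterSet:
    """Markov clustering (expansion + inflation) of a weighted graph.

    Self-loops are added with the node's maximum incident weight (1 for
    isolated nodes), columns are normalized to a stochastic flow matrix, and
    expansion (matrix square) alternates with inflation (elementwise power,
    renormalize) until the largest elementwise change drops below ``tol``.
    Clusters are the connected structures of the converged flow.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return ClusterSet([], {"inflation": inflation})
    pos = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[pos[a], pos[b]] = M[pos[b], pos[a]] = w
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = M ** inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(M > max(prune, 1e-9))
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    clusters = [
        sorted(nodes[i] for i in comp)
        for comp in nx.connected_components(support)
    ]
    clusters.sort(key=lambda c: c[0])
    return ClusterSet(
        clusters,
        params={"inflation": inflation, "max_iter": max_iter, "tol": tol},
        converged=converged,
    )


def cluster_proteins(
    proteins: list[SequenceRecord],
    max_evalue: float = 1e-5,
    min_bitscore: float = 50.0,
    inflation: float = 2.0,
) -> tuple[ClusterSet, list[SimilarityEdge]]:
    """score -> threshold -> graph -> MCL convenience chain."""
    edges = pairwise_protein_scores(proteins)
    graph = build_graph(
        edges, max_evalue, min_bitscore, all_ids=[p.id for p in proteins]
    )
    clusters = markov_cluster(graph, inflation=inflation)
    clusters.params.update({"max_evalue": max_evalue, "min_bitscore": min_bitscore})
    return clusters, edges
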
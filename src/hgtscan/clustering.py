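"""Homolog clustering: local-alignment similarity graph + Markov clustering.

Gene sequences are compared all-against-all by Smith-Waterman local
alignment on both strands (match +1, mismatch -1, gap open -2, gap
extend -1); pairs scoring at or above a threshold — calibrated against
a shuffled-sequence null when not given — become edges of an
undirected similarity graph, which is partitioned by Markov clustering
(alternating matrix expansion and entrywise inflation until the flow
matrix converges).  Retained clusters must span the outgroup, the
parasites, their closest autotrophic relative, and the host clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .panel import TaxonPanel
from .simulate import revcomp


@dataclass
class SimilarityGraph:
    nodes: list
    edges: list = field(default_factory=list)   # (i, j, weight)

    def __post_init__(self) -> None:
        for i, j, w in self.edges:
            if i == j:
                raise ValueError("self-loops are not stored")
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"bad edge weight {w}")

    def adjacency(self) -> np.ndarray:
        idx = {n: k for k, n in enumerate(self.nodes)}
        A = np.zeros((len(self.nodes),) * 2)
        for i, j, w in self.edges:
            A[idx[i], idx[j]] = A[idx[j], idx[i]] = w
        return A


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def local_alignment_score(a: str, b: str) -> float:
    """Best Smith-Waterman score over both strands."""
    aligner = _aligner()
    return float(max(aligner.score(a, b), aligner.score(a, revcomp(b))))


def calibrate_min_score(seqs: dict[str, str], n_pairs: int = 1000,
                        seed: int = 0, quantile: float = 0.99) -> float:
    """Score threshold from a shuffled-pair null distribution.

    Pairs of sequences are drawn, each shuffled to destroy homology
    while preserving composition, and the chosen quantile of their
    local-alignment scores becomes the threshold.
    """
    rng = np.random.default_rng(seed)
    pool = list(seqs.values())
    if len(pool) < 2:
        raise ValueError("need at least 2 sequences")
    scores = np.empty(n_pairs)
    for i in range(n_pairs):
        x, y = rng.choice(len(pool), size=2, replace=True)
        a = "".join(rng.permutation(list(pool[x])))
        b = "".join(rng.permutation(list(pool[y])))
        scores[i] = local_alignment_score(a, b)
    return float(np.quantile(scores, quantile))


def similarity_graph(seqs: dict[str, str], min_score: float) -> SimilarityGraph:
    """All-against-all local alignment; edge iff score >= min_score."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    names = list(seqs)
    edges = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            score = local_alignment_score(seqs[names[i]], seqs[names[j]])
            if score >= min_score:
                edges.append((names[i], names[j], score))
    return SimilarityGraph(names, edges)


def mcl_cluster(graph: SimilarityGraph, inflation: float = 2.0,
                expansion: int = 2, tol: float = 1e-6,
                max_iter: int = 200, add_self_loops: bool = True) -> list[list]:
    """Markov clustering of the similarity graph.

    The column-stochastic flow matrix is alternately raised to the
    ``expansion`` power and inflated entrywise (power ``inflation``,
    then column renormalisation) until the largest columnwise change
    falls below ``tol``; clusters are read off the attractor structure.
    Self-loops (weight = max incident weight, 1 for isolated nodes)
    are added first, the standard regularisation.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    if expansion < 2:
        raise ValueError("expansion must be at least 2")
    A = graph.adjacency()
    n = len(graph.nodes)
    if add_self_loops:
        loops = A.max(axis=0)
        loops[loops == 0] = 1.0
        A = A + np.diag(loops)
    M = A / A.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        Mexp = np.linalg.matrix_power(M, expansion)
        Minf = Mexp ** inflation
        Minf /= Minf.sum(axis=0, keepdims=True)
        change = np.abs(Minf - M).max()
        M = Minf
        if change < tol:
            break
    else:
        raise RuntimeError(f"MCL failed to converge; residual {change:.2e}")
    # attractor-based extraction: union the supports of rows with
    # positive diagonal, merging overlaps (union-find)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    thresh = 1e-8
    for i in range(n):
        if M[i, i] > thresh:
            for j in np.nonzero(M[i] > thresh)[0]:
                parent[find(j)] = find(i)
    # nodes not covered by any attractor row join their strongest column
    for j in range(n):
        col = np.nonzero(M[:, j] > thresh)[0]
        for i in col:
            parent[find(j)] = find(i)
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(graph.nodes[i])
    return sorted(groups.values(), key=lambda c: (-len(c), c))


def filter_clusters(clusters: list[list], panel: TaxonPanel,
                    taxon_of: dict[str, str]) -> list[list]:
    """Keep clusters spanning outgroup, parasite, the parasites'
    closest autotroph, and the host clade (the rooting-and-contrast
    requirement for downstream transfer detection)."""
    needed = ("outgroup", "parasite", "vgt_sister", "host_clade")
    kept = []
    for cluster in clusters:
        roles = {panel.role(taxon_of[s]) for s in cluster}
        if all(r in roles for r in needed):
            kept.append(cluster)
    return kept
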
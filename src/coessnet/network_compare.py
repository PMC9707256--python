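"""Set-level comparison of two ranked networks.

Networks built from different essentiality scoring schemes can reach the
same global enrichment yet contain systematically different edges; this
module quantifies shared and exclusive edges/genes between two top-k
truncations, and the score agreement on common edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityRanking, top_k


@dataclass(frozen=True)
class NetworkOverlap:
    """Edge/gene overlap between two top-k networks.

    ``common_edge_scores`` pairs each common edge's score in network A
    with its score in network B, aligned row-wise.
    """

    n_edges_a: int
    n_edges_b: int
    n_edges_common: int
    n_genes_a: int
    n_genes_b: int
    n_genes_common: int
    exclusive_genes_a: frozenset[str]
    exclusive_genes_b: frozenset[str]
    common_edge_scores: np.ndarray  # (n_edges_common, 2)

    def __post_init__(self) -> None:
        assert self.n_edges_common <= min(self.n_edges_a, self.n_edges_b)
        assert self.n_genes_common <= min(self.n_genes_a, self.n_genes_b)
        assert len(self.common_edge_scores) == self.n_edges_common


def compare_networks(a: SimilarityRanking, b: SimilarityRanking,
                     k_a: int, k_b: int) -> NetworkOverlap:
    """Overlap of the top ``k_a`` edges of A with the top ``k_b`` edges of B.

    Edges are unordered gene pairs; a pair present with swapped gene order
    in the two inputs is the same edge. Comparing equal-sized networks is
    the k_a == k_b case.
    """
    ta, tb = top_k(a, k_a), top_k(b, k_b)
    score_a = {frozenset(p): s for p, s in zip(ta.pairs, ta.edges["score"])}
    score_b = {frozenset(p): s for p, s in zip(tb.pairs, tb.edges["score"])}
    common_edges = sorted(score_a.keys() & score_b.keys(), key=sorted)
    genes_a, genes_b = ta.genes, tb.genes
    common_genes = genes_a & genes_b
    scores = np.array([[score_a[e], score_b[e]] for e in common_edges],
                      dtype=float).reshape(len(common_edges), 2)
    return NetworkOverlap(
        n_edges_a=len(score_a), n_edges_b=len(score_b),
        n_edges_common=len(common_edges),
        n_genes_a=len(genes_a), n_genes_b=len(genes_b),
        n_genes_common=len(common_genes),
        exclusive_genes_a=frozenset(genes_a - genes_b),
        exclusive_genes_b=frozenset(genes_b - genes_a),
        common_edge_scores=scores)


def common_edge_correlation(overlap: NetworkOverlap) -> float:
    """Pearson correlation of the two networks' scores on common edges."""
    if overlap.n_edges_common < 3:
        raise ValueError("need at least 3 common edges")
    return float(np.corrcoef(overlap.common_edge_scores.T)[0, 1])
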
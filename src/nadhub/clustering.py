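"""CLANS-style all-vs-all similarity graph, force-directed layout, clusters.

NadE homologs recovered from PII islands separate into families (dimeric
glutamine-dependent, octameric glutamine-dependent, ammonia-dependent).  This
module builds an all-vs-all similarity graph — either by ingesting a
precomputed BLAST tabular hit table, or by aligning sequences directly with
an affine-gap Smith-Waterman (BLOSUM62) and a Karlin-Altschul-style e-value
approximation — lays it out in 2D with seeded attraction/repulsion dynamics,
and extracts clusters as connected components of the cutoff-filtered graph.

The e-value from the built-in aligner uses fixed gapped-BLOSUM62
Karlin-Altschul parameters (lambda 0.267, K 0.041) and is approximate; the
hit-table path is the exact-compatibility route.  Cluster assignment by
connected components is deterministic and brute-force checkable; the layout
is for visualisation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["SimilarityGraph", "Layout2D", "build_graph", "build_graph_from_hits",
           "force_layout", "extract_clusters", "pairwise_evalue"]

_KA_LAMBDA = 0.267   # gapped BLOSUM62, gap open 11 / extend 1
_KA_K = 0.041
_EVALUE_FLOOR = 1e-200


@dataclass
class SimilarityGraph:
    """Symmetric similarity graph with capped -log10(evalue) attractions."""

    graph: nx.Graph
    cap: float = 200.0

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    def attraction(self, i, j) -> float:
        return self.graph.edges[i, j]["attraction"] if self.graph.has_edge(i, j) else 0.0

    def add_similarity(self, i, j, evalue: float) -> None:
        if i == j:
            return
        a = min(-np.log10(max(evalue, _EVALUE_FLOOR)), self.cap) / self.cap
        a = max(a, 0.0)
        if self.graph.has_edge(i, j):
            # keep the strongest of reciprocal hits
            prev = self.graph.edges[i, j]
            if evalue < prev["evalue"]:
                prev.update(evalue=evalue, attraction=a)
        else:
            self.graph.add_edge(i, j, evalue=evalue, attraction=a)


def pairwise_evalue(score: float, m: int, n: int,
                    lam: float = _KA_LAMBDA, K: float = _KA_K) -> float:
    """Karlin-Altschul-style e-value approximation, E = K*m*n*exp(-lambda*S)."""
    return float(K * m * n * np.exp(-lam * score))


def build_graph(sequences: Mapping[str, str], evalue_cutoff: float = 1e-5,
                cap: float = 200.0) -> SimilarityGraph:
    """All-vs-all local alignment of protein sequences into a similarity graph.

    Smith-Waterman with BLOSUM62 and affine gaps (open 11, extend 1); edges
    whose approximate e-value exceeds ``evalue_cutoff`` are dropped.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0

    ids = sorted(sequences)
    sg = SimilarityGraph(nx.Graph(), cap=cap)
    sg.graph.add_nodes_from(ids)
    for a_i, i in enumerate(ids):
        for j in ids[a_i + 1:]:
            score = aligner.score(sequences[i], sequences[j])
            ev = pairwise_evalue(score, len(sequences[i]), len(sequences[j]))
            if ev <= evalue_cutoff:
                sg.add_similarity(i, j, ev)
    return sg


def build_graph_from_hits(hits: pd.DataFrame, evalue_cutoff: float = 1e-5,
                          cap: float = 200.0) -> SimilarityGraph:
    """Ingest a precomputed hit table (qseqid, sseqid, evalue columns)."""
    if hits.empty:
        raise ValueError("empty hit table")
    sg = SimilarityGraph(nx.Graph(), cap=cap)
    sg.graph.add_nodes_from(pd.unique(hits[["qseqid", "sseqid"]].values.ravel()))
    for row in hits.itertuples():
        if row.qseqid != row.sseqid and row.evalue <= evalue_cutoff:
            sg.add_similarity(row.qseqid, row.sseqid, float(row.evalue))
    return sg


@dataclass
class Layout2D:
    """2D embedding of the similarity graph."""

    coords: pd.DataFrame  # index: node id; columns x, y
    seed: int | None
    iterations: int
    mean_displacement: float


def force_layout(sg: SimilarityGraph, iterations: int = 500,
                 seed: int | None = 0, k_att: float = 0.1, k_rep: float = 1.0,
                 damping: float = 0.5, max_step: float = 1.0,
                 tolerance: float = 1e-4, eps: float = 1e-6) -> Layout2D:
    """Seeded force-directed layout: pairwise attraction along edges weighted
    by the capped similarity, inverse-square repulsion between all pairs.

    Nodes are processed in canonical (sorted) order so the result is
    invariant to input order; coincident points are separated by an ``eps``
    offset before computing repulsion.  Stops after ``iterations`` sweeps or
    when the mean per-node displacement falls below ``tolerance``.
    """
    nodes = sg.nodes
    n = len(nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1.0, 1.0, (n, 2))

    A = np.zeros((n, n))
    for i, j, data in sg.graph.edges(data=True):
        A[idx[i], idx[j]] = A[idx[j], idx[i]] = data["attraction"]

    mean_disp = np.inf
    it = 0
    for it in range(1, iterations + 1):
        delta = pos[None, :, :] - pos[:, None, :]       # delta[i,j] = x_j - x_i
        d2 = np.sum(delta**2, axis=-1)
        np.fill_diagonal(d2, 1.0)
        d2 = np.maximum(d2, eps**2)
        att = k_att * np.einsum("ij,ijk->ik", A, delta)
        # repulsion pushes i away from every j: k_rep * (x_i - x_j)/|x_i - x_j|^2
        rep = -k_rep * np.einsum("ij,ijk->ik", 1.0 / d2, delta)
        step = damping * np.clip(att + rep, -max_step, max_step)
        pos = pos + step
        mean_disp = float(np.mean(np.linalg.norm(step, axis=1)))
        if mean_disp < tolerance:
            break
    coords = pd.DataFrame(pos, index=nodes, columns=["x", "y"])
    return Layout2D(coords=coords, seed=seed, iterations=it,
                    mean_displacement=mean_disp)


def extract_clusters(sg: SimilarityGraph, evalue_cutoff: float | None = None) -> dict:
    """Cluster nodes as connected components of the cutoff-filtered graph.

    Labels are integers ordered by decreasing component size, ties broken by
    the smallest member id, so the labelling is deterministic and invariant
    to edge-list permutation.
    """
    g = sg.graph
    if evalue_cutoff is not None:
        g = nx.Graph()
        g.add_nodes_from(sg.graph.nodes)
        g.add_edges_from((i, j) for i, j, d in sg.graph.edges(data=True)
                         if d["evalue"] <= evalue_cutoff)
    comps = sorted(nx.connected_components(g),
                   key=lambda c: (-len(c), min(map(str, c))))
    return {node: label for label, comp in enumerate(comps)
            for node in sorted(comp, key=str)}
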
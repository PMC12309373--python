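"""PPI graph construction and Markov clustering.

The graph is induced on the deregulated genes: an edge survives only if
both endpoints are deregulated and its confidence score reaches the
configured minimum. Deregulated genes without a surviving edge are not
graph members and later form the lonely set.

Markov clustering (MCL) alternates expansion (squaring the column-
stochastic flow matrix) and inflation (elementwise power followed by
re-normalization) until the flow stabilizes; rows with surviving diagonal
mass are attractors, and each attractor's support is a cluster. Inflation
controls granularity: higher values yield more, smaller clusters. Flow
never crosses connected components, so the algorithm is run per component.
"""
from __future__ import annotations

import logging

import networkx as nx
import numpy as np

from .errors import ConvergenceError
from .model import Cluster, Clustering, GeneLists, PipelineConfig

log = logging.getLogger(__name__)

__all__ = ["build_graph", "mcl_cluster", "partition_and_filter"]


def build_graph(lists: GeneLists, edges, cfg: PipelineConfig) -> nx.Graph:
    """Confidence-thresholded undirected graph over deregulated genes."""
    g = nx.Graph(confidence_min=cfg.confidence_min)
    dereg = lists.deregulated
    for a, b, score in edges:
        if score >= cfg.confidence_min and a in dereg and b in dereg:
            g.add_edge(a, b, weight=score)
    return g


def _mcl_component(nodes, adj, cfg: PipelineConfig):
    """MCL on one connected component; returns a partition of its nodes.

    ``adj`` is the dense symmetric weight matrix of the component in the
    order of ``nodes``. Self-loop weight is the maximum incident edge
    weight, which keeps the stochastic flow well-conditioned.
    """
    n = len(nodes)
    M = adj.astype(float).copy()
    for i in range(n):
        mx = M[i].max()
        M[i, i] = mx if mx > 0 else 1.0
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    residual = np.inf
    for _ in range(cfg.mcl_max_iter):
        M2 = np.linalg.matrix_power(M, cfg.mcl_expansion)
        np.power(M2, cfg.inflation, out=M2)
        M2[M2 < cfg.mcl_prune] = 0.0
        col = M2.sum(axis=0, keepdims=True)
        col[col == 0.0] = 1.0
        M2 /= col
        residual = np.abs(M2 - M).max()
        M = M2
        if residual < cfg.mcl_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"MCL did not converge in {cfg.mcl_max_iter} iterations "
            f"(residual {residual:.3e}, component size {n})"
        )

    tol = cfg.mcl_tol
    attractors = [i for i in range(n) if M[i, i] > tol]
    systems = []
    for i in attractors:
        members = frozenset(j for j in range(n) if M[i, j] > tol)
        if members not in systems:
            systems.append(members)
    if not systems:  # numerically degenerate; fall back to one cluster
        systems = [frozenset(range(n))]

    # resolve nodes claimed by several attractor systems: larger cluster
    # wins, ties broken by lexicographically smallest member tuple
    def rank(s):
        return (-len(s), tuple(sorted(nodes[j] for j in s)))

    assignment = {}
    for s in sorted(systems, key=rank):
        for j in s:
            assignment.setdefault(j, s)
    # nodes attracted by nothing above tolerance: strongest attractor wins
    for j in range(n):
        if j not in assignment:
            best = max(attractors, key=lambda i: (M[i, j], -i), default=None)
            assignment[j] = assignment.get(best, frozenset([j]))

    clusters = {}
    for j, s in assignment.items():
        clusters.setdefault(s, set()).add(j)
    return [frozenset(nodes[j] for j in members) for members in clusters.values()]


def mcl_cluster(graph: nx.Graph, cfg: PipelineConfig) -> list:
    """Deterministic MCL partition of the graph nodes.

    Returns a list of frozensets covering every node exactly once, sorted
    by decreasing size then smallest member, so identical inputs yield an
    identical partition.
    """
    partition = []
    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)):
        nodes = sorted(comp)
        adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
        partition.extend(_mcl_component(nodes, adj, cfg))
    partition.sort(key=lambda c: (-len(c), min(c)))
    return partition


def partition_and_filter(
    lists: GeneLists, partition, cfg: PipelineConfig
) -> Clustering:
    """Apply the lower cluster size filter and collect the lonely set.

    Cells with at least ``min_cluster_size`` genes become clusters c1, c2,
    ... (decreasing size, ties by smallest member gene id); every other
    partition member, plus deregulated genes absent from the graph, is
    lonely.
    """
    in_graph = set()
    for cell in partition:
        in_graph |= cell
    retained = [c for c in partition if len(c) >= cfg.min_cluster_size]
    retained.sort(key=lambda c: (-len(c), min(c)))
    clusters = [
        Cluster(cluster_id=f"c{i}", genes=cell, provenance="mcl")
        for i, cell in enumerate(retained, start=1)
    ]
    dropped = [c for c in partition if len(c) < cfg.min_cluster_size]
    lonely = set(lists.deregulated) - in_graph
    for cell in dropped:
        lonely |= cell
    log.info(
        "partition: %d cells, %d retained (size >= %d), %d lonely genes",
        len(partition), len(clusters), cfg.min_cluster_size, len(lonely),
    )
    return Clustering(clusters=clusters, lonely=frozenset(lonely))
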
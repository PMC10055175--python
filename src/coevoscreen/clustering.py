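"""Significant-association graph and Markov clustering (MCL).

Significant gene pairs from the coevolution screen form an undirected
weighted graph (weight = -log10 of the Bonferroni-adjusted P, capped, or
1.0 in binary mode).  The graph is clustered with the Markov Cluster
algorithm: simulate flow on the graph by alternating expansion (matrix
self-multiplication) and inflation (entrywise powers followed by column
normalization); flow concentrates inside natural clusters and evaporates
between them, and the converged matrix's attractor rows read out a
partition of the nodes.

The MCL iteration is implemented here from scratch on a dense matrix —
association graphs at screen output scale are small — with the standard
regularizations: self-loops (weight = the node's maximum incident edge
weight) before normalization, and pruning of tiny entries after each
inflation to keep the matrix sparse in effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .coevolution import PairAssociation

__all__ = [
    "AssociationGraph",
    "ClusterSet",
    "build_association_graph",
    "mcl",
    "parse_clusters_for_seeds",
    "WEIGHT_CAP",
]

#: cap on -log10(p_adj) edge weights, so p_adj == 0 (float underflow)
#: still yields a finite weight
WEIGHT_CAP = 300.0

AssociationGraph = nx.Graph


@dataclass
class ClusterSet:
    """Disjoint gene clusters produced by MCL.

    ``clusters`` partition the clustered node set; each cluster is a
    sorted tuple of gene identifiers.  ``converged`` is False when the
    iteration hit ``max_iter`` before the flow matrix stabilized (the
    partition is still returned).  ``max_colsum_error`` records the worst
    deviation of any column sum from 1 observed after any normalization
    step, as a numerical diagnostic.
    """

    clusters: list[tuple[str, ...]]
    converged: bool = True
    iterations: int = 0
    max_colsum_error: float = 0.0
    singleton_policy: str = "dropped"

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def as_mapping(self) -> dict[str, int]:
        """gene -> cluster index (clusters numbered in list order)."""
        return {g: i for i, cl in enumerate(self.clusters) for g in cl}


def build_association_graph(
    associations: list[PairAssociation],
    alpha: float = 0.001,
    mode: str = "weighted",
    keep_isolated: bool = False,
) -> nx.Graph:
    """Build the graph of significant pairwise associations.

    An edge joins every pair with adjusted P < alpha; its weight is
    min(300, -log10(p_adj)) in ``weighted`` mode or exactly 1.0 in
    ``binary`` mode.  Genes with no significant partner are dropped by
    default; ``keep_isolated`` retains them as isolated nodes.
    """
    if mode not in ("weighted", "binary"):
        raise ValueError(f"mode must be 'weighted' or 'binary', got {mode!r}")
    graph = nx.Graph()
    if keep_isolated:
        for assoc in associations:
            graph.add_node(assoc.gene_a)
            graph.add_node(assoc.gene_b)
    for assoc in associations:
        if assoc.p_adj < alpha:
            if mode == "binary":
                weight = 1.0
            elif assoc.p_adj <= 0.0:
                weight = WEIGHT_CAP
            else:
                weight = min(WEIGHT_CAP, -np.log10(assoc.p_adj))
            graph.add_edge(assoc.gene_a, assoc.gene_b, weight=weight)
    return graph


def _normalize_columns(mat: np.ndarray) -> float:
    """Column-normalize in place; return worst |colsum - 1| afterwards."""
    sums = mat.sum(axis=0)
    sums[sums == 0.0] = 1.0  # a dead column stays dead
    mat /= sums
    return float(np.abs(mat.sum(axis=0) - 1.0).max())


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
    add_self_loops: bool = True,
) -> ClusterSet:
    """Markov clustering of an association graph.

    Iterates expansion (``M ** expansion`` matrix power), inflation
    (entrywise power ``inflation`` then column normalization) and pruning
    of entries below ``prune_threshold`` (followed by renormalization)
    until the largest entrywise change falls below ``tol`` or ``max_iter``
    is reached; non-convergence is flagged, not raised.

    Clusters are read from attractor rows of the converged matrix;
    overlapping attractor systems are merged, and a node attracted to
    several clusters goes to the largest one (ties: the cluster with the
    lexicographically smallest member).  The result is always a partition
    of the graph's nodes, and never joins disconnected components.
    """
    if inflation <= 1.0:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n == 0:
        return ClusterSet(clusters=[])
    if n == 1:
        return ClusterSet(clusters=[(nodes[0],)])

    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight", dtype=float)
    if add_self_loops:
        loop = adj.max(axis=0)
        loop[loop == 0.0] = 1.0  # isolated node: unit self-loop
        np.fill_diagonal(adj, loop)
    else:
        np.fill_diagonal(adj, np.maximum(np.diag(adj), 1e-12))

    mat = adj.copy()
    worst_colsum = _normalize_columns(mat)

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        prev = mat.copy()
        mat = np.linalg.matrix_power(mat, expansion)
        np.power(mat, inflation, out=mat)
        worst_colsum = max(worst_colsum, _normalize_columns(mat))
        # prune tiny entries, keeping each column's maximum so no column dies
        keep = mat >= prune_threshold
        keep[mat.argmax(axis=0), np.arange(n)] = True
        mat[~keep] = 0.0
        worst_colsum = max(worst_colsum, _normalize_columns(mat))
        if np.abs(mat - prev).max() < tol:
            converged = True
            break

    clusters = _read_clusters(mat, nodes, eps=prune_threshold)
    return ClusterSet(
        clusters=clusters,
        converged=converged,
        iterations=iterations,
        max_colsum_error=worst_colsum,
    )


def _read_clusters(mat: np.ndarray, nodes: list[str], eps: float) -> list[tuple[str, ...]]:
    n = len(nodes)
    attractors = [i for i in range(n) if mat[i, i] > eps]
    if not attractors:
        # pathological non-converged state: fall back to argmax assignment
        attractors = list(np.unique(mat.argmax(axis=0)))

    # merge attractors whose row supports overlap (attractor systems)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    supports = {i: set(np.nonzero(mat[i] > eps)[0]) | {i} for i in attractors}
    for i in attractors:
        for j in attractors:
            if j > i and supports[i] & supports[j]:
                union(i, j)

    systems: dict[int, set[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), set()).update(supports[i])

    raw_clusters = [sorted(members) for members in systems.values()]

    # a node claimed by several systems goes to the largest cluster,
    # ties broken by lexicographically smallest member
    claims: dict[int, list[int]] = {}
    for ci, members in enumerate(raw_clusters):
        for node in members:
            claims.setdefault(node, []).append(ci)
    assignment: dict[int, int] = {}
    for node, cis in claims.items():
        assignment[node] = min(
            cis, key=lambda ci: (-len(raw_clusters[ci]), nodes[raw_clusters[ci][0]])
        )
    # numerically orphaned nodes: strongest incoming attractor row
    for node in range(n):
        if node not in assignment:
            best = int(mat[:, node].argmax())
            assignment[node] = assignment.get(best, len(raw_clusters))
            if assignment[node] == len(raw_clusters):
                raw_clusters.append([node])

    final: dict[int, list[str]] = {}
    for node, ci in assignment.items():
        final.setdefault(ci, []).append(nodes[node])
    clusters = [tuple(sorted(members)) for members in final.values()]
    clusters.sort(key=lambda cl: (-len(cl), cl))
    return clusters


@dataclass
class SeedReport:
    """One cluster's seed content (screen readout)."""

    cluster: tuple[str, ...]
    seeds: tuple[str, ...]
    candidates: tuple[str, ...] = field(default_factory=tuple)


def parse_clusters_for_seeds(clusters: ClusterSet, seeds: set[str]) -> list[SeedReport]:
    """Scan clusters for seed genes and surface the non-seed co-members.

    Clusters are reported sorted by descending seed count (ties by cluster
    members); non-seed members of seed-containing clusters are the
    candidate novel components — the discovery pattern of the screen.
    """
    reports = []
    for cl in clusters.clusters:
        in_seeds = tuple(sorted(g for g in cl if g in seeds))
        non_seeds = tuple(sorted(g for g in cl if g not in seeds)) if in_seeds else ()
        reports.append(SeedReport(cluster=cl, seeds=in_seeds, candidates=non_seeds))
    reports.sort(key=lambda r: (-len(r.seeds), r.cluster))
    return reports
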
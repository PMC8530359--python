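"""Two-step spacer clustering: locus distance clusters, then Markov clustering.

Validated protospacer loci are first chained per contig into locus
clusters (single linkage, inter-locus gap <= 50 kb).  A weighted
undirected co-occurrence graph over spacers is built from these: the
weight of an edge is the number of locus clusters in which both spacers
have at least one locus.  Graph communities are found with a
deterministic dense Markov clustering (MCL) at inflation 4 and
pre-inflation 0.4, and clusters are kept when they contain at least 10
spacers and their induced unweighted subgraph has a global clustering
coefficient (3 x triangles / connected triples) of at least 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .protospacer import ProtospacerLocus
from .seqcore import Interval


@dataclass
class LocusCluster:
    cluster_id: str
    loci: list[ProtospacerLocus]

    @property
    def span(self) -> Interval:
        c = self.loci[0].interval.contig_id
        return Interval(c, min(l.interval.start for l in self.loci),
                        max(l.interval.end for l in self.loci))

    @property
    def spacer_ids(self) -> set[str]:
        return {l.spacer_id for l in self.loci}


@dataclass
class SpacerCluster:
    cluster_id: str
    spacer_ids: set[str]
    gcc: float
    mean_adjacent_locus_distance: float
    locus_clusters: list[LocusCluster] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.spacer_ids)


def cluster_loci(loci: list[ProtospacerLocus], max_gap: int = 50_000,
                 ) -> list[LocusCluster]:
    """Single-linkage chaining of loci per contig (gap measured end-to-start)."""
    by_contig: dict[str, list[ProtospacerLocus]] = {}
    for l in loci:
        by_contig.setdefault(l.interval.contig_id, []).append(l)
    clusters: list[LocusCluster] = []
    for contig_id in sorted(by_contig):
        group = sorted(by_contig[contig_id],
                       key=lambda l: (l.interval.start, l.interval.end, l.spacer_id))
        chain = [group[0]]
        chain_end = group[0].interval.end
        for l in group[1:]:
            if l.interval.start - chain_end <= max_gap:
                chain.append(l)
                chain_end = max(chain_end, l.interval.end)
            else:
                clusters.append(LocusCluster(f"LC{len(clusters) + 1:05d}", chain))
                chain = [l]
                chain_end = l.interval.end
        clusters.append(LocusCluster(f"LC{len(clusters) + 1:05d}", chain))
    return clusters


def build_graph(locus_clusters: list[LocusCluster]) -> nx.Graph:
    """Weighted spacer co-occurrence graph (no self-edges)."""
    g = nx.Graph()
    for lc in locus_clusters:
        members = sorted(lc.spacer_ids)
        g.add_nodes_from(members)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                if g.has_edge(u, v):
                    g[u][v]["weight"] += 1
                else:
                    g.add_edge(u, v, weight=1)
    return g


def markov_cluster(graph: nx.Graph, inflation: float = 4.0,
                   pre_inflation: float = 0.4, expansion: int = 2,
                   prune: float = 1e-5, tol: float = 1e-6,
                   max_iter: int = 100) -> list[set[str]]:
    """Deterministic dense MCL on a weighted undirected graph.

    Edge weights are first raised to ``pre_inflation`` entrywise;
    self-loops are added with weight equal to the node's maximum incident
    (pre-inflated) weight; columns are normalized; then expansion (matrix
    power) and inflation (entrywise power + renormalization) alternate,
    pruning entries below ``prune``, until the largest entry change falls
    below ``tol``.  Clusters are read from attractor rows; a node
    reachable from several attractors joins the one with the largest
    flow value (ties broken by lowest cluster index).  Node order never
    affects memberships: nodes are processed in sorted order.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    index = {u: i for i, u in enumerate(nodes)}
    mat = np.zeros((n, n))
    for u, v, w in graph.edges(data="weight", default=1):
        val = float(w) ** pre_inflation
        mat[index[u], index[v]] = val
        mat[index[v], index[u]] = val
    loop = mat.max(axis=0)
    loop[loop == 0] = 1.0  # isolated nodes keep themselves
    np.fill_diagonal(mat, loop)
    mat /= mat.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        new = np.linalg.matrix_power(mat, expansion)
        np.power(new, inflation, out=new)
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        new[new < prune] = 0.0  # prune after normalization
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        if np.abs(new - mat).max() < tol:
            mat = new
            converged = True
            break
        mat = new
    if not converged:
        warnings.warn("MCL did not converge within max_iter; "
                      "returning current partition", RuntimeWarning)

    # attractors: nodes with positive diagonal flow
    attractors = np.nonzero(np.diag(mat) > 0)[0]
    # group attractors that flow into each other (rows overlap)
    cluster_rows: list[np.ndarray] = []
    assigned_attr: dict[int, int] = {}
    for a in attractors:
        row = mat[a] > 0
        placed = False
        for ci, crow in enumerate(cluster_rows):
            if (row & crow).any():
                cluster_rows[ci] = crow | row
                assigned_attr[a] = ci
                placed = True
                break
        if not placed:
            assigned_attr[a] = len(cluster_rows)
            cluster_rows.append(row)

    if not cluster_rows:
        return [{u} for u in nodes]
    clusters: list[set[str]] = [set() for _ in cluster_rows]
    flow = np.zeros((len(cluster_rows), n))
    for a, ci in assigned_attr.items():
        flow[ci] = np.maximum(flow[ci], mat[a])
    for j in range(n):
        col = flow[:, j]
        if col.max() > 0:
            clusters[int(np.argmax(col))].add(nodes[j])
        else:
            clusters.append({nodes[j]})  # unattracted node: singleton
    return [c for c in clusters if c]


def global_clustering_coefficient(graph: nx.Graph) -> float:
    """3 x triangles / connected triples on the unweighted graph."""
    return nx.transitivity(graph)


def filter_clusters(partition: list[set[str]], graph: nx.Graph,
                    locus_clusters: list[LocusCluster],
                    min_size: int = 10, min_gcc: float = 0.5,
                    ) -> list[SpacerCluster]:
    """Keep clusters with >= min_size spacers and gcc >= min_gcc.

    The mean adjacent-locus distance of a kept cluster is the mean, over
    locus clusters restricted to its members, of start-to-start distances
    between adjacent member loci.
    """
    kept: list[SpacerCluster] = []
    for members in sorted(partition, key=lambda c: (-len(c), sorted(c))):
        if len(members) < min_size:
            continue
        gcc = global_clustering_coefficient(graph.subgraph(members))
        if gcc < min_gcc:
            continue
        dists: list[int] = []
        member_lcs: list[LocusCluster] = []
        for lc in locus_clusters:
            mloci = sorted((l for l in lc.loci if l.spacer_id in members),
                           key=lambda l: l.interval.start)
            if not mloci:
                continue
            member_lcs.append(LocusCluster(lc.cluster_id, mloci))
            dists.extend(mloci[i + 1].interval.start - mloci[i].interval.start
                         for i in range(len(mloci) - 1))
        mean_dist = float(np.mean(dists)) if dists else 0.0
        kept.append(SpacerCluster(f"SC{len(kept) + 1:04d}", set(members),
                                  gcc, mean_dist, member_lcs))
    return kept
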
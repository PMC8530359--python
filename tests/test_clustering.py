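"""Locus clustering, the co-occurrence graph, MCL and cluster filtering."""

import itertools

import networkx as nx
import numpy as np
import pytest

from crisprmge.clustering import (LocusCluster, build_graph, cluster_loci,
                                  filter_clusters,
                                  global_clustering_coefficient,
                                  markov_cluster)
from crisprmge.protospacer import ProtospacerLocus
from crisprmge.seqcore import Interval


def locus(contig: str, start: int, spacer: str, length: int = 30,
          ) -> ProtospacerLocus:
    return ProtospacerLocus(spacer, Interval(contig, start, start + length),
                            1.0, validated=True)


def brute_force_partition(loci, max_gap):
    """Transitive closure of the '<= max_gap apart on one contig' relation."""
    g = nx.Graph()
    g.add_nodes_from(range(len(loci)))
    for i, j in itertools.combinations(range(len(loci)), 2):
        a, b = loci[i].interval, loci[j].interval
        if a.contig_id != b.contig_id:
            continue
        gap = max(a.start, b.start) - min(a.end, b.end)
        if gap <= max_gap:
            g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestClusterLoci:
    def test_55kb_gap_splits(self):
        loci = [locus("c", 0, "s1"), locus("c", 40_000, "s2"),
                locus("c", 95_000, "s3")]
        clusters = cluster_loci(loci)
        assert [{l.spacer_id for l in c.loci} for c in clusters] \
            == [{"s1", "s2"}, {"s3"}]

    def test_contigs_never_co_clustered(self):
        loci = [locus("c1", 0, "s1"), locus("c2", 10, "s2")]
        assert len(cluster_loci(loci)) == 2

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(10):
            loci = [locus(f"c{int(rng.integers(2))}",
                          int(rng.integers(0, 200_000)), f"s{i}")
                    for i in range(30)]
            got = {frozenset(loci.index(l) for l in c.loci)
                   for c in cluster_loci(loci, max_gap=20_000)}
            assert got == brute_force_partition(loci, 20_000)


class TestBuildGraph:
    def test_cooccurrence_weights(self):
        lcs = [LocusCluster(f"LC{i}", [locus("c", 0, "a"), locus("c", 100, "b")])
               for i in range(3)]
        g = build_graph(lcs)
        assert g["a"]["b"]["weight"] == 3

    def test_no_edge_without_shared_cluster(self):
        lcs = [LocusCluster("LC1", [locus("c1", 0, "a")]),
               LocusCluster("LC2", [locus("c2", 0, "b")])]
        g = build_graph(lcs)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"a", "b"}

    def test_per_phage_spacers_form_cliques(self, small_community,
                                            small_result):
        """Spacers planted in one phage end up in one dense component."""
        validated = small_result.validated_loci
        lcs = cluster_loci(validated)
        g = build_graph(lcs)
        comps = list(nx.connected_components(g))
        # one component per targeted phage contig
        phage_contigs = {l.interval.contig_id for l in validated
                         if l.interval.contig_id.endswith("_contig")}
        assert len(comps) >= len(phage_contigs)
        for comp in comps:
            sub = g.subgraph(comp)
            assert global_clustering_coefficient(sub) > 0.9


class TestMarkovCluster:
    def test_disconnected_triangles_never_merge(self):
        g = nx.Graph()
        for base in ("a", "b"):
            nodes = [f"{base}{i}" for i in range(3)]
            g.add_weighted_edges_from(
                (u, v, 1) for u, v in itertools.combinations(nodes, 2))
        part = markov_cluster(g)
        assert sorted(sorted(c) for c in part) \
            == [["a0", "a1", "a2"], ["b0", "b1", "b2"]]

    def test_single_clique_one_cluster(self):
        g = nx.complete_graph(10)
        nx.set_edge_attributes(g, 1, "weight")
        part = markov_cluster(nx.relabel_nodes(g, str))
        assert len(part) == 1 and len(part[0]) == 10

    def test_two_community_toy_graph(self):
        """Two dense 10-node communities joined by one weak edge separate."""
        g = nx.Graph()
        left = [f"L{i}" for i in range(10)]
        right = [f"R{i}" for i in range(10)]
        for group in (left, right):
            g.add_weighted_edges_from(
                (u, v, 3) for u, v in itertools.combinations(group, 2))
        g.add_edge("L0", "R0", weight=1)
        part = markov_cluster(g)
        assert sorted(sorted(c) for c in part) == [sorted(left), sorted(right)]

    def test_partition_property(self, rng):
        g = nx.gnp_random_graph(25, 0.2, seed=11)
        nx.set_edge_attributes(g, 1, "weight")
        part = markov_cluster(nx.relabel_nodes(g, str))
        nodes = sorted(n for c in part for n in c)
        assert nodes == sorted(str(n) for n in g.nodes)  # each node exactly once

    def test_determinism_under_relabeling(self, rng):
        g = nx.gnp_random_graph(20, 0.25, seed=5)
        nx.set_edge_attributes(g, 1, "weight")
        g1 = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        perm = list(g.nodes)
        rng.shuffle(perm)
        g2 = nx.Graph()
        for u, v, d in g1.edges(data=True):  # insertion order scrambled
            g2.add_edge(u, v, weight=d["weight"])
        p1 = {frozenset(c) for c in markov_cluster(g1)}
        p2 = {frozenset(c) for c in markov_cluster(g2)}
        assert p1 == p2


class TestFilterClusters:
    def test_path_discarded_clique_kept(self):
        path = nx.path_graph(10)
        clique = nx.complete_graph(range(100, 110))
        g = nx.union(nx.relabel_nodes(path, str),
                     nx.relabel_nodes(clique, str))
        nx.set_edge_attributes(g, 1, "weight")
        part = [set(map(str, range(10))), set(map(str, range(100, 110)))]
        kept = filter_clusters(part, g, [])
        assert len(kept) == 1
        assert kept[0].spacer_ids == set(map(str, range(100, 110)))
        assert kept[0].gcc == 1.0

    def test_small_cluster_discarded(self):
        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, str)
        nx.set_edge_attributes(g, 1, "weight")
        assert filter_clusters([set(g.nodes)], g, []) == []

    def test_gcc_matches_brute_force_enumeration(self, rng):
        """Transitivity equals direct triangle/triple counting, n <= 12."""
        for seed in range(8):
            g = nx.gnp_random_graph(int(rng.integers(4, 13)), 0.4, seed=seed)
            triangles = sum(1 for trio in itertools.combinations(g.nodes, 3)
                            if g.has_edge(trio[0], trio[1])
                            and g.has_edge(trio[1], trio[2])
                            and g.has_edge(trio[0], trio[2]))
            triples = sum(d * (d - 1) // 2 for _, d in g.degree)
            expected = 3 * triangles / triples if triples else 0.0
            assert global_clustering_coefficient(g) == pytest.approx(expected)

    def test_rand_index_against_planted_truth(self, small_community,
                                              small_result):
        """Spacers of one phage co-cluster with Rand index >= 0.95."""
        com = small_community
        truth_label = {}
        for t in com.truth.spacers:
            truth_label[t.canonical_seq] = t.phage_id
        seq_by_id = {s.spacer_id: s.seq for s in small_result.spacers}
        pred_label = {}
        for sc in small_result.spacer_clusters:
            for sid in sc.spacer_ids:
                pred_label[sid] = sc.cluster_id
        common = [sid for sid in pred_label
                  if seq_by_id[sid] in truth_label]
        agree = total = 0
        for a, b in itertools.combinations(common, 2):
            same_truth = truth_label[seq_by_id[a]] == truth_label[seq_by_id[b]]
            same_pred = pred_label[a] == pred_label[b]
            agree += (same_truth == same_pred)
            total += 1
        assert total > 0 and agree / total >= 0.95
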
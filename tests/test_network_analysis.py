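"""Network construction, subnetworks, topology and community oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from fflnet import (MergedFFL, ValidationError, ablate_nodes, build_network,
                    composite_subnetwork, degree_summary, enumerate_3node,
                    enumerate_4node, feedback_loops, find_hubs,
                    k_clique_communities, merge_ffls, seeded_subnetwork)
from fflnet.network_analysis import RegulatoryNetwork
from conftest import random_store


def merged_from(store):
    return (merge_ffls(enumerate_3node(store))
            + merge_ffls(enumerate_4node(store)))


M1 = MergedFFL("t1", "m1", "TF-FFL", ("g1",), "3-node")
M2 = MergedFFL("t2", "m2", "composite-FFL", ("g1", "g2"), "3-node")


class TestBuildNetwork:
    def test_minimal_expansion(self):
        net = build_network([M1])
        assert net.n_nodes == 3 and net.n_edges == 3

    def test_idempotent_union(self):
        once = build_network([M1])
        twice = build_network([M1, M1])
        assert set(once.edge_keys()) == set(twice.edge_keys())
        assert once.node_classes == twice.node_classes

    def test_provenance_regenerates_edges(self):
        net = build_network([M1, M2])
        for src, tgt, rel in net.edge_keys():
            prov = net.provenance(src, tgt, rel)
            assert prov
            regen = build_network(
                [m for m in (M1, M2) if (m.tf, m.mirna, m.arity) in prov])
            assert (src, tgt, rel) in set(regen.edge_keys())


class TestSubnetworks:
    @pytest.mark.parametrize("seed", range(5))
    def test_composite_subset_of_full(self, seed):
        merged = merged_from(random_store(seed, n_tf=5, n_mirna=5, n_gene=5, density=0.35))
        comp = composite_subnetwork(merged)
        full = build_network(merged) if merged else None
        if merged:
            assert set(comp.edge_keys()) <= set(full.edge_keys())
        for src, tgt, rel in comp.edge_keys():
            for tf, mi, arity in comp.provenance(src, tgt, rel):
                m = next(x for x in merged if (x.tf, x.mirna, x.arity)
                         == (tf, mi, arity))
                assert m.ffl_class == "composite-FFL"

    def test_no_composites_gives_empty(self):
        assert composite_subnetwork([M1]).n_nodes == 0

    def test_seed_absent_gives_empty(self):
        assert seeded_subnetwork([M1, M2], {"nonexistent"}).n_nodes == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_all_seeds_equals_full(self, seed):
        merged = merged_from(random_store(seed, n_tf=5, n_mirna=5, n_gene=5, density=0.35))
        if not merged:
            pytest.skip("no FFLs at this seed")
        full = build_network(merged)
        sub = seeded_subnetwork(merged, set(full.node_classes))
        assert set(sub.edge_keys()) == set(full.edge_keys())

    def test_target_seed_pulls_whole_ffl(self):
        sub = seeded_subnetwork([M1, M2], {"g2"})
        assert set(sub.node_classes) == {"t2", "m2", "g1", "g2"}


class TestDegrees:
    def test_triangle_degrees(self):
        summary = degree_summary(build_network([M1]))
        for cls in ("gene", "miRNA", "TF"):
            assert summary["per_class"][cls]["mean"] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_handshake_lemma(self, seed):
        merged = merged_from(random_store(seed, n_tf=5, n_mirna=5, n_gene=5, density=0.35))
        if not merged:
            pytest.skip("no FFLs at this seed")
        net = build_network(merged)
        g = net.to_undirected_simple()
        total = sum(s["n"] * s["mean"]
                    for s in degree_summary(net)["per_class"].values())
        assert total == pytest.approx(2 * g.number_of_edges())

    def test_empty_network(self):
        assert degree_summary(RegulatoryNetwork())["per_class"] == {}


class TestHubs:
    @staticmethod
    def star_network(n_leaves=4):
        """One TF connected to several genes: clear degree-10-style top."""
        net = RegulatoryNetwork()
        net.add_node("hub", "TF")
        for i in range(n_leaves):
            net.add_node(f"g{i}", "gene")
            net.add_edge("hub", f"g{i}", "TF-gene")
        return net

    def test_clear_top_element(self):
        net = RegulatoryNetwork()
        # one class of 5 genes with degrees 4,1,1,1,1 via a star
        net.add_node("c", "gene")
        for i in range(4):
            net.add_node(f"g{i}", "gene")
            net.add_edge("c", f"g{i}", "gene-gene")
        reports = find_hubs(net, 0.2)
        (rep,) = reports
        assert rep.hubs == ("c",)

    def test_uniform_degrees_no_hubs(self):
        # 5-cycle of genes: all degrees 2, median guard trips
        net = RegulatoryNetwork()
        for i in range(5):
            net.add_node(f"g{i}", "gene")
        for i in range(5):
            net.add_edge(f"g{i}", f"g{(i + 1) % 5}", "gene-gene")
        (rep,) = find_hubs(net, 0.2)
        assert rep.hubs == ()

    def test_small_class_skipped(self):
        assert find_hubs(self.star_network(3)) == []  # both classes < 5

    def test_empty_network(self):
        assert find_hubs(RegulatoryNetwork()) == []

    def test_scale_consistent_under_disjoint_copy(self):
        net = RegulatoryNetwork()
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(12)]
        for g in genes:
            net.add_node(g, "gene")
        for a, b in itertools.combinations(genes, 2):
            if rng.random() < 0.4:
                net.add_edge(a, b, "gene-gene")
        doubled = RegulatoryNetwork()
        for copy in ("A", "B"):
            for g in genes:
                doubled.add_node(f"{copy}{g}", "gene")
        for a, b, r in net.edge_keys():
            for copy in ("A", "B"):
                doubled.add_edge(f"{copy}{a}", f"{copy}{b}", r)
        c1 = {r.node_class: r.cutoff for r in find_hubs(net, 0.2)}
        c2 = {r.node_class: r.cutoff for r in find_hubs(doubled, 0.2)}
        assert c1 == c2


class TestFeedbackLoops:
    def test_reciprocal_pair_found(self):
        net = build_network([M2])
        assert feedback_loops(net) == [("t2", "m2")]

    def test_one_direction_only(self):
        assert feedback_loops(build_network([M1])) == []

    def test_dedup_across_arities(self):
        m4 = MergedFFL("t2", "m2", "composite-FFL", (("g3", "g4"),), "4-node")
        assert feedback_loops(build_network([M2, m4])) == [("t2", "m2")]


def oracle_clique_percolation(g, k):
    """Brute force: all k-cliques, adjacency = sharing k-1 nodes, then
    connected components of the clique graph."""
    cliques = [frozenset(c) for c in itertools.combinations(g.nodes, k)
               if all(g.has_edge(a, b)
                      for a, b in itertools.combinations(c, 2))]
    cg = nx.Graph()
    cg.add_nodes_from(range(len(cliques)))
    for i, j in itertools.combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) == k - 1:
            cg.add_edge(i, j)
    return {frozenset().union(*(cliques[i] for i in comp))
            for comp in nx.connected_components(cg)}


class TestCommunities:
    def test_shared_edge_percolates(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("b", "d"), ("c", "d")])
        comms = k_clique_communities(g, 3)
        assert [set(c.members) for c in comms] == [{"a", "b", "c", "d"}]

    def test_disjoint_triangles_stay_apart(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
        assert len(k_clique_communities(g, 3)) == 2

    @pytest.mark.parametrize("seed,k", [(s, k) for s in range(10)
                                        for k in (3, 4)])
    def test_matches_brute_force_oracle(self, seed, k):
        g = nx.gnp_random_graph(15, 0.35, seed=seed)
        got = {c.members for c in k_clique_communities(g, k)}
        assert got == oracle_clique_percolation(g, k)

    @pytest.mark.parametrize("seed", range(5))
    def test_k2_equals_connected_components(self, seed):
        g = nx.gnp_random_graph(12, 0.15, seed=seed)
        got = {c.members for c in k_clique_communities(g, 2)}
        expected = {frozenset(c) for c in nx.connected_components(g)
                    if len(c) > 1}
        assert got == expected

    def test_k_below_two_rejected(self):
        with pytest.raises(ValidationError):
            k_clique_communities(nx.Graph(), 1)


class TestAblation:
    def test_remove_nothing_identity(self):
        net = build_network([M1, M2])
        out, report = ablate_nodes(net, set())
        assert set(out.edge_keys()) == set(net.edge_keys())
        assert report["components_before"] == report["components_after"]

    def test_cut_vertex_splits_path(self):
        net = RegulatoryNetwork()
        for n in ("a", "b", "c"):
            net.add_node(n, "gene")
        net.add_edge("a", "b", "gene-gene")
        net.add_edge("b", "c", "gene-gene")
        out, report = ablate_nodes(net, {"b"})
        assert report["components_after"] == 2
        assert set(out.node_classes) == {"a", "c"}

    @pytest.mark.parametrize("seed", range(5))
    def test_component_counts_match_bfs_oracle(self, seed):
        merged = merged_from(random_store(seed, n_tf=5, n_mirna=5, n_gene=5, density=0.35))
        if not merged:
            pytest.skip("no FFLs at this seed")
        net = build_network(merged)
        rng = np.random.default_rng(seed)
        removed = {n for n in net.node_classes if rng.random() < 0.3}
        out, report = ablate_nodes(net, removed)
        g = net.to_undirected_simple()
        g.remove_nodes_from(removed)
        assert report["components_after"] == \
            nx.number_connected_components(g)
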
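"""Pathway merging, hubs, chains, neighborhoods and permutation tests."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from hormonet.network import (
    InteractionNetwork,
    PathwayCollection,
    extract_chains,
    find_hubs,
    hub_percentage,
    merge_pathways,
    neighborhood,
    permutation_enrichment,
)
from tests.conftest import toy_network


class TestMergePathways:
    def test_shared_edge_collapses(self):
        coll = PathwayCollection.from_dict(
            {"p1": ["a", "b", "c"], "p2": ["a", "b", "d"]},
            {"p1": [("a", "b")], "p2": [("a", "b")]},
        )
        net = merge_pathways(coll, de_genes={"a"})
        assert net.n_edges == 1
        assert net.n_pathways_included == 2

    def test_pathway_without_de_member_contributes_nothing(self):
        coll = PathwayCollection.from_dict(
            {"hit": ["a", "b"], "miss": ["x", "y"]},
            {"hit": [("a", "b")], "miss": [("x", "y")]},
        )
        net = merge_pathways(coll, de_genes={"a"})
        assert set(net.graph.nodes) == {"A", "B"}
        assert net.n_pathways_included == 1

    def test_three_disjoint_cliques(self):
        members, edges = {}, {}
        for k in range(3):
            genes = [f"p{k}_{i}" for i in range(4)]
            members[f"pw{k}"] = genes
            edges[f"pw{k}"] = list(itertools.combinations(genes, 2))
        coll = PathwayCollection.from_dict(members, edges)
        net = merge_pathways(coll, de_genes={"p0_0", "p1_0", "p2_0"})
        assert net.n_nodes == 12
        assert net.n_edges == 18  # 3 * C(4,2)

    def test_self_loops_dropped_and_annotations_set(self):
        coll = PathwayCollection.from_dict(
            {"p": ["a", "b", "c"]}, {"p": [("a", "a"), ("a", "b")]}
        )
        net = merge_pathways(coll, de_genes={"a", "b"}, crosstalk_genes={"b"})
        assert net.n_edges == 1
        assert net.annotation("A") == "other_DE"
        assert net.annotation("B") == "crosstalk_DE"
        assert net.annotation("C") == "non_DE"

    def test_merge_idempotence(self):
        coll = PathwayCollection.from_dict(
            {"p1": ["a", "b", "c"], "p2": ["b", "c", "d"]},
            {"p1": [("a", "b"), ("b", "c")], "p2": [("b", "c"), ("c", "d")]},
        )
        net = merge_pathways(coll, de_genes={"a", "d"})
        again = PathwayCollection.from_dict(
            {"all": sorted(net.graph.nodes)},
            {"all": [tuple(e) for e in net.graph.edges]},
        )
        net2 = merge_pathways(again, de_genes={"a", "d"})
        assert set(net.graph.nodes) == set(net2.graph.nodes)
        assert set(map(frozenset, net.graph.edges)) == set(
            map(frozenset, net2.graph.edges)
        )


class TestHubs:
    def test_star_with_20_leaves_center_is_hub(self):
        edges = [("hub", f"leaf{i}") for i in range(20)]
        net = toy_network(edges, crosstalk=["hub"])
        assert find_hubs(net) == {"HUB"}

    def test_star_with_19_leaves_has_no_hub(self):
        edges = [("hub", f"leaf{i}") for i in range(19)]
        net = toy_network(edges, crosstalk=["hub"])
        assert find_hubs(net) == set()

    def test_published_hub_percentage(self):
        # 402 hubs among 3750 network nodes -> 10.72%
        assert hub_percentage(402, 3750) == pytest.approx(10.72, abs=0.005)

    def test_degree_recount_oracle_on_random_graphs(self):
        for seed in range(5):
            g = nx.gnp_random_graph(40, 0.3, seed=seed)
            g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
            net = toy_network(list(g.edges), crosstalk=list(g.nodes)[:5])
            for thr in (2, 5, 10):
                hubs = find_hubs(net, hub_threshold=thr)
                brute = {
                    n for n in net.graph.nodes
                    if sum(1 for e in net.graph.edges if n in e) >= thr
                }
                assert hubs == brute


class TestChains:
    def test_isolated_crosstalk_node_dropped(self):
        net = toy_network(
            [("a", "b"), ("b", "c"), ("d", "e")],
            crosstalk=["a", "b", "c", "d"],
        )
        chains = extract_chains(net, "crosstalk_only")
        assert chains.chains == [["A", "B", "C"]]

    def test_sorted_by_size_descending(self):
        edges = [(f"x{i}", f"x{i+1}") for i in range(11)]  # 12-node path
        edges += [("y0", "y1"), ("y1", "y2"), ("y2", "y3")]  # 4-node path
        xt = [f"x{i}" for i in range(12)] + [f"y{i}" for i in range(4)]
        net = toy_network(edges, crosstalk=xt)
        chains = extract_chains(net, "crosstalk_only")
        assert chains.sizes == [12, 4]

    def test_bridge_gene_modes(self):
        # a-b-c where the bridge b is DE but not crosstalk-regulated
        edges = [("a", "b"), ("b", "c")]
        net = toy_network(edges, crosstalk=["a", "c"], other_de=["b"])
        assert extract_chains(net, "all_de").chains == [["A", "B", "C"]]
        assert extract_chains(net, "crosstalk_only").chains == []

    def test_unknown_mode_rejected(self):
        net = toy_network([("a", "b")], crosstalk=["a", "b"])
        with pytest.raises(ValueError):
            extract_chains(net, "everything")


class TestNeighborhood:
    def test_path_rings(self):
        net = toy_network([("s", "a"), ("a", "b")], crosstalk=["s"])
        nb = neighborhood(net, ["s"])
        assert nb.first_neighbors == {"A"}
        assert nb.second_neighbors == {"B"}

    def test_triangle_has_no_second_ring(self):
        net = toy_network([("s", "a"), ("s", "b"), ("a", "b")], crosstalk=["s"])
        nb = neighborhood(net, ["s"])
        assert nb.first_neighbors == {"A", "B"}
        assert nb.second_neighbors == set()

    def test_shared_neighbor_flagged_common(self):
        net = toy_network(
            [("s1", "x"), ("s2", "x"), ("s1", "y")], crosstalk=["s1", "s2"]
        )
        nb = neighborhood(net, ["s1", "s2"])
        assert "X" in nb.first_neighbors
        assert nb.common_first == {"X"}

    def test_unknown_seed_raises_with_names(self):
        net = toy_network([("a", "b")], crosstalk=["a"])
        with pytest.raises(KeyError, match="NOPE"):
            neighborhood(net, ["a", "nope"])

    def test_rings_match_shortest_path_oracle(self):
        for seed in range(5):
            g = nx.gnp_random_graph(50, 0.08, seed=100 + seed)
            g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
            net = toy_network(list(g.edges), crosstalk=list(sorted(g.nodes))[:3])
            seeds = sorted(net.graph.nodes)[:2]
            nb = neighborhood(net, seeds)
            dist = {}
            for n in net.graph.nodes:
                best = min(
                    (
                        nx.shortest_path_length(net.graph, s, n)
                        for s in seeds
                        if nx.has_path(net.graph, s, n)
                    ),
                    default=None,
                )
                dist[n] = best
            assert nb.first_neighbors == {n for n, d in dist.items() if d == 1}
            assert nb.second_neighbors == {n for n, d in dist.items() if d == 2}


class TestPermutationEnrichment:
    @staticmethod
    def _enumeration_oracle(net, seeds, label):
        """Exhaustive null over all label placements (independent oracle)."""
        nb = neighborhood(net, seeds)
        ring = nb.first_neighbors | nb.second_neighbors
        labeled = net.nodes_with(label)
        non_seed = sorted(set(net.graph.nodes) - nb.seeds)
        k = len(labeled - nb.seeds)
        stats_ = [
            len(set(combo) & ring)
            for combo in itertools.combinations(non_seed, k)
        ]
        observed = len(ring & labeled)
        arr = np.array(stats_, dtype=float)
        return observed, arr.mean(), arr.std(), np.mean(arr >= observed)

    def test_exhaustive_matches_enumeration_exactly(self):
        # 6-node graph, 2 labeled nodes: C(5,2)=10 assignments
        net = toy_network(
            [("s", "a"), ("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")],
            crosstalk=["a", "b"],
        )
        res = permutation_enrichment(net, ["s"], exhaustive=True)
        obs, mean, sd, p = self._enumeration_oracle(net, ["S"], "crosstalk_DE")
        assert res.exhaustive
        assert res.observed == obs
        assert res.null_mean == pytest.approx(mean)
        assert res.null_sd == pytest.approx(sd)
        assert res.empirical_p == pytest.approx(p)
        assert res.z_score == pytest.approx((obs - mean) / sd)

    def test_exhaustive_on_several_random_graphs(self):
        for seed in range(4):
            g = nx.gnp_random_graph(9, 0.35, seed=seed)
            g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
            labeled = sorted(g.nodes)[:3]
            net = toy_network(list(g.edges), crosstalk=labeled)
            seeds = [sorted(net.graph.nodes)[-1]]
            res = permutation_enrichment(net, seeds, exhaustive=True)
            obs, mean, sd, p = self._enumeration_oracle(
                net, seeds, "crosstalk_DE"
            )
            assert (res.observed, res.empirical_p) == (obs, pytest.approx(p))
            assert res.null_mean == pytest.approx(mean)
            assert res.null_sd == pytest.approx(sd)

    def test_sampled_null_matches_hypergeometric_moments(self):
        g = nx.gnp_random_graph(60, 0.1, seed=7)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        labeled = sorted(g.nodes)[:12]
        net = toy_network(list(g.edges), crosstalk=labeled)
        seeds = [sorted(net.graph.nodes)[-1]]
        n_perm = 10_000
        res = permutation_enrichment(
            net, seeds, n_permutations=n_perm, seed=1, exhaustive=False
        )
        nb = neighborhood(net, seeds)
        ring = (nb.first_neighbors | nb.second_neighbors) - nb.seeds
        N = net.n_nodes - 1
        K = len(set(labeled) - nb.seeds)
        n_ring = len(ring)
        hg = stats.hypergeom(N, K, n_ring)
        se_mean = hg.std() / np.sqrt(n_perm)
        assert abs(res.null_mean - hg.mean()) < 3 * se_mean
        se_sd = hg.std() / np.sqrt(2 * n_perm)
        assert abs(res.null_sd - hg.std()) < 3 * se_sd

    def test_fixed_seed_reproducible(self):
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        net = toy_network(list(g.edges), crosstalk=sorted(g.nodes)[:6])
        seeds = [sorted(net.graph.nodes)[0]]
        r1 = permutation_enrichment(net, seeds, n_permutations=500, seed=5,
                                    exhaustive=False)
        r2 = permutation_enrichment(net, seeds, n_permutations=500, seed=5,
                                    exhaustive=False)
        assert (r1.null_mean, r1.null_sd, r1.empirical_p) == (
            r2.null_mean, r2.null_sd, r2.empirical_p)

    def test_all_nodes_labeled_is_degenerate(self):
        net = toy_network([("s", "a"), ("a", "b")],
                          crosstalk=["s", "a", "b"])
        res = permutation_enrichment(net, ["s"], exhaustive=True)
        assert res.null_sd == 0.0
        assert res.degenerate
        assert math.isnan(res.z_score)

    def test_no_labeled_nodes_flagged(self):
        net = toy_network([("s", "a"), ("a", "b")], other_de=["s"])
        res = permutation_enrichment(net, ["s"], label="crosstalk_DE")
        assert res.degenerate
        assert math.isnan(res.z_score)

    def test_degree_rewire_null_runs(self):
        g = nx.gnp_random_graph(20, 0.3, seed=11)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        net = toy_network(list(g.edges), crosstalk=sorted(g.nodes)[:4])
        res = permutation_enrichment(
            net, [sorted(net.graph.nodes)[0]], n_permutations=100, seed=2,
            null_model="degree_rewire",
        )
        assert res.n_permutations == 100
        assert 0 < res.empirical_p <= 1
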
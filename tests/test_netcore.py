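"""Graph container, I/O, structural descriptors and centralities."""

import math

import networkx as nx
import numpy as np
import pytest

from netcompare import (Network, assortativity, centrality, degree_histogram,
                        edge_density, fit_power_law, giant_component,
                        network_stats, read_network, write_network)
from netcompare.netcore import ParseError

from conftest import random_network


class TestNetworkModel:
    def test_self_loops_dropped_and_duplicates_collapse(self):
        net = Network([("a", "a"), ("a", "b"), ("b", "a"), ("a", "b")])
        assert net.edges == {("a", "b")}
        assert net.n_selfloops_dropped == 1

    def test_edge_is_unordered(self):
        assert Network([("a", "b")]).edges == Network([("b", "a")]).edges

    def test_endpoints_become_nodes(self):
        net = Network([("a", "b")], nodes=["z"])
        assert net.nodes == {"a", "b", "z"}


class TestIO:
    def test_read_edgelist(self, tmp_path):
        p = tmp_path / "net.edgelist"
        p.write_text("a b\nb c\n# comment\n")
        net = read_network(p)
        assert net.nodes == {"a", "b", "c"}
        assert net.edges == {("a", "b"), ("b", "c")}

    def test_read_drops_self_loop_with_warning(self, tmp_path):
        p = tmp_path / "net.edgelist"
        p.write_text("a a\na b\n")
        net = read_network(p)
        assert net.edges == {("a", "b")}
        assert net.n_selfloops_dropped == 1

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "net.edgelist"
        p.write_text("a b\nc\n")
        with pytest.raises(ParseError, match=":2"):
            read_network(p)

    def test_read_sif(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("a interacts b c\nd interacts e\nf\n")
        net = read_network(p, format="sif")
        assert net.edges == {("a", "b"), ("a", "c"), ("d", "e")}
        assert "f" in net.nodes

    def test_round_trip(self, tmp_path):
        net = random_network(20, 0.2, seed=3)
        path = tmp_path / "rt.edgelist"
        write_network(net, path)
        back = read_network(path)
        assert back.edges == net.edges
        assert back.nodes >= {g for e in net.edges for g in e}


class TestEdgeDensity:
    # printed (N, E, density) rows of published yeast / E. coli network
    # summary tables; densities reproduce to the printed precision
    @pytest.mark.parametrize("n,e,expected", [
        (9163, 27493, 6.5497e-04),
        (6169, 112562, 5.9165e-03),
        (4441, 12873, 1.3057e-03),
        (7258, 21820, 8.2853e-04),
        (3619, 20198, 3.0852e-03),
        (1681, 3717, 2.6324e-03),
    ])
    def test_published_summary_densities(self, n, e, expected):
        assert edge_density(n, e) == pytest.approx(expected, rel=5e-5)

    def test_complete_graph(self):
        k4 = Network([("a", "b"), ("a", "c"), ("a", "d"),
                      ("b", "c"), ("b", "d"), ("c", "d")])
        assert edge_density(k4) == 1.0

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            edge_density(1, 0)

    def test_matches_brute_force_on_random_graphs(self):
        for s in range(20):
            net = random_network(15, 0.3, seed=s)
            brute = net.n_edges / math.comb(net.n_nodes, 2)
            assert edge_density(net) == pytest.approx(brute, abs=1e-12)


class TestGiantComponent:
    def test_larger_component_wins(self):
        net = Network([("a", "b"), ("b", "c"), ("d", "e")])
        assert giant_component(net).nodes == {"a", "b", "c"}

    def test_connected_graph_identity(self, triangle):
        assert giant_component(triangle) == triangle

    def test_tie_broken_lexicographically(self):
        net = Network([("c", "d"), ("a", "b")])
        assert giant_component(net).nodes == {"a", "b"}

    def test_empty_network(self):
        assert giant_component(Network()).n_nodes == 0


class TestAssortativity:
    def test_star_is_minus_one(self, star4):
        assert assortativity(star4) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self, cycle4):
        assert math.isnan(assortativity(cycle4))

    def test_disjoint_edges_undefined(self):
        assert math.isnan(assortativity(Network([("a", "b"), ("c", "d")])))

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            assortativity(Network(nodes=["a", "b"]))

    def test_agrees_with_networkx_oracle(self):
        checked = 0
        for s in range(100):
            net = random_network(12, 0.25, seed=100 + s)
            if net.n_edges < 2:
                continue
            ours = assortativity(net)
            theirs = nx.degree_assortativity_coefficient(net.graph)
            if math.isnan(ours) or math.isnan(theirs):
                assert math.isnan(ours) == math.isnan(theirs)
            else:
                assert ours == pytest.approx(theirs, abs=1e-10)
                checked += 1
        assert checked > 50


class TestDegreeHistogram:
    @pytest.mark.parametrize("edges,expected", [
        ([("h", "x"), ("h", "y"), ("h", "z")], {1: 0.75, 3: 0.25}),
        ([("a", "b"), ("b", "c"), ("a", "c")], {2: 1.0}),
        ([("a", "b"), ("b", "c")], {1: 2 / 3, 2: 1 / 3}),
    ])
    def test_counts(self, edges, expected):
        hist = degree_histogram(Network(edges))
        assert hist == pytest.approx(expected)

    def test_degree_zero_nodes_excluded(self):
        net = Network([("a", "b")], nodes=["isolated"])
        assert degree_histogram(net) == {1: 1.0}

    def test_frequencies_sum_to_one(self):
        hist = degree_histogram(random_network(30, 0.15, seed=7))
        assert sum(hist.values()) == pytest.approx(1.0)


class TestPowerLawFit:
    def test_collinear_points_fit_exactly(self):
        # p_k proportional to k^-2: slope -2 exactly in log-log
        fit = fit_power_law({1: 16 / 21, 2: 4 / 21, 4: 1 / 21})
        assert fit.alpha == pytest.approx(2.0, abs=1e-12)

    def test_flat_histogram(self):
        assert fit_power_law({1: 0.5, 2: 0.5}).alpha == pytest.approx(0.0, abs=1e-12)

    def test_scaling_absorbed_by_intercept(self):
        h = {1: 16 / 21, 2: 4 / 21, 4: 1 / 21}
        scaled = {k: 3.7 * v for k, v in h.items()}
        assert fit_power_law(scaled).alpha == pytest.approx(fit_power_law(h).alpha)

    def test_single_degree_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law({2: 1.0})

    @pytest.mark.parametrize("alpha", [2.0, 3.0])
    def test_recovers_exponent_from_sampled_law(self, alpha):
        # degrees sampled i.i.d. from an exact discrete power law
        ks = np.arange(1, 1001)
        pk = ks ** -alpha
        pk /= pk.sum()
        estimates = []
        for s in range(10):
            rng = np.random.default_rng(s)
            degs = rng.choice(ks, size=10_000, p=pk)
            vals, counts = np.unique(degs, return_counts=True)
            hist = dict(zip(vals.tolist(), (counts / counts.sum()).tolist()))
            estimates.append(fit_power_law(hist).alpha)
        assert np.median(estimates) == pytest.approx(alpha, abs=0.3)


class TestCentrality:
    def test_degree(self, star4):
        assert centrality(star4, "degree") == {"h": 3.0, "x": 1.0, "y": 1.0, "z": 1.0}

    def test_closeness_path(self, path3):
        c = centrality(path3, "closeness")
        assert c["b"] == pytest.approx(1 / 2)
        assert c["a"] == pytest.approx(1 / 3)

    def test_closeness_unreachable_counts_n(self):
        net = Network([("a", "b")], nodes=["c"])
        # a: d(b)=1, d(c)=N=3 -> 1/4
        assert centrality(net, "closeness")["a"] == pytest.approx(1 / 4)

    def test_transitivity(self, triangle, star4):
        assert centrality(triangle, "transitivity")["a"] == pytest.approx(1.0)
        c = centrality(star4, "transitivity")
        assert c["h"] == pytest.approx(0.0)
        assert math.isnan(c["x"])

    def test_hubscore_star(self, star4):
        c = centrality(star4, "hubscore")
        assert c["h"] == pytest.approx(1.0)
        for leaf in "xyz":
            assert c[leaf] == pytest.approx(1 / math.sqrt(3))

    def test_betweenness_path(self, path3):
        c = centrality(path3, "betweenness")
        assert c["b"] == pytest.approx(1.0)
        assert c["a"] == pytest.approx(0.0)

    def test_unknown_measure_rejected(self, path3):
        with pytest.raises(ValueError):
            centrality(path3, "pagerank")

    def test_hubscore_matches_power_iteration(self):
        # connected, non-bipartite (forced triangle) so A.A^T top eigenvalue
        # is simple and power iteration has a unique limit
        for s in range(5):
            net = random_network(15, 0.25, seed=200 + s)
            net.graph.add_edges_from([("g0", "g1"), ("g1", "g2"), ("g0", "g2")])
            net = giant_component(net)
            nodes = sorted(net.nodes)
            a = nx.to_numpy_array(net.graph, nodelist=nodes)
            m = a @ a.T
            v = np.ones(len(nodes))
            for _ in range(10_000):
                v = m @ v
                v /= np.linalg.norm(v)
            v = np.abs(v) / np.abs(v).max()
            ours = centrality(net, "hubscore")
            assert np.max(np.abs(v - [ours[n] for n in nodes])) < 1e-8

    def test_closeness_invariant_under_relabeling(self):
        net = random_network(12, 0.3, seed=5)
        mapping = {f"g{i}": f"x{(i * 7) % 12}" for i in range(12)}
        relabeled = Network([(mapping[a], mapping[b]) for a, b in net.edges],
                            nodes=mapping.values())
        c1 = centrality(net, "closeness")
        c2 = centrality(relabeled, "closeness")
        for g in net.nodes:
            assert c2[mapping[g]] == pytest.approx(c1[g])

    def test_leaf_betweenness_zero(self):
        for s in range(5):
            net = random_network(15, 0.2, seed=300 + s)
            bet = centrality(net, "betweenness")
            for g in net.nodes:
                if net.degree(g) == 1:
                    assert bet[g] == 0.0


def test_network_stats_composition(star4):
    s = network_stats(star4)
    assert (s.n_nodes, s.n_edges, s.gcc_size) == (4, 3, 4)
    assert s.edge_density == pytest.approx(0.5)
    assert s.assortativity == pytest.approx(-1.0)
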
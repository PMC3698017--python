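"""Annotation model, GEA/GPEA hypergeometric tests, p-value adjustment."""

import math

import numpy as np
import pytest

from netcompare import (AnnotationSet, Network, adjust, gea, gen_annotations,
                        gen_network, gpea_global, gpea_interface,
                        read_annotations, write_annotations)

from conftest import random_network


def hypergeom_tail_oracle(k, N, m, n):
    return sum(math.comb(m, i) * math.comb(N - m, n - i)
               for i in range(k, min(m, n) + 1)) / math.comb(N, n)


class TestAnnotationSet:
    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            AnnotationSet({"T": set()})

    def test_restrict_drops_empty_terms(self, toy_annotation):
        r = toy_annotation.restrict({"a", "b"})
        assert set(r.terms) == {"T1", "T2"}
        assert r.genes_of("T1") == {"a", "b"}

    def test_terms_of_gene(self, toy_annotation):
        assert toy_annotation.terms_of("a") == {"T1", "T2"}

    def test_tsv_round_trip(self, toy_annotation, tmp_path):
        path = tmp_path / "ann.tsv"
        write_annotations(toy_annotation, path)
        back = read_annotations(path)
        assert back.term_to_genes == toy_annotation.term_to_genes

    def test_gaf_not_rows_dropped(self, tmp_path):
        path = tmp_path / "ann.gaf"
        path.write_text("!gaf-version: 2.2\n"
                        "DB\tg1\tG1\t\tGO:1\tREF\tIEA\t\tP\n"
                        "DB\tg2\tG2\tNOT\tGO:1\tREF\tIEA\t\tP\n"
                        "DB\tg3\tG3\tinvolved_in\tGO:2\tREF\tIEA\t\tP\n")
        ann = read_annotations(path, format="gaf")
        assert ann.term_to_genes == {"GO:1": {"g1"}, "GO:2": {"g3"}}


class TestGEA:
    def test_hand_computed_instance(self):
        # universe 10, term 4, interest 5, k = 4:
        # p = C(4,4) C(6,1) / C(10,5) = 6/252
        universe = [f"g{i}" for i in range(10)]
        ann = AnnotationSet({"T": set(universe[:4])})
        res = gea(universe[:4] + [universe[9]], universe, ann,
                  min_size=1, max_size=10, annotated_only=False)
        assert res[0].k == 4
        assert res[0].p_raw == pytest.approx(6 / 252)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        ann = AnnotationSet({"T": set(universe[:4])})
        res = gea(universe[8:], universe, ann, min_size=1, max_size=10,
                  annotated_only=False)
        assert res[0].p_raw == 1.0

    def test_saturated_draw_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        ann = AnnotationSet({"T1": set(universe[:3]), "T2": set(universe[2:6])})
        res = gea(universe, universe, ann, min_size=1, max_size=10,
                  annotated_only=False)
        assert all(r.p_raw == pytest.approx(1.0) for r in res)

    def test_empty_universe_rejected(self, toy_annotation):
        with pytest.raises(ValueError):
            gea({"a"}, set(), toy_annotation)

    def test_interest_outside_universe_rejected(self, toy_annotation):
        with pytest.raises(ValueError):
            gea({"zzz"}, {"a", "b"}, toy_annotation)

    def test_term_size_filter(self):
        universe = [f"g{i}" for i in range(12)]
        ann = AnnotationSet({"small": {"g0"}, "mid": set(universe[:5]),
                             "big": set(universe)})
        res = gea(universe[:3], universe, ann, min_size=2, max_size=8,
                  annotated_only=False)
        assert [r.term for r in res] == ["mid"]

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            nu = int(rng.integers(8, 30))
            universe = [f"g{i}" for i in range(nu)]
            term = set(rng.choice(universe, size=int(rng.integers(2, nu // 2 + 2)),
                                  replace=False))
            interest = set(rng.choice(universe, size=int(rng.integers(1, nu // 2 + 1)),
                                      replace=False))
            ann = AnnotationSet({"T": term})
            res = gea(interest, universe, ann, min_size=1, max_size=nu,
                      annotated_only=False)
            r = res[0]
            assert r.p_raw == pytest.approx(
                hypergeom_tail_oracle(r.k, r.N, r.m, r.n), abs=1e-12)


class TestGPEAGlobal:
    def test_hand_computed_instance(self):
        # 5 genes -> N = 10 pairs, 4 edges, term of 3 genes (m = 3 pairs)
        # with k = 2 internal edges: p = 70/210 (same tail as the 5-gene
        # interface example; identical hypergeometric structure)
        genes = list("abcde")
        net = Network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")], nodes=genes)
        ann = AnnotationSet({"T": {"a", "b", "c"}})
        res = gpea_global(net, ann, min_size=1, max_size=10)
        r = res[0]
        assert (r.N, r.m, r.n, r.k) == (10, 3, 4, 2)
        assert r.p_raw == pytest.approx(70 / 210)

    def test_term_without_internal_edges_p_one(self):
        net = Network([("a", "b"), ("c", "d")], nodes=list("abcd"))
        ann = AnnotationSet({"T": {"a", "c"}})
        assert gpea_global(net, ann, min_size=1, max_size=10)[0].p_raw == 1.0

    def test_planted_clique_ranks_first(self):
        genes = [f"g{i}" for i in range(12)]
        clique = genes[:4]
        edges = [(a, b) for i, a in enumerate(clique) for b in clique[i + 1:]]
        net = Network(edges, nodes=genes)
        ann = AnnotationSet({"planted": set(clique),
                             "bg1": set(genes[4:8]), "bg2": set(genes[2:7])})
        res = gpea_global(net, ann, min_size=2, max_size=12)
        best = min(res, key=lambda r: r.p_raw)
        assert best.term == "planted"

    def test_matches_summation_oracle(self):
        for s in range(20):
            net = random_network(8, 0.35, seed=400 + s)  # N = 28 pairs
            rng = np.random.default_rng(s)
            genes = sorted(net.nodes)
            ann = AnnotationSet({"T": set(rng.choice(genes, size=4, replace=False))})
            res = gpea_global(net, ann, min_size=1, max_size=10)
            r = res[0]
            assert r.p_raw == pytest.approx(
                hypergeom_tail_oracle(r.k, r.N, r.m, r.n), abs=1e-12)

    def test_null_annotation_rejection_controlled(self):
        # label-randomized annotations: raw-alpha rejections stay near alpha
        net = gen_network(60, 110, seed=9)
        rng = np.random.default_rng(10)
        genes = sorted(net.nodes)
        n_tests = n_rej = 0
        for _ in range(100):
            ann = gen_annotations(genes, n_terms=10, size_range=(5, 15),
                                  planted_terms=0, seed=int(rng.integers(2 ** 31)))
            for r in gpea_global(net, ann, min_size=3, max_size=50):
                n_tests += 1
                n_rej += r.p_raw <= 0.05
        assert n_rej / n_tests <= 0.10


class TestGPEAInterface:
    def test_hand_computed_instance(self):
        # union 6 edges, intersection 3; term contributes m = 2 union edges,
        # both shared: p = C(2,2) C(4,1) / C(6,3) = 4/20
        genes = list("abcdefg")
        shared = [("a", "b"), ("a", "c"), ("d", "e")]
        only_a = [("d", "f"), ("e", "f")]
        only_b = [("f", "g")]
        a = Network(shared + only_a, nodes=genes)
        b = Network(shared + only_b, nodes=genes)
        ann = AnnotationSet({"T": {"a", "b", "c"}})
        res = gpea_interface(a, b, ann, min_size=1, max_size=10)
        r = res[0]
        assert (r.N, r.n, r.m, r.k) == (6, 3, 2, 2)
        assert r.p_raw == pytest.approx(4 / 20)

    def test_degenerate_identity_reduces_to_global(self, triangle):
        ann = AnnotationSet({"T": {"a", "b", "c"}})
        ri = gpea_interface(triangle, triangle, ann, min_size=1, max_size=10)[0]
        rg = gpea_global(triangle, ann, min_size=1, max_size=10)[0]
        assert ri.N == ri.n == rg.n  # N collapses to the edge count
        assert ri.p_raw == pytest.approx(rg.p_raw) == 1.0

    def test_term_absent_from_both_networks_p_one(self):
        a = Network([("a", "b")], nodes=list("abxy"))
        b = Network([("a", "b")], nodes=list("abxy"))
        ann = AnnotationSet({"T": {"x", "y"}})
        assert gpea_interface(a, b, ann, min_size=1, max_size=10)[0].p_raw == 1.0

    def test_no_shared_edges_all_p_one(self):
        a = Network([("a", "b")], nodes=list("abcd"))
        b = Network([("c", "d")], nodes=list("abcd"))
        ann = AnnotationSet({"T": {"a", "b", "c"}})
        res = gpea_interface(a, b, ann, min_size=1, max_size=10)
        assert all(r.p_raw == 1.0 for r in res)

    def test_matches_summation_oracle(self):
        for s in range(20):
            a = random_network(8, 0.4, seed=500 + s)
            b = random_network(8, 0.4, seed=600 + s)
            if not (a.edges & b.edges):
                continue
            rng = np.random.default_rng(s)
            genes = sorted(a.nodes)
            ann = AnnotationSet({"T": set(rng.choice(genes, size=5, replace=False))})
            res = gpea_interface(a, b, ann, min_size=1, max_size=10)
            r = res[0]
            assert r.p_raw == pytest.approx(
                hypergeom_tail_oracle(r.k, r.N, r.m, r.n), abs=1e-12)


class TestAdjust:
    def test_single_value_unchanged(self):
        assert adjust([0.01], "bonferroni") == [pytest.approx(0.01)]
        assert adjust([0.01], "bh") == [pytest.approx(0.01)]

    def test_bonferroni(self):
        assert adjust([0.03, 0.4], "bonferroni") == pytest.approx([0.06, 0.8])

    def test_bonferroni_caps_at_one(self):
        assert adjust([0.9, 0.9], "bonferroni") == pytest.approx([1.0, 1.0])

    def test_bh_step_up_by_hand(self):
        assert adjust([0.01, 0.02, 0.9], "bh") == pytest.approx([0.03, 0.03, 0.9])

    def test_input_order_preserved(self):
        p = [0.7, 0.01, 0.3]
        adj = adjust(p, "bh")
        assert adj[1] == min(adj)

    def test_bh_monotone_on_sorted_input(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.random(50))
        adj = adjust(p, "bh")
        assert all(adj[i] <= adj[i + 1] + 1e-15 for i in range(49))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.random(30)
        for method in ("bonferroni", "bh"):
            adj = adjust(p, method)
            assert all(a >= r - 1e-15 for a, r in zip(adj, p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust([1.2], "bh")
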
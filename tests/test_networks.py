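import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from omegascan.networks import (
    propagate_annotations,
    category_clustering,
    connectivity_summary,
    fisher_enrichment,
    load_edges,
    map_categories,
)
from omegascan.simulate import make_network_fixture

from .oracles import hypergeom_upper_tail


def edges_df(rows):
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


class TestLoadEdges:
    def test_reciprocal_duplicates_keep_max_score(self):
        net = load_edges(edges_df([("A", "B", 700), ("B", "A", 900)]), min_score=0)
        assert net.number_of_edges() == 1
        assert net["A"]["B"]["score"] == 900

    def test_min_score_filters_everything(self):
        net = load_edges(edges_df([("A", "B", 700), ("B", "C", 900)]), min_score=950)
        assert net.number_of_edges() == 0

    def test_self_loops_dropped_and_counted(self):
        net = load_edges(edges_df([("A", "A", 800), ("A", "B", 500)]), min_score=0)
        assert net.number_of_edges() == 1
        assert net.graph["n_self_loops_dropped"] == 1

    def test_score_out_of_range_raises(self):
        with pytest.raises(ValueError):
            load_edges(edges_df([("A", "B", 1200)]))

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            load_edges(pd.DataFrame({"a": [1], "b": [2]}))

    def test_random_rows_match_independent_dedup_pass(self, rng):
        names = [f"P{i}" for i in range(12)]
        rows = [
            (names[rng.integers(12)], names[rng.integers(12)], int(rng.integers(0, 1001)))
            for _ in range(500)
        ]
        net = load_edges(edges_df(rows), min_score=300)
        best: dict[frozenset, int] = {}
        for a, b, s in rows:
            if a == b:
                continue
            key = frozenset((a, b))
            best[key] = max(best.get(key, 0), s)
        expected = {k: v for k, v in best.items() if v >= 300}
        got = {frozenset(e): net.edges[e]["score"] for e in net.edges}
        assert got == expected

    def test_loading_is_order_independent(self, rng):
        rows = [("A", "B", 500), ("C", "D", 700), ("B", "A", 650), ("D", "C", 400)]
        n1 = load_edges(edges_df(rows), min_score=0)
        n2 = load_edges(edges_df(rows[::-1]), min_score=0)
        assert {frozenset(e) for e in n1.edges} == {frozenset(e) for e in n2.edges}
        assert n1["A"]["B"]["score"] == n2["A"]["B"]["score"]


class TestConnectivity:
    def test_single_edge_triple(self):
        net = load_edges(edges_df([("A", "B", 800)]), min_score=0)
        summary = connectivity_summary(net, {"A", "B", "C"})
        assert summary.n_connected == 2
        assert summary.hubs[0] == ("A", 1)  # lexicographic tie-break over B

    def test_no_edges_gives_zero(self):
        net = load_edges(edges_df([("X", "Y", 900)]), min_score=0)
        assert connectivity_summary(net, {"A", "B"}).n_connected == 0

    def test_counts_match_brute_force_on_planted_fixture(self, rng):
        edges, _, _ = make_network_fixture(40, 4, 0.6, 0.05, seed=13)
        net = load_edges(edges, min_score=0)
        focal = {f"P{i:04d}" for i in range(0, 40, 2)}
        summary = connectivity_summary(net, focal)
        expected = 0
        for a in focal:
            expected += any(
                frozenset((a, b)) in {frozenset(e) for e in net.edges}
                for b in focal if b != a
            )
        assert summary.n_connected == expected


class TestMapCategories:
    GROUPS = {"muscle": ["GO:1", "GO:2"], "nervous": ["GO:3"]}

    def test_multi_label_node(self):
        annot = {"N1": {"GO:1", "GO:3"}}
        labels = map_categories(["N1"], annot, self.GROUPS)
        assert labels["N1"] == {"muscle", "nervous"}

    def test_node_without_grouped_terms_gets_empty_set(self):
        labels = map_categories(["N1"], {"N1": {"GO:99"}}, self.GROUPS)
        assert labels["N1"] == set()

    def test_matches_set_union_oracle(self, rng):
        terms = [f"GO:{i}" for i in range(8)]
        groups = {f"g{j}": [terms[j], terms[j + 4]] for j in range(4)}
        nodes = [f"N{i}" for i in range(30)]
        annot = {
            n: {terms[i] for i in rng.choice(8, size=rng.integers(0, 4), replace=False)}
            for n in nodes
        }
        labels = map_categories(nodes, annot, groups)
        for n in nodes:
            expected = {
                g for g, gterms in groups.items()
                if annot[n] & set(gterms)
            }
            assert labels[n] == expected


class TestCategoryClustering:
    def test_all_nodes_carry_category_gives_p_one(self):
        net = load_edges(edges_df([("A", "B", 500), ("B", "C", 600)]), min_score=0)
        labeling = {n: {"cat"} for n in "ABC"}
        obs, p = category_clustering(net, labeling, "cat", n_permutations=100)
        assert obs == 1.0 and p == 1.0

    def test_absent_category_raises(self):
        net = load_edges(edges_df([("A", "B", 500)]), min_score=0)
        with pytest.raises(ValueError):
            category_clustering(net, {"A": set(), "B": set()}, "cat")

    def test_planted_cluster_is_detected(self):
        edges, annot, truth = make_network_fixture(32, 4, 0.9, 0.0, seed=17)
        net = load_edges(edges, min_score=0)
        groups = {f"cat{c}": terms for c, terms in truth["cluster_terms"].items()}
        labeling = map_categories(net.nodes(), annot, groups)
        obs, p = category_clustering(net, labeling, "cat0", n_permutations=199, seed=5)
        assert p <= 0.05

    def test_p_value_in_unit_interval(self, rng):
        edges, annot, truth = make_network_fixture(20, 2, 0.5, 0.2, seed=18)
        net = load_edges(edges, min_score=0)
        groups = {f"cat{c}": terms for c, terms in truth["cluster_terms"].items()}
        labeling = map_categories(net.nodes(), annot, groups)
        _, p = category_clustering(net, labeling, "cat1", n_permutations=199)
        assert 0 < p <= 1


class TestFisherEnrichment:
    def test_term_covering_universe_has_p_one(self):
        annot = {f"g{i}": {"GO:ALL"} for i in range(20)}
        res = fisher_enrichment({"g0", "g1"}, annot.keys(), annot)
        assert res[0].p_value == 1.0

    def test_worked_hypergeometric_example(self):
        # universe 100, term 10 members, selected 10, overlap 5
        annot = {}
        for i in range(100):
            annot[f"g{i}"] = {"GO:T"} if i < 10 else {"GO:OTHER"}
        selected = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        res = {r.term: r for r in fisher_enrichment(selected, annot.keys(), annot)}
        expected = hypergeom_upper_tail(5, 100, 10, 10)
        assert res["GO:T"].p_value == pytest.approx(expected, rel=1e-10)

    def test_matches_exact_tail_on_random_tables(self, rng):
        for _ in range(20):
            N = int(rng.integers(20, 120))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            got = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
            want = hypergeom_upper_tail(k, N, K, n)
            assert got == pytest.approx(want, rel=1e-9)

    def test_agrees_with_scipy_fisher_exact(self):
        annot = {}
        for i in range(60):
            annot[f"g{i}"] = {"GO:T"} if i < 12 else {"GO:X"}
        selected = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(20, 24)}
        res = {r.term: r for r in fisher_enrichment(selected, annot.keys(), annot)}
        r = res["GO:T"]
        table = [
            [r.n_selected_in_term, r.n_selected - r.n_selected_in_term],
            [r.n_term_in_universe - r.n_selected_in_term,
             (r.n_universe - r.n_term_in_universe) - (r.n_selected - r.n_selected_in_term)],
        ]
        _, p = scipy.stats.fisher_exact(table, alternative="greater")
        assert r.p_value == pytest.approx(p, rel=1e-9)

    def test_planted_cluster_term_attains_minimum_q(self):
        _, annot, truth = make_network_fixture(60, 4, 0.8, 0.02, seed=19)
        cluster = truth["cluster_of"]
        selected = {p for p, c in cluster.items() if c == 2}
        res = fisher_enrichment(selected, annot.keys(), annot)
        best = min(res, key=lambda r: (r.q_value, r.term))
        assert best.term in truth["cluster_terms"][2]

    def test_empty_selected_raises(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), {"g"}, {"g": {"GO:1"}})

    def test_true_path_propagation_closes_over_ancestors(self):
        # child -> parent -> root; annotating the child implies all three
        parents = {"GO:child": ["GO:parent"], "GO:parent": ["GO:root"]}
        annot = {"g0": {"GO:child"}, "g1": {"GO:parent"}}
        for i in range(2, 30):
            annot[f"g{i}"] = {"GO:root"}
        closed = propagate_annotations(annot, parents)
        assert closed["g0"] == {"GO:child", "GO:parent", "GO:root"}
        assert closed["g1"] == {"GO:parent", "GO:root"}
        res = {r.term: r for r in fisher_enrichment(
            {"g0"}, annot.keys(), annot, term_parents=parents)}
        assert res["GO:root"].n_term_in_universe == 30

    def test_selected_outside_universe_raises(self):
        with pytest.raises(ValueError):
            fisher_enrichment({"zz"}, {"g"}, {"g": {"GO:1"}})
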
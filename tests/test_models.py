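"""Structures and learning: CMI, spanning tree, CPTs, BIC, hill-climbing."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcbnet.cohort_io import FeatureSpec
from dcbnet.models import (
    BICScorer,
    DAGStructure,
    FittedClassifier,
    bic_score,
    build_nb_structure,
    conditional_mutual_information,
    fit_cpts,
    hill_climb,
    learn_tan_structure,
    maximum_weight_spanning_tree,
    tan_root,
)

from conftest import brute_force_cmi, random_discrete_frame


def _spec(cards, class_card=2):
    return FeatureSpec(
        features=tuple(
            (f"v{k}", tuple(str(i) for i in range(card)))
            for k, card in enumerate(cards)
        ),
        class_var="c",
        class_domain=tuple(str(i) for i in range(class_card)),
    )


class TestDAGStructure:
    def test_rejects_cycle_self_loop_duplicate(self):
        with pytest.raises(ValueError):
            DAGStructure(("a", "b"), (("a", "b"), ("b", "a")))
        with pytest.raises(ValueError):
            DAGStructure(("a",), (("a", "a"),))
        with pytest.raises(ValueError):
            DAGStructure(("a", "b"), (("a", "b"), ("a", "b")))

    def test_tan_constraint(self):
        spec = _spec([2, 2, 2])
        nb = build_nb_structure(spec)
        # NB over >=2 features lacks the augmenting tree, so it is not TAN
        assert not nb.is_tan("c")
        tan = DAGStructure(
            nb.nodes, nb.edges + (("v0", "v1"), ("v1", "v2")))
        assert tan.is_tan("c")
        # a feature with two non-class parents violates the constraint
        bad = DAGStructure(
            nb.nodes, nb.edges + (("v0", "v2"), ("v1", "v2")))
        assert not bad.is_tan("c")

    def test_nb_structure_edges(self):
        spec = _spec([2, 3, 2])
        nb = build_nb_structure(spec)
        assert len(nb.edges) == 3
        assert all(u == "c" for u, _ in nb.edges)


class TestCMI:
    def test_perfect_within_class_dependence_is_ln2(self):
        # class 0: x1 == x2; class 1: x1 != x2 -> I = ln 2 in both strata
        rows = [("0", "0", "0"), ("0", "0", "0"), ("1", "1", "0"), ("1", "1", "0"),
                ("0", "1", "1"), ("0", "1", "1"), ("1", "0", "1"), ("1", "0", "1")]
        df = pd.DataFrame(rows, columns=["x1", "x2", "c"])
        spec = FeatureSpec(features=(("x1", ("0", "1")), ("x2", ("0", "1"))),
                           class_var="c", class_domain=("0", "1"))
        val = conditional_mutual_information(df, "x1", "x2", "c", spec)
        assert val == pytest.approx(np.log(2), abs=1e-12)

    def test_constant_variable_gives_zero(self):
        df = pd.DataFrame({"x1": ["0", "1", "0"], "x2": ["0", "0", "0"],
                           "c": ["0", "1", "0"]})
        spec = FeatureSpec(features=(("x1", ("0", "1")), ("x2", ("0", "1"))),
                           class_var="c", class_domain=("0", "1"))
        assert conditional_mutual_information(df, "x1", "x2", "c", spec) == 0.0

    def test_symmetry_and_nonnegativity_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            cards = rng.integers(2, 5, size=3)
            df = random_discrete_frame(rng, int(rng.integers(5, 50)), cards)
            df = df.rename(columns={"v2": "c"})
            spec = _spec(cards[:2], class_card=int(cards[2]))
            a = conditional_mutual_information(df, "v0", "v1", "c", spec)
            b = conditional_mutual_information(df, "v1", "v0", "c", spec)
            assert a == pytest.approx(b, abs=1e-12)
            assert a >= -1e-12

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            cards = rng.integers(2, 5, size=3)
            df = random_discrete_frame(rng, int(rng.integers(8, 50)), cards)
            df = df.rename(columns={"v2": "c"})
            spec = _spec(cards[:2], class_card=int(cards[2]))
            fast = conditional_mutual_information(df, "v0", "v1", "c", spec)
            slow = brute_force_cmi(df, "v0", "v1", "c")
            assert fast == pytest.approx(slow, abs=1e-10)


def exhaustive_max_tree_weight(weights):
    """Oracle: maximum total weight over all labelled spanning trees."""
    names = list(weights.index)
    all_edges = list(itertools.combinations(names, 2))
    best = -np.inf
    for subset in itertools.combinations(all_edges, len(names) - 1):
        g = nx.Graph(subset)
        if g.number_of_nodes() == len(names) and nx.is_tree(g):
            w = sum(weights.loc[u, v] for u, v in subset)
            best = max(best, w)
    return best


class TestSpanningTree:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for k in (3, 4, 5):
            for _ in range(5):
                w = rng.random((k, k))
                w = (w + w.T) / 2
                names = [f"f{i}" for i in range(k)]
                weights = pd.DataFrame(w, index=names, columns=names)
                tree = maximum_weight_spanning_tree(weights)
                got = sum(weights.loc[u, v] for u, v in tree)
                assert got == pytest.approx(
                    exhaustive_max_tree_weight(weights), abs=1e-12)

    def test_deterministic_under_ties(self):
        names = ["a", "b", "c"]
        w = pd.DataFrame(1.0, index=names, columns=names)
        assert maximum_weight_spanning_tree(w) == \
            maximum_weight_spanning_tree(w) == [("a", "b"), ("a", "c")]


class TestLearnTAN:
    def test_two_features_unique_tree(self, truth):
        spec = _spec([2, 2])
        rng = np.random.default_rng(0)
        df = random_discrete_frame(rng, 50, [2, 2, 2]).rename(columns={"v2": "c"})
        s = learn_tan_structure(df, spec, seed=1)
        assert {tuple(sorted(e)) for e in s.edges if "c" not in e} == {("v0", "v1")}
        assert s.is_tan("c")

    def test_single_feature_warns_and_returns_nb(self):
        spec = _spec([2])
        df = pd.DataFrame({"v0": ["0", "1"] * 10, "c": ["0", "1"] * 10})
        with pytest.warns(UserWarning):
            s = learn_tan_structure(df, spec, seed=0)
        assert s.edges == (("c", "v0"),)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=15, deadline=None)
    def test_output_always_satisfies_tan_constraint(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        cards = [int(rng.integers(2, 4)) for _ in range(k)] + [2]
        df = random_discrete_frame(rng, int(rng.integers(10, 80)), cards)
        df = df.rename(columns={f"v{k}": "c"})
        spec = _spec(cards[:-1])
        s = learn_tan_structure(df, spec, seed=seed)
        assert s.is_tan("c")
        assert tan_root(s, "c") in spec.feature_names

    def test_root_orientation_outward(self, truth, cohort_5k):
        s = learn_tan_structure(cohort_5k.labelled(), seed=9)
        root = tan_root(s, "dcb")
        # root has no feature parent; every other feature has exactly one
        for f in s.nodes:
            if f in ("dcb", root):
                continue
            non_class = [p for p in s.parents(f) if p != "dcb"]
            assert len(non_class) == 1


class TestFitCPTs:
    def test_laplace_and_mle_counts(self):
        spec = _spec([2])
        df = pd.DataFrame({"c": ["0"] * 4 + ["1"] * 2,
                           "v0": ["0", "0", "0", "1", "0", "1"]})
        s = build_nb_structure(spec)
        mle = fit_cpts(s, df, pseudocount=0.0, spec=spec)
        np.testing.assert_allclose(
            mle.cpts.tables["v0"][0], [0.75, 0.25])
        lap = fit_cpts(s, df, pseudocount=1.0, spec=spec)
        np.testing.assert_allclose(
            lap.cpts.tables["v0"][0], [4 / 6, 2 / 6])

    def test_unobserved_config_uniform_with_smoothing(self):
        spec = _spec([2])
        df = pd.DataFrame({"c": ["0"] * 4, "v0": ["0", "0", "1", "1"]})
        s = build_nb_structure(spec)
        m = fit_cpts(s, df, pseudocount=1.0, spec=spec)
        # class state '1' never observed -> uniform row
        np.testing.assert_allclose(m.cpts.tables["v0"][1], [0.5, 0.5])

    def test_unobserved_config_errors_without_smoothing(self):
        spec = _spec([2])
        df = pd.DataFrame({"c": ["0"] * 4, "v0": ["0", "0", "1", "1"]})
        with pytest.raises(ValueError, match="pseudocount|smooth"):
            fit_cpts(build_nb_structure(spec), df, pseudocount=0.0, spec=spec)

    def test_rows_normalize(self, truth, cohort_290):
        s = learn_tan_structure(cohort_290.labelled(), seed=0)
        m = fit_cpts(s, cohort_290.labelled(), 1.0)
        for node, table in m.cpts.tables.items():
            np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-9)
            assert (table > 0).all()

    def test_json_round_trip(self, truth, cohort_290, tmp_path):
        s = learn_tan_structure(cohort_290.labelled(), seed=0)
        m = fit_cpts(s, cohort_290.labelled(), 1.0, meta={"model_kind": "tan"})
        path = tmp_path / "model.json"
        m.to_json(path)
        back = FittedClassifier.from_json(path)
        assert back.structure == m.structure
        for node in m.structure.nodes:
            np.testing.assert_allclose(back.cpts.tables[node],
                                       m.cpts.tables[node])
        assert back.meta["model_kind"] == "tan"


class TestBIC:
    def _dependent_df(self, n, seed=0):
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 2, n)
        v0 = np.where(rng.random(n) < 0.85, c, 1 - c)
        return pd.DataFrame({"c": c.astype(str), "v0": v0.astype(str)})

    def test_informative_edge_beats_empty_graph(self):
        df = self._dependent_df(2000)
        spec = _spec([2])
        empty = DAGStructure(("c", "v0"), ())
        edge = DAGStructure(("c", "v0"), (("c", "v0"),))
        assert bic_score(edge, df, spec) > bic_score(empty, df, spec)

    def test_decomposability(self):
        df = self._dependent_df(500, seed=1)
        spec = _spec([2])
        s = DAGStructure(("c", "v0"), (("c", "v0"),))
        scorer = BICScorer(df, spec)
        total = scorer.structure(s)
        assert total == pytest.approx(
            scorer.family("c", ()) + scorer.family("v0", ("c",)), abs=1e-12)

    def test_consistency_on_independent_data(self):
        # with independent variables, BIC should prefer the empty graph
        rng = np.random.default_rng(7)
        spec = _spec([2])
        empty = DAGStructure(("c", "v0"), ())
        edge = DAGStructure(("c", "v0"), (("c", "v0"),))
        prefers_empty = 0
        for _ in range(40):
            df = pd.DataFrame(
                {"c": rng.integers(0, 2, 800).astype(str),
                 "v0": rng.integers(0, 2, 800).astype(str)})
            prefers_empty += bic_score(empty, df, spec) >= bic_score(edge, df, spec)
        assert prefers_empty >= 38  # >= 95%


class TestHillClimb:
    def test_local_optimum_is_fixed_point(self, truth, cohort_5k):
        scorer = BICScorer(cohort_5k)
        nodes = tuple(scorer.nodes)
        g1 = hill_climb(cohort_5k, DAGStructure(nodes, ()), scorer=scorer)
        g2 = hill_climb(cohort_5k, g1, scorer=scorer)
        assert set(g1.edges) == set(g2.edges)

    def test_score_never_decreases(self, truth, cohort_290):
        scorer = BICScorer(cohort_290)
        nodes = tuple(scorer.nodes)
        rng = np.random.default_rng(2)
        feats = [n for n in nodes]
        start_edges = tuple(
            (feats[i], feats[j])
            for i, j in [(0, 3), (1, 4), (2, 5)]
        )
        start = DAGStructure(nodes, start_edges)
        out = hill_climb(cohort_290, start, scorer=scorer)
        assert scorer.structure(out) >= scorer.structure(start)

    def test_recovers_three_node_chain(self):
        rng = np.random.default_rng(8)
        n = 5000
        a = rng.integers(0, 2, n)
        b = np.where(rng.random(n) < 0.9, a, 1 - a)
        c = np.where(rng.random(n) < 0.9, b, 1 - b)
        df = pd.DataFrame({"c": a.astype(str), "v0": b.astype(str),
                           "v1": c.astype(str)})
        spec = _spec([2, 2])
        g = hill_climb(df, DAGStructure(("c", "v0", "v1"), ()), spec=spec)
        assert g.undirected_pairs() == {("c", "v0"), ("v0", "v1")}
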
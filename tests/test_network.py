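"""Graphical-model stage: BIC scores, forest/stepwise search, functional nodes."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tnlike.network import (
    BicGraph,
    FunctionalNode,
    compare_activity,
    decomposable_bic,
    edge_bic_gain,
    min_bic_forest,
    mirna_activity_correlation,
    node_activity,
    split_functional_nodes,
    stepw_add,
)
from tnlike.synth import generate_tree_gaussian


def brute_force_forest(matrix: pd.DataFrame):
    """Oracle: exhaustive search over all acyclic edge subsets.

    For a forest the decomposable BIC decomposes edgewise, so the optimal
    forest minimises the sum of edge gains n*ln(1-r^2)+ln(n) over acyclic
    subsets.  Feasible for p <= 5 (<= 2^10 subsets).
    """
    p, n = matrix.shape
    corr = np.corrcoef(matrix.to_numpy())
    pairs = list(itertools.combinations(range(p), 2))
    best_gain, best_set = 0.0, frozenset()
    for k in range(len(pairs) + 1):
        for subset in itertools.combinations(pairs, k):
            g = nx.Graph(subset)
            g.add_nodes_from(range(p))
            if not nx.is_forest(g):
                continue
            gain = sum(edge_bic_gain(corr[i, j], n) for i, j in subset)
            if gain < best_gain:
                best_gain, best_set = gain, frozenset(subset)
    ids = list(matrix.index)
    return best_gain, {frozenset((ids[i], ids[j])) for i, j in best_set}


class TestEdgeBicGain:
    def test_zero_correlation_positive(self):
        assert edge_bic_gain(0.0, 50) == pytest.approx(math.log(50))

    def test_arithmetic(self):
        # 100*ln(0.19) + ln(100) = -166.1 + 4.61 ~ -161.5... computed exactly
        expected = 100 * math.log(1 - 0.81) + math.log(100)
        assert edge_bic_gain(0.9, 100) == pytest.approx(expected)
        assert expected == pytest.approx(-161.5, abs=0.2)

    def test_symmetric_and_sign_blind(self):
        assert edge_bic_gain(0.7, 40) == edge_bic_gain(-0.7, 40)

    def test_perfect_correlation_sentinel(self):
        assert edge_bic_gain(1.0, 10) == -np.inf


class TestMinBicForest:
    def test_independent_features_empty(self, rng):
        x = pd.DataFrame(rng.standard_normal((2, 100)), index=["a", "b"])
        assert min_bic_forest(x).graph.number_of_edges() == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = 3 + seed % 3  # p in {3,4,5}
        # random covariance with occasional strong pairs
        a = rng.standard_normal((p, p))
        cov = a @ a.T + 0.5 * np.eye(p)
        x = rng.multivariate_normal(np.zeros(p), cov, size=50).T
        matrix = pd.DataFrame(x, index=[f"v{i}" for i in range(p)])
        got = min_bic_forest(matrix)
        oracle_gain, oracle_edges = brute_force_forest(matrix)
        got_edges = {frozenset(e) for e in got.graph.edges}
        assert got.total_gain() == pytest.approx(oracle_gain, abs=1e-9)
        assert got_edges == oracle_edges

    def test_recovers_true_tree(self):
        hits = 0
        for seed in range(10):
            df, true_edges = generate_tree_gaussian(8, 4000, 0.6, seed=seed)
            got = {frozenset(e) for e in min_bic_forest(df).graph.edges}
            hits += got == {frozenset(e) for e in true_edges}
        assert hits >= 9

    def test_total_bic_no_worse_than_empty(self, rng):
        x = pd.DataFrame(rng.standard_normal((6, 80)))
        assert min_bic_forest(x).total_gain() <= 0

    def test_single_feature_rejected(self, rng):
        with pytest.raises(ValueError):
            min_bic_forest(pd.DataFrame(rng.standard_normal((1, 10))))


class TestStepwAdd:
    def _triangle_data(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        x = pd.DataFrame(
            {
                "a": z + 0.5 * rng.standard_normal(n),
                "b": z + 0.5 * rng.standard_normal(n),
                "c": z + 0.5 * rng.standard_normal(n),
            }
        ).T
        return x

    def test_closes_triangle_and_matches_brute_force(self):
        x = self._triangle_data()
        n = x.shape[1]
        corr = pd.DataFrame(np.corrcoef(x.to_numpy()), index=x.index, columns=x.index)
        forest = min_bic_forest(x)
        assert forest.graph.number_of_edges() == 2
        stepped = stepw_add(forest, x)
        assert stepped.graph.number_of_edges() == 3

        # brute force: triangle BIC = n ln det R_abc + 3 ln n; forest BIC from
        # its two pairwise determinants + 2 ln n
        tri_bic = n * math.log(np.linalg.det(corr.to_numpy())) + 3 * math.log(n)
        f_edges = list(forest.graph.edges)
        f_bic = sum(
            n * math.log(1 - corr.loc[i, j] ** 2) for i, j in f_edges
        ) + 2 * math.log(n)
        assert tri_bic < f_bic  # the addition is justified
        assert decomposable_bic(stepped.graph, corr, n) == pytest.approx(tri_bic)
        assert decomposable_bic(forest.graph, corr, n) == pytest.approx(f_bic)

    def test_no_addition_on_tree_truth(self):
        df, _ = generate_tree_gaussian(6, 4000, 0.6, seed=3)
        forest = min_bic_forest(df)
        stepped = stepw_add(forest, df)
        assert set(stepped.graph.edges) == set(forest.graph.edges)

    def test_max_edges_zero_identity(self):
        x = self._triangle_data(seed=1)
        forest = min_bic_forest(x)
        stepped = stepw_add(forest, x, max_edges=0)
        assert set(stepped.graph.edges) == set(forest.graph.edges)

    def test_bic_never_increases_and_stays_chordal(self, rng):
        x = pd.DataFrame(rng.standard_normal((6, 60)) @ rng.standard_normal((60, 60)))
        x.index = [f"v{i}" for i in range(6)]
        corr = pd.DataFrame(np.corrcoef(x.to_numpy()), index=x.index, columns=x.index)
        forest = min_bic_forest(x)
        prev = decomposable_bic(forest.graph, corr, x.shape[1])
        g = forest
        for _ in range(4):
            g2 = stepw_add(g, x, max_edges=1)
            assert nx.is_chordal(g2.graph)
            cur = decomposable_bic(g2.graph, corr, x.shape[1])
            assert cur <= prev + 1e-9
            if g2.graph.number_of_edges() == g.graph.number_of_edges():
                break
            prev, g = cur, g2

    def test_non_chordal_input_rejected(self, rng):
        x = pd.DataFrame(rng.standard_normal((4, 50)), index=list("abcd"))
        g = nx.cycle_graph(4)
        g = nx.relabel_nodes(g, dict(enumerate("abcd")))
        with pytest.raises(ValueError):
            stepw_add(BicGraph(g, 50), x)


class TestFunctionalNodes:
    def test_small_component_intact(self):
        g = nx.path_graph(5)
        nodes = split_functional_nodes(BicGraph(g, 100), max_size=30)
        assert len(nodes) == 1 and len(nodes[0].members) == 5

    def test_path_60_split_in_half(self):
        g = nx.path_graph(60)
        nodes = split_functional_nodes(BicGraph(g, 100), max_size=30)
        sizes = sorted(len(n.members) for n in nodes)
        assert sizes == [30, 30]

    def test_empty_graph(self):
        assert split_functional_nodes(BicGraph(nx.Graph(), 100)) == []

    def test_majority_annotation_label(self):
        g = nx.path_graph(3)
        ann = pd.Series({0: "glycolysis", 1: "glycolysis", 2: "TCA"})
        nodes = split_functional_nodes(BicGraph(g, 100), annotation=ann)
        assert nodes[0].label == "glycolysis"


class TestActivity:
    def test_single_protein_node(self, rng):
        m = pd.DataFrame(rng.standard_normal((3, 5)), index=["a", "b", "c"])
        node = FunctionalNode("n0", ("a",))
        pd.testing.assert_series_equal(
            node_activity(node, m), m.loc["a"], check_names=False
        )

    def test_mean_of_members(self):
        m = pd.DataFrame([[1.0, -1.0], [1.0, 1.0]], index=["a", "b"])
        act = node_activity(FunctionalNode("n0", ("a", "b")), m)
        assert act.tolist() == [1.0, 0.0]

    def test_mirna_excluded(self):
        m = pd.DataFrame([[1.0, 1.0], [9.0, 9.0]], index=["prot", "mir"])
        kind = pd.Series({"prot": "protein", "mir": "mirna"})
        act = node_activity(FunctionalNode("n0", ("prot", "mir")), m, kind)
        assert act.tolist() == [1.0, 1.0]

    def test_all_mirna_node_rejected(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["mir"])
        kind = pd.Series({"mir": "mirna"})
        with pytest.raises(ValueError):
            node_activity(FunctionalNode("n0", ("mir",)), m, kind)

    def test_planted_module_separates_groups(self):
        from tnlike.synth import CohortSpec, generate_cohort
        from tnlike import preprocess

        spec = CohortSpec(
            n_per_group=(30, 10, 30), n_proteins=100, n_differential=20,
            effect_size=1.5, missing_rate=0.0, batch_shift=0.0,
            overlap_fraction=1.0, n_tnlike_extra=0, seed=2,
        )
        c = generate_cohort(spec)
        z = preprocess.zscore_rows(preprocess.log2_transform(c.expression)).data
        g = c.true_labels
        # orient members by their true shift direction so the module mean
        # accumulates rather than cancels the planted signal
        truth = c.truth_log2
        diff = sorted(c.true_differential)
        sign = np.sign(
            truth.loc[diff, g[g == "TNBC"].index].mean(axis=1)
            - truth.loc[diff, g[g == "ER-true"].index].mean(axis=1)
        )
        oriented = z.loc[diff].mul(sign, axis=0)
        act = node_activity(FunctionalNode("n0", tuple(diff)), oriented)
        keep = g[g != "TN-like"].index
        _, p = compare_activity(act[keep], g[keep])
        assert p < 1e-6
        gap = act[g[g == "TNBC"].index].mean() - act[g[g == "ER-true"].index].mean()
        # z-scoring compresses the planted 1.5-sigma shift somewhat
        assert gap == pytest.approx(spec.effect_size, rel=0.35)

    def test_compare_identical_groups(self, rng):
        act = pd.Series(np.tile(rng.standard_normal(10), 2))
        labels = ["A"] * 10 + ["B"] * 10
        _, p = compare_activity(act, labels)
        assert p > 0.9

    def test_compare_label_swap_invariant(self, rng):
        act = pd.Series(rng.standard_normal(20))
        labels = np.array(["A"] * 10 + ["B"] * 10)
        _, p1 = compare_activity(act, labels)
        _, p2 = compare_activity(act, labels[::-1])
        assert p1 == pytest.approx(p2)

    def test_shifted_groups_significant(self, rng):
        act = pd.Series(np.r_[rng.standard_normal(30), rng.standard_normal(30) + 2])
        labels = ["A"] * 30 + ["B"] * 30
        _, p = compare_activity(act, labels)
        assert p < 0.001


class TestMirnaCorrelation:
    def test_duplicate_and_negated(self, rng):
        act = pd.Series(rng.standard_normal(20))
        r, _ = mirna_activity_correlation(act.copy(), act)
        assert r == pytest.approx(1.0)
        r, _ = mirna_activity_correlation(-act, act)
        assert r == pytest.approx(-1.0)

    def test_independent_small_r(self, rng):
        act = pd.Series(rng.standard_normal(500))
        mir = pd.Series(rng.standard_normal(500), index=act.index)
        r, p = mirna_activity_correlation(mir, act)
        assert abs(r) < 0.15

    def test_zero_variance_rejected(self):
        act = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            mirna_activity_correlation(pd.Series([1.0, 1.0, 1.0]), act)
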
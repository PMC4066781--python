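"""Decomposition machinery and the two-group permutation test engine.

Brute-force oracles (independent of the implementation's route): moralization
by explicit parent-pair marriage, maximal cliques by subset enumeration,
exhaustive running-intersection checks, dense-matrix statistics and exhaustive
permutation enumeration at tiny n.
"""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pathwire.graph_model import Config, ExpressionDataset
from pathwire.ggm_testing import (SingularMarginalError, adjust_bh,
                                  build_junction_tree,
                                  concentration_statistic,
                                  decomposable_mle, joint_permutation_test,
                                  mean_statistic, moralize,
                                  permutation_pvalue, select_pathways,
                                  triangulate)
from pathwire.ggm_testing import test_pathway as run_pathway_test


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def moral_oracle(digraph: nx.DiGraph) -> nx.Graph:
    """Textbook moralization: undirect every edge, marry all parent pairs."""
    g = nx.Graph()
    g.add_nodes_from(digraph.nodes)
    for u, v in digraph.edges:
        if u != v:
            g.add_edge(u, v)
    for child in digraph.nodes:
        parents = [p for p in digraph.predecessors(child) if p != child]
        for a, b in itertools.combinations(parents, 2):
            g.add_edge(a, b)
    return g


def maximal_cliques_oracle(g: nx.Graph) -> set:
    """All maximal cliques by subset enumeration (n <= ~12)."""
    nodes = sorted(g.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(g.has_edge(a, b)
                   for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    return {tuple(sorted(c)) for c in cliques
            if not any(c < d for d in cliques)}


def random_dag(rng, n, p=0.3) -> nx.DiGraph:
    g = nx.DiGraph()
    names = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j])
    return g


def _dataset_from_matrix(X, n1):
    feats = [f"f{i}" for i in range(X.shape[0])]
    samples = [f"s{i:03d}" for i in range(X.shape[1])]
    values = pd.DataFrame(X, index=feats, columns=samples)
    groups = pd.Series(["a"] * n1 + ["b"] * (X.shape[1] - n1), index=samples)
    return ExpressionDataset(values, groups)


def _chain_decomp():
    """A - B - C chain: cliques {A,B}, {B,C}, separator {B}."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return triangulate(g)


# ---------------------------------------------------------------------------
# moralization
# ---------------------------------------------------------------------------

class TestMoralize:
    def test_single_edge(self):
        d = nx.DiGraph([("A", "B")])
        m = moralize(d)
        assert set(m.edges) == {("A", "B")}

    def test_v_structure_marries_parents(self):
        d = nx.DiGraph([("A", "C"), ("B", "C")])
        m = moralize(d)
        assert {frozenset(e) for e in m.edges} == {
            frozenset({"A", "C"}), frozenset({"B", "C"}),
            frozenset({"A", "B"})}

    def test_matches_oracle_on_random_dags(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            d = random_dag(rng, 8)
            ours = moralize(d)
            ref = moral_oracle(d)
            assert ({frozenset(e) for e in ours.edges}
                    == {frozenset(e) for e in ref.edges})


# ---------------------------------------------------------------------------
# triangulation / cliques / junction tree
# ---------------------------------------------------------------------------

class TestTriangulate:
    def test_tree_needs_no_fill(self):
        t = nx.random_labeled_tree(9, seed=4)
        t = nx.relabel_nodes(t, {i: f"n{i}" for i in t.nodes})
        d = triangulate(t)
        assert d.fill_edges == ()

    def test_four_cycle_one_fill(self):
        c4 = nx.cycle_graph(["A", "B", "C", "D"])
        d = triangulate(c4)
        assert len(d.fill_edges) == 1
        assert nx.is_chordal(d.chordal)

    def test_random_graphs_chordal_and_cliques_match_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, 0.35,
                                    seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            d = triangulate(g)
            assert nx.is_chordal(d.chordal)
            assert set(g.edges) <= {tuple(sorted(e))
                                    for e in map(sorted, d.chordal.edges)} \
                   or all(d.chordal.has_edge(*e) for e in g.edges)
            assert set(d.cliques) == maximal_cliques_oracle(d.chordal)

    def test_clique_cover_is_node_set(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(9, 0.3, seed=8)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        d = triangulate(g)
        assert set().union(*map(set, d.cliques)) == set(g.nodes)


class TestJunctionTree:
    def test_two_clique_chain(self):
        d = _chain_decomp()
        jt = build_junction_tree(d)
        assert jt.cliques == [("A", "B"), ("B", "C")]
        assert jt.separator(("A", "B"), ("B", "C")) == ("B",)

    def test_single_clique_tree(self):
        g = nx.complete_graph(["A", "B", "C"])
        jt = build_junction_tree(triangulate(g))
        assert len(jt.cliques) == 1
        assert jt.tree.number_of_edges() == 0

    def test_edge_count_equals_cliques_minus_components(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            g = nx.gnp_random_graph(10, 0.22,
                                    seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            d = triangulate(g)
            jt = d.junction_tree
            assert (jt.tree.number_of_edges()
                    == len(d.cliques) - jt.n_components)

    def test_rip_exhaustive_on_random_chordal_graphs(self):
        rng = np.random.default_rng(37)
        for _ in range(30):
            g = nx.gnp_random_graph(12, 0.3,
                                    seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            jt = triangulate(g).junction_tree
            # independent exhaustive check
            for c1, c2 in itertools.combinations(jt.cliques, 2):
                inter = set(c1) & set(c2)
                if not inter or not nx.has_path(jt.tree, c1, c2):
                    continue
                for c in nx.shortest_path(jt.tree, c1, c2):
                    assert inter <= set(c)


# ---------------------------------------------------------------------------
# decomposable MLE
# ---------------------------------------------------------------------------

def _random_spd(rng, p):
    a = rng.standard_normal((p, 2 * p))
    return a @ a.T / (2 * p)


class TestDecomposableMLE:
    def test_complete_graph_is_saturated(self):
        rng = np.random.default_rng(0)
        g = nx.complete_graph(["A", "B", "C", "D"])
        d = triangulate(g)
        S = _random_spd(rng, 4)
        sigma, K, logdet = decomposable_mle(S, d)
        np.testing.assert_allclose(sigma, S, atol=1e-10)
        assert logdet == pytest.approx(np.linalg.slogdet(S)[1])

    def test_edgeless_graph_is_independence(self):
        rng = np.random.default_rng(1)
        g = nx.Graph()
        g.add_nodes_from(["A", "B", "C"])
        d = triangulate(g)
        S = _random_spd(rng, 3)
        sigma, _, logdet = decomposable_mle(S, d)
        np.testing.assert_allclose(sigma, np.diag(np.diag(S)), atol=1e-12)
        assert logdet == pytest.approx(float(np.sum(np.log(np.diag(S)))))

    def test_chain_conditional_independence(self):
        # A-B-C chain: Sigma_AC = S_AB * S_BC / S_BB
        rng = np.random.default_rng(2)
        d = _chain_decomp()
        S = _random_spd(rng, 3)  # order A, B, C
        sigma, K, _ = decomposable_mle(S, d)
        assert sigma[0, 2] == pytest.approx(S[0, 1] * S[1, 2] / S[1, 1])
        # clique-covered entries match S exactly
        for i, j in [(0, 0), (0, 1), (1, 1), (1, 2), (2, 2)]:
            assert sigma[i, j] == pytest.approx(S[i, j], abs=1e-10)

    def test_logdet_identity_random_decompositions(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.35,
                                    seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            d = triangulate(g)
            S = _random_spd(rng, n)
            sigma, _, logdet = decomposable_mle(S, d)
            assert abs(logdet - np.linalg.slogdet(sigma)[1]) < 1e-8

    def test_singular_marginal_raises_without_ridge(self):
        d = _chain_decomp()
        S = np.zeros((3, 3))  # rank-deficient marginals
        with pytest.raises(SingularMarginalError, match="ridge"):
            decomposable_mle(S, d)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class TestMeanStatistic:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(4)
        d = _chain_decomp()
        X = rng.standard_normal((3, 8))
        assert mean_statistic(X, X.copy(), d) == pytest.approx(0.0)

    def test_univariate_closed_form(self):
        rng = np.random.default_rng(5)
        g = nx.Graph()
        g.add_node("A")
        d = triangulate(g)
        x1 = rng.standard_normal((1, 7))
        x2 = rng.standard_normal((1, 9)) + 1.0
        n1, n2 = 7, 9
        diff = x1.mean() - x2.mean()
        s_pool = (n1 * x1.var() + n2 * x2.var()) / (n1 + n2)  # MLE variances
        expected = n1 * n2 / (n1 + n2) * diff**2 / s_pool
        assert mean_statistic(x1, x2, d) == pytest.approx(expected)

    def test_three_variable_toy_vs_dense_oracle(self):
        # chain decomposition: build Sigma-hat densely from its closed
        # form, invert with numpy, and evaluate T^2 by direct matrix
        # arithmetic
        rng = np.random.default_rng(6)
        d = _chain_decomp()
        X1 = rng.standard_normal((3, 5))
        X2 = rng.standard_normal((3, 5)) + np.array([[0.5], [0], [0]])
        n1 = n2 = 5
        c1 = X1 - X1.mean(1, keepdims=True)
        c2 = X2 - X2.mean(1, keepdims=True)
        S = (c1 @ c1.T + c2 @ c2.T) / (n1 + n2)
        sigma = S.copy()
        sigma[0, 2] = sigma[2, 0] = S[0, 1] * S[1, 2] / S[1, 1]
        dvec = X1.mean(1) - X2.mean(1)
        expected = (n1 * n2 / (n1 + n2)
                    * dvec @ np.linalg.inv(sigma) @ dvec)
        assert mean_statistic(X1, X2, d) == pytest.approx(expected)


class TestConcentrationStatistic:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(7)
        d = _chain_decomp()
        X = rng.standard_normal((3, 10))
        assert concentration_statistic(X, X.copy(), d) == pytest.approx(
            0.0, abs=1e-9)

    def test_closed_form_isotropic_example(self):
        # S1 = I, S2 = 2I (2 vars, n1 = n2 = 10):
        # pooled = 1.5 I, Lambda = 20 logdet(1.5 I) - 10*0 - 10 logdet(2I)
        rng = np.random.default_rng(8)
        g = nx.complete_graph(["A", "B"])
        d = triangulate(g)

        def with_exact_cov(target, n):
            X = rng.standard_normal((2, n))
            X = X - X.mean(1, keepdims=True)
            S = X @ X.T / n
            W = np.linalg.cholesky(np.linalg.inv(S)).T  # W S W' = I
            return np.linalg.cholesky(target) @ W @ X

        X1 = with_exact_cov(np.eye(2), 10)
        X2 = with_exact_cov(2 * np.eye(2), 10)
        expected = 20 * 2 * math.log(1.5) - 10 * 2 * math.log(2.0)
        assert concentration_statistic(X1, X2, d) == pytest.approx(expected)

    def test_nonnegative_lrt_random_data(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(4, 8))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            d = triangulate(g)
            if d.max_clique_size >= 12:
                continue
            X1 = rng.standard_normal((n, 30))
            X2 = rng.standard_normal((n, 25))
            assert concentration_statistic(X1, X2, d) >= -1e-9


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _mean_diff_stat(X1, X2):
    return abs(X1.mean() - X2.mean())


class TestPermutationPvalue:
    def test_floor_when_observed_exceeds_all(self):
        X = np.array([[10., 11., 12., 0., 0.5, 1.]])
        labels = np.array([True] * 3 + [False] * 3)
        p = permutation_pvalue(_mean_diff_stat, X, labels, B=99,
                               rng=np.random.default_rng(0))
        # only relabelings equal to the observed (or its mirror) tie it
        assert p <= (1 + 12) / 100

    def test_constant_data_p_one(self):
        X = np.ones((2, 8))
        labels = np.array([True] * 4 + [False] * 4)
        p = permutation_pvalue(_mean_diff_stat, X, labels, B=50,
                               rng=np.random.default_rng(1))
        assert p == 1.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((2, 6))
        X[:, :3] += 1.0
        labels = np.array([True] * 3 + [False] * 3)
        obs = _mean_diff_stat(X[:, labels], X[:, ~labels])
        exact = np.mean([
            _mean_diff_stat(X[:, list(idx)],
                            X[:, [i for i in range(6) if i not in idx]])
            >= obs
            for idx in itertools.combinations(range(6), 3)])
        p = permutation_pvalue(_mean_diff_stat, X, labels, B=999,
                               rng=np.random.default_rng(11))
        assert p == pytest.approx(exact, abs=0.1)


class TestJointEngine:
    def test_row0_matches_scalar_statistics(self):
        rng = np.random.default_rng(12)
        g = nx.gnp_random_graph(6, 0.4, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        d = triangulate(g)
        X = rng.standard_normal((6, 24))
        labels = np.array([True] * 10 + [False] * 14)
        res = joint_permutation_test(X, labels, d.blocks(), B=5,
                                     rng=np.random.default_rng(13))
        X1, X2 = X[:, labels], X[:, ~labels]
        assert res.stat_mean == pytest.approx(mean_statistic(X1, X2, d))
        assert res.stat_var == pytest.approx(
            concentration_statistic(X1, X2, d))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(14)
        d = _chain_decomp()
        X = rng.standard_normal((3, 16))
        labels = np.array([True] * 8 + [False] * 8)
        r1 = joint_permutation_test(X, labels, d.blocks(), 50,
                                    np.random.default_rng(99))
        r2 = joint_permutation_test(X, labels, d.blocks(), 50,
                                    np.random.default_rng(99))
        assert (r1.p_mean, r1.p_var) == (r2.p_mean, r2.p_var)


# ---------------------------------------------------------------------------
# pathway-level testing
# ---------------------------------------------------------------------------

class TestTestPathway:
    def test_unmeasured_pathway_skipped(self, toy_graph, two_group_dataset,
                                        default_config):
        # dataset features F0..F5 do not overlap the graph nodes
        rng = np.random.default_rng(0)
        assert run_pathway_test(toy_graph, two_group_dataset, default_config,
                            rng) is None

    def test_planted_shift_detected(self):
        from pathwire.synthetic_data import SimulationSpec, \
            simulate_expression, simulate_pathway
        hits = 0
        for s in range(10):
            spec = SimulationSpec(seed=s, delta=2.0, variance_scale=1.0)
            g = simulate_pathway(spec)
            expr = simulate_expression(g, spec)
            cfg = Config(permutations=200, seed=s)
            res = run_pathway_test(g, expr, cfg, np.random.default_rng(s))
            hits += res.p_mean <= 0.05
        assert hits >= 9

    def test_null_pvalues_roughly_uniform(self):
        from pathwire.synthetic_data import SimulationSpec, \
            simulate_expression, simulate_pathway
        ps = []
        for s in range(40):
            spec = SimulationSpec(seed=s, n1=15, n2=15, planted_path=None)
            g = simulate_pathway(spec)
            expr = simulate_expression(g, spec)
            cfg = Config(permutations=99, seed=s)
            res = run_pathway_test(g, expr, cfg, np.random.default_rng(s))
            ps.append(res.p_mean)
        ps = np.asarray(ps)
        assert 0.25 <= ps.mean() <= 0.75
        assert (ps <= 0.10).mean() <= 0.30


class TestAdjustAndSelect:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_step_up_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_monotone_nondecreasing_in_sorted_order(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(size=25)
        q = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0)

    def _table(self, rows):
        return pd.DataFrame(rows, columns=["pathway_id", "q_mean", "q_var"])

    def test_both_rule(self):
        t = self._table([("a", 0.0, 0.09), ("b", 0.2, 0.0), ("c", 0.05, 0.05)])
        assert select_pathways(t, 0.1, "both") == ["a", "c"]

    def test_either_rule(self):
        t = self._table([("a", 0.0, 0.9), ("b", 0.2, 0.2)])
        assert select_pathways(t, 0.1, "either") == ["a"]

    def test_empty(self):
        assert select_pathways(pd.DataFrame(), 0.1) == []
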
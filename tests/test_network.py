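import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import hypergeom

from gclayers.matrix import ExpressionMatrix
from gclayers.network import (
    enrich_branch,
    forward_bic_search,
    gaussian_bic,
    is_decomposable,
    ml_spanning_tree,
    node_activity,
    partition_branches,
)


def _gauss_matrix(cov, n, seed, names=None):
    rng = np.random.default_rng(seed)
    p = len(cov)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n).T
    names = names or [f"G{i}" for i in range(p)]
    return ExpressionMatrix(pd.DataFrame(
        X, index=names, columns=[f"S{j}" for j in range(n)]))


def brute_force_chordal(g: nx.Graph) -> bool:
    """A graph is chordal iff no vertex subset of size ≥ 4 induces a cycle."""
    nodes = list(g.nodes)
    for size in range(4, len(nodes) + 1):
        for sub in itertools.combinations(nodes, size):
            induced = g.subgraph(sub)
            if all(d == 2 for _, d in induced.degree) and nx.is_connected(induced):
                return False
    return True


class TestIsDecomposable:
    def test_four_cycle_is_not(self):
        assert not is_decomposable(nx.cycle_graph(4))
        g = nx.cycle_graph(4)
        g.add_edge(0, 2)
        assert is_decomposable(g)

    def test_trees_and_forests_are(self):
        assert is_decomposable(nx.random_labeled_tree(12, seed=1))
        forest = nx.Graph()
        forest.add_edges_from([(0, 1), (2, 3)])
        forest.add_node(9)
        assert is_decomposable(forest)

    def test_complete_graphs_are(self):
        assert is_decomposable(nx.complete_graph(6))

    def test_agrees_with_bruteforce_on_five_vertices(self):
        """Exhaustive check over all 2^10 graphs on 5 vertices (the
        6-vertex sweep runs in the acceptance suite)."""
        pairs = list(itertools.combinations(range(5), 2))
        for mask in range(2 ** len(pairs)):
            g = nx.Graph()
            g.add_nodes_from(range(5))
            g.add_edges_from(e for i, e in enumerate(pairs) if mask >> i & 1)
            assert is_decomposable(g) == brute_force_chordal(g), f"mask={mask}"


class TestMlSpanningTree:
    def test_keeps_two_strongest_edges_of_three_genes(self):
        # pairwise |r| ≈ 0.9 (0-1), 0.5 (0-2), weak (1-2)
        cov = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.45], [0.5, 0.45, 1.0]])
        m = _gauss_matrix(cov, 400, seed=2)
        tree = ml_spanning_tree(m)
        R = np.corrcoef(m.values.to_numpy())
        n = m.n_samples
        # oracle: score all 3 spanning trees by summed edge log-likelihood
        def tree_score(edges):
            return sum(-(n / 2) * math.log(1 - R[i, j] ** 2) for i, j in edges)

        trees = [[(0, 1), (0, 2)], [(0, 1), (1, 2)], [(0, 2), (1, 2)]]
        best = max(trees, key=tree_score)
        expected = {tuple(sorted((f"G{i}", f"G{j}"))) for i, j in best}
        assert set(tree.edges) == expected

    def test_independent_genes_give_empty_forest(self):
        # exactly orthogonal contrasts: all pairwise r = 0
        X = np.array([
            [1, -1, 1, -1, 1, -1, 1, -1],
            [1, 1, -1, -1, 1, 1, -1, -1],
            [1, -1, -1, 1, 1, -1, -1, 1],
        ], dtype=float)
        m = ExpressionMatrix(pd.DataFrame(
            X, index=["G0", "G1", "G2"], columns=[f"S{j}" for j in range(8)]))
        tree = ml_spanning_tree(m)
        assert tree.graph.number_of_edges() == 0

    def test_edge_count_bounded_by_p_minus_one(self, rng):
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(15, 40)),
            index=[f"G{i}" for i in range(15)],
            columns=[f"S{j}" for j in range(40)]))
        assert ml_spanning_tree(m).graph.number_of_edges() <= 14

    def test_zero_variance_gene_rejected(self):
        m = ExpressionMatrix(pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["GZ", "G1"],
            columns=["S0", "S1", "S2"]))
        with pytest.raises(ValueError, match="GZ"):
            ml_spanning_tree(m)


class TestForwardSearch:
    def test_zero_budget_is_identity(self):
        cov = np.eye(3) + 0.5 - 0.5 * np.eye(3)
        m = _gauss_matrix(cov, 100, seed=3)
        tree = ml_spanning_tree(m)
        out = forward_bic_search(tree, m, max_added_edges=0)
        assert set(out.edges) == set(tree.edges)

    def test_triangle_model_recovered(self):
        cov = np.array([[1.0, 0.6, 0.6], [0.6, 1.0, 0.6], [0.6, 0.6, 1.0]])
        m = _gauss_matrix(cov, 500, seed=4)
        out = forward_bic_search(ml_spanning_tree(m), m)
        # oracle: exhaustively score all 8 graphs on 3 vertices (all chordal)
        best_bic, best_edges = np.inf, None
        for k in range(4):
            for edges in itertools.combinations([(0, 1), (0, 2), (1, 2)], k):
                g = nx.Graph()
                g.add_nodes_from(["G0", "G1", "G2"])
                g.add_edges_from((f"G{i}", f"G{j}") for i, j in edges)
                b = gaussian_bic(g, m)
                if b < best_bic:
                    best_bic, best_edges = b, g.number_of_edges()
        assert best_edges == 3  # the triangle wins on this model
        assert out.graph.number_of_edges() == 3
        assert out.bic == pytest.approx(best_bic, abs=1e-6)

    def test_tree_model_adds_no_edges_in_most_seeds(self):
        # chain 0-1-2-3 Gaussian model; the tree is already optimal
        prec_chain = np.array([
            [1.5, -0.6, 0.0, 0.0],
            [-0.6, 1.8, -0.6, 0.0],
            [0.0, -0.6, 1.8, -0.6],
            [0.0, 0.0, -0.6, 1.5],
        ])
        cov = np.linalg.inv(prec_chain)
        clean = 0
        for seed in range(5):
            m = _gauss_matrix(cov, 500, seed=seed)
            tree = ml_spanning_tree(m)
            out = forward_bic_search(tree, m)
            clean += out.graph.number_of_edges() == tree.graph.number_of_edges()
        assert clean >= 4

    def test_bic_decreases_and_matches_fresh_recomputation(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(8, 8))
        cov = A @ A.T + 8 * np.eye(8)
        m = _gauss_matrix(cov, 200, seed=10)
        tree = ml_spanning_tree(m)
        out = forward_bic_search(tree, m, max_added_edges=10)
        assert out.bic <= tree.bic + 1e-9
        added = set(out.edges) - set(tree.edges)
        assert all(out.edge_gain[e] < 0 for e in added)
        assert is_decomposable(out.graph)
        assert out.bic == pytest.approx(gaussian_bic(out.graph, m), abs=1e-6)

    def test_non_decomposable_start_rejected(self):
        from gclayers.network import DecomposableGraph

        m = _gauss_matrix(np.eye(4), 50, seed=1)
        bad = DecomposableGraph(graph=nx.cycle_graph(["G0", "G1", "G2", "G3"]))
        with pytest.raises(ValueError, match="not decomposable"):
            forward_bic_search(bad, m)


class TestPartitionBranches:
    def test_single_small_component_is_one_branch(self):
        g = nx.path_graph(["a", "b", "c"])
        assert set(partition_branches(g, max_branch_size=5).values()) == {1}

    def test_bridge_between_cliques_is_cut(self):
        g = nx.complete_graph(["a1", "a2", "a3", "a4"])
        g = nx.compose(g, nx.complete_graph(["b1", "b2", "b3", "b4"]))
        g.add_edge("a1", "b1")  # the bridge has maximal betweenness
        branches = partition_branches(g, max_branch_size=4)
        assert len(set(branches.values())) == 2
        assert branches["a1"] != branches["b1"]
        assert branches["a1"] == branches["a4"]

    def test_target_branch_count(self):
        g = nx.path_graph([f"v{i:02d}" for i in range(24)])
        branches = partition_branches(g, max_branch_size=24, n_branches=12)
        assert len(set(branches.values())) == 12

    def test_small_branches_merged(self):
        g = nx.path_graph(["a", "b", "c", "d", "e", "f"])
        branches = partition_branches(g, max_branch_size=3, min_branch_size=2)
        sizes = pd.Series(branches).value_counts()
        assert (sizes >= 2).all()

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            partition_branches(nx.path_graph(3), max_branch_size=2, min_branch_size=5)


class TestEnrichment:
    def test_branch_equal_to_set_ranks_first(self):
        branch = [f"G{i}" for i in range(10)]
        background = [f"G{i}" for i in range(100)]
        annotation = {"HIT": branch, "OTHER": [f"G{i}" for i in range(50, 60)]}
        table = enrich_branch(branch, background, annotation)
        assert table.iloc[0]["name"] == "HIT"
        # point mass of drawing all 10 set members in 10 draws from 100
        assert table.iloc[0]["p"] == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_disjoint_sets_give_p_one(self):
        table = enrich_branch(
            ["G1", "G2"], ["G1", "G2", "G3", "G4"], {"S": ["G3", "G4"]}
        )
        assert (table["p"] == 1.0).all()

    def test_tail_matches_direct_summation(self):
        # 10 branch genes, 5 in the set; background 100, set size 8
        branch = [f"G{i}" for i in range(10)]
        background = [f"G{i}" for i in range(100)]
        annotation = {"S": [f"G{i}" for i in range(5)] + ["G90", "G91", "G92"]}
        table = enrich_branch(branch, background, annotation)
        direct = sum(
            comb(8, k) * comb(92, 10 - k) / comb(100, 10) for k in range(5, 9)
        )
        assert table.iloc[0]["p"] == pytest.approx(direct, rel=1e-9)
        assert table.iloc[0]["p"] == pytest.approx(
            hypergeom.sf(4, 100, 8, 10), rel=1e-12
        )

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            enrich_branch(["G1"], ["G1"], {})


class TestNodeActivity:
    def test_single_gene_node_equals_gene_row(self, rng):
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(5, 6)), index=[f"G{i}" for i in range(5)],
            columns=[f"S{j}" for j in range(6)]))
        act = node_activity(m, {"n1": ["G2"]})
        assert np.allclose(act.loc["n1"], m.values.loc["G2"])

    def test_constant_matrix(self):
        m = ExpressionMatrix(pd.DataFrame(
            3.5, index=["G0", "G1"], columns=["S0", "S1"]))
        act = node_activity(m, {"n": ["G0", "G1"]})
        assert (act.to_numpy() == 3.5).all()

    def test_matches_bruteforce_and_is_order_invariant(self, rng):
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(6, 4)), index=[f"G{i}" for i in range(6)],
            columns=[f"S{j}" for j in range(4)]))
        genes = ["G3", "G0", "G5"]
        act = node_activity(m, {"n": genes})
        brute = sum(m.values.loc[g] for g in genes) / 3
        assert np.allclose(act.loc["n"], brute)
        act2 = node_activity(m, {"n": list(reversed(genes))})
        assert np.allclose(act.loc["n"], act2.loc["n"])

    def test_linearity(self, rng):
        vals = rng.normal(size=(4, 3))
        m1 = ExpressionMatrix(pd.DataFrame(
            vals, index=list("ABCD"), columns=["S0", "S1", "S2"]))
        m2 = ExpressionMatrix(pd.DataFrame(
            2 * vals + 1, index=list("ABCD"), columns=["S0", "S1", "S2"]))
        a1 = node_activity(m1, {"n": ["A", "C"]})
        a2 = node_activity(m2, {"n": ["A", "C"]})
        assert np.allclose(a2, 2 * a1 + 1)

    def test_empty_set_rejected(self, rng):
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(2, 2)), index=["A", "B"], columns=["S0", "S1"]))
        with pytest.raises(ValueError, match="empty"):
            node_activity(m, {"n": []})
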
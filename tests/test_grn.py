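"""JSD computation, entropy-based thresholding and the GRN metric panel."""

import igraph as ig
import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mesoconnect import (
    DivergenceMatrix,
    ExpressionMatrix,
    ValidationError,
    betweenness_entropy,
    betweenness_entropy_sweep,
    build_grn,
    grn_metric_panel,
    jensen_shannon_divergence,
    normalize_profile,
    pairwise_divergence,
)

probability_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=8
).filter(lambda xs: sum(xs) > 1e-6).map(
    lambda xs: np.asarray(xs) / np.sum(xs)
)


class TestNormalizeProfile:
    @pytest.mark.parametrize(
        "row,expected",
        [([2, 2], [0.5, 0.5]), ([1, 0, 3], [0.25, 0, 0.75])],
    )
    def test_values(self, row, expected):
        np.testing.assert_allclose(normalize_profile(np.array(row)), expected)

    def test_all_zero_errors(self):
        with pytest.raises(ValidationError):
            normalize_profile(np.array([0.0, 0.0]), label="gX")


class TestJSD:
    def test_identical_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jensen_shannon_divergence(p, p) == 0.0

    def test_disjoint_supports_is_one(self):
        assert jensen_shannon_divergence([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # 0.5*KL + 0.5*KL evaluates to 0.215762 nats = 0.311278 bits
        d = jensen_shannon_divergence([0.5, 0.5], [1.0, 0.0])
        assert d == pytest.approx(0.311278, abs=1e-6)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValidationError):
            jensen_shannon_divergence([1.0], [0.5, 0.5])

    def test_unnormalized_input_errors(self):
        with pytest.raises(ValidationError):
            jensen_shannon_divergence([0.5, 0.4], [0.5, 0.5])

    @given(probability_vectors, probability_vectors)
    def test_symmetry_and_range(self, p, q):
        if p.size != q.size:
            return
        d_pq = jensen_shannon_divergence(p, q)
        d_qp = jensen_shannon_divergence(q, p)
        assert d_pq == d_qp
        assert 0.0 <= d_pq <= 1.0

    @given(probability_vectors)
    def test_zero_iff_equal(self, p):
        assert jensen_shannon_divergence(p, p) <= 1e-12


class TestPairwiseDivergence:
    def test_identical_rows_zero(self):
        expr = ExpressionMatrix(["a", "b"], ["r1", "r2"],
                                [[1.0, 3.0], [2.0, 6.0]])
        d = pairwise_divergence(expr, axis="genes")
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        values = rng.random((5, 7)) + 0.01
        expr = ExpressionMatrix([f"g{i}" for i in range(5)],
                                [f"r{j}" for j in range(7)], values)
        d = pairwise_divergence(expr, axis="genes")
        P = values / values.sum(axis=1, keepdims=True)
        for i in range(5):
            for j in range(5):
                expected = jensen_shannon_divergence(P[i], P[j])
                assert d.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_transpose_swaps_axes(self, rng):
        values = rng.random((4, 6)) + 0.01
        expr = ExpressionMatrix([f"g{i}" for i in range(4)],
                                [f"r{j}" for j in range(6)], values)
        exprT = ExpressionMatrix([f"r{j}" for j in range(6)],
                                 [f"g{i}" for i in range(4)], values.T)
        d_regions = pairwise_divergence(expr, axis="regions")
        d_genesT = pairwise_divergence(exprT, axis="genes")
        np.testing.assert_allclose(d_regions.values, d_genesT.values,
                                   atol=1e-12)

    def test_invariants_on_random_input(self, rng):
        values = rng.random((10, 5)) + 0.01
        expr = ExpressionMatrix([f"g{i}" for i in range(10)],
                                [f"r{j}" for j in range(5)], values)
        d = pairwise_divergence(expr, axis="genes")
        np.testing.assert_allclose(d.values, d.values.T)
        np.testing.assert_allclose(np.diag(d.values), 0.0)
        assert d.values.min() >= 0 and d.values.max() <= 1


class TestBetweennessEntropy:
    def test_path_p4_gives_ln2(self):
        # betweenness [0, 2, 2, 0]: two occupied cells of equal weight
        g = ig.Graph(n=4, edges=[(0, 1), (1, 2), (2, 3)])
        assert betweenness_entropy(g) == pytest.approx(np.log(2), abs=1e-12)

    def test_complete_graph_zero(self):
        g = ig.Graph.Full(6)
        assert betweenness_entropy(g) == 0.0

    def test_empty_graph_zero(self):
        assert betweenness_entropy(ig.Graph(n=5)) == 0.0


class TestEntropySweep:
    def test_selects_max_entropy_deterministically(self, rng):
        values = rng.random((12, 6)) + 0.01
        expr = ExpressionMatrix([f"g{i}" for i in range(12)],
                                [f"r{j}" for j in range(6)], values)
        d = pairwise_divergence(expr, axis="genes")
        s1 = betweenness_entropy_sweep(d)
        s2 = betweenness_entropy_sweep(d)
        assert s1.selected_percentile == s2.selected_percentile
        assert s1.entropy[s1.selected_percentile - 1] == s1.entropy.max()
        # ties break to the smallest percentile
        ties = np.nonzero(s1.entropy == s1.entropy.max())[0]
        assert s1.selected_percentile == s1.percentile_grid[ties[0]]

    def test_too_few_nodes_error(self):
        d = DivergenceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(ValidationError):
            betweenness_entropy_sweep(d)

    def test_empty_grid_error(self, rng):
        values = rng.random((5, 4)) + 0.01
        expr = ExpressionMatrix([f"g{i}" for i in range(5)],
                                [f"r{j}" for j in range(4)], values)
        d = pairwise_divergence(expr, axis="genes")
        with pytest.raises(ValidationError):
            betweenness_entropy_sweep(d, grid=np.array([], dtype=int))


class TestBuildGrn:
    @pytest.fixture
    def small_divergence(self):
        vals = np.array([
            [0.0, 0.1, 0.5, 0.6],
            [0.1, 0.0, 0.2, 0.7],
            [0.5, 0.2, 0.0, 0.3],
            [0.6, 0.7, 0.3, 0.0],
        ])
        return DivergenceMatrix(["a", "b", "c", "d"], vals)

    def test_cutoff_below_minimum_gives_empty_graph(self, small_divergence):
        g = build_grn(small_divergence, 0.05)
        assert g.number_of_nodes() == 0

    def test_cutoff_above_maximum_gives_complete_graph(self, small_divergence):
        g = build_grn(small_divergence, 1.0)
        assert g.number_of_edges() == 6

    def test_exact_edge_set(self, small_divergence):
        # pairs <= 0.3: (a,b)=.1, (b,c)=.2, (c,d)=.3 -> a path, nobody isolated
        g = build_grn(small_divergence, 0.3)
        assert set(map(frozenset, g.edges())) == {
            frozenset({"a", "b"}), frozenset({"b", "c"}), frozenset({"c", "d"})
        }

    def test_isolated_nodes_removed(self, small_divergence):
        g = build_grn(small_divergence, 0.1)
        assert set(g.nodes()) == {"a", "b"}

    def test_edge_count_monotone_in_cutoff(self, rng):
        values = rng.random((9, 5)) + 0.01
        expr = ExpressionMatrix([f"g{i}" for i in range(9)],
                                [f"r{j}" for j in range(5)], values)
        d = pairwise_divergence(expr, axis="genes")
        counts = [build_grn(d, c).number_of_edges()
                  for c in np.linspace(0, 1, 21)]
        assert (np.diff(counts) >= 0).all()


def _brute_betweenness_closeness(g: nx.Graph):
    """All-pairs BFS oracle for unnormalized betweenness and closeness."""
    nodes = list(g)
    betw = {v: 0.0 for v in nodes}
    close = {}
    for s in nodes:
        for t in nodes:
            if s >= t:
                continue
            paths = list(nx.all_shortest_paths(g, s, t)) \
                if nx.has_path(g, s, t) else []
            for path in paths:
                for v in path[1:-1]:
                    betw[v] += 1.0 / len(paths)
    n = len(nodes)
    for v in nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        total = sum(lengths.values())
        if total > 0:
            # networkx convention for disconnected graphs
            close[v] = (len(lengths) - 1) / total * (len(lengths) - 1) / (n - 1)
        else:
            close[v] = 0.0
    return betw, close


def _power_eigenvector(g: nx.Graph, iters=5000):
    nodes = list(g)
    A = nx.to_numpy_array(g, nodelist=nodes)
    v = np.ones(len(nodes))
    for _ in range(iters):
        v = A @ v
        v /= np.linalg.norm(v)
    return dict(zip(nodes, v / np.linalg.norm(v)))


class TestMetricPanel:
    def test_p4_betweenness_and_assortativity(self):
        g = nx.path_graph(4)
        panel = grn_metric_panel(g)
        np.testing.assert_allclose(panel.per_node["betweenness"].to_numpy(),
                                   [0, 2, 2, 0])
        assert panel.assortativity == pytest.approx(-0.5, abs=1e-12)

    def test_k4_degenerate_assortativity_nan(self):
        with pytest.warns(UserWarning, match="assortativity"):
            panel = grn_metric_panel(nx.complete_graph(4))
        assert np.isnan(panel.assortativity)
        assert panel.per_node["closeness"].nunique() == 1

    def test_disconnected_warns_and_reports_largest_component(self, two_cliques):
        g = two_cliques
        with pytest.warns(UserWarning, match="disconnected"):
            panel = grn_metric_panel(g)
        assert (panel.per_node["eigenvector"] >= 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracles(self, seed):
        g = nx.gnp_random_graph(18, 0.25, seed=seed)
        g.remove_nodes_from(list(nx.isolates(g)))
        if not nx.is_connected(g):
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        panel = grn_metric_panel(g)
        betw, close = _brute_betweenness_closeness(g)
        eig = _power_eigenvector(g)
        for v in g:
            assert panel.per_node.loc[v, "betweenness"] == pytest.approx(
                betw[v], abs=1e-8)
            assert panel.per_node.loc[v, "closeness"] == pytest.approx(
                close[v], abs=1e-8)
        got = panel.per_node["eigenvector"].to_numpy()
        want = np.array([eig[v] for v in panel.per_node.index])
        np.testing.assert_allclose(got / np.linalg.norm(got), want, atol=1e-6)
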
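import numpy as np
import pytest
from scipy import stats

from megconn.connectivity import (
    ConnectivityEdge,
    ConnectivityGraph,
    Direction,
    build_graph,
    classify_edges_and_nodes,
    detect_pattern,
    fit_mvar,
    granger_direction,
    pairwise_correlation,
    select_order_bic,
    t_threshold,
)
from megconn.source_reconstruction import SourceGrid, VirtualSensorSet
from megconn.synthetic import SourceNetworkSpec, simulate_mvar

LABELS2 = ("PFC", "TL")


def _var2(a_xy=0.0, a_yx=0.0, rho=0.0, diag=0.2, n=2000, seed=0):
    coupling = np.array([[[diag, a_xy], [a_yx, diag]]])
    spec = SourceNetworkSpec(2, coupling, np.array([[1.0, rho], [rho, 1.0]]), LABELS2)
    return simulate_mvar(spec, n, seed=seed)


class TestPairwiseCorrelation:
    def test_identity_and_sign_flip(self, rng):
        x = rng.standard_normal(100)
        R = pairwise_correlation(np.vstack([x, x, -x]))
        np.testing.assert_allclose(R[0, 1], 1.0, atol=1e-12)
        np.testing.assert_allclose(R[0, 2], -1.0, atol=1e-12)

    def test_hand_computed_example(self):
        """R([1,2,3],[1,2,4]) = 9 / sqrt(84)."""
        R = pairwise_correlation(np.array([[1.0, 2, 3], [1, 2, 4]]))
        np.testing.assert_allclose(R[0, 1], 9.0 / np.sqrt(84.0), rtol=1e-12)

    def test_zero_variance_source_excluded_not_nan(self, rng):
        sig = np.vstack([rng.standard_normal(50), np.full(50, 3.0), rng.standard_normal(50)])
        with pytest.warns(UserWarning, match="zero variance"):
            R = pairwise_correlation(sig)
        assert np.isfinite(R).all()
        assert R[0, 1] == 0.0 and R[1, 2] == 0.0 and R[1, 1] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pairwise_correlation(np.zeros((2, 2)))


class TestTThreshold:
    def test_null_never_retained(self):
        R = np.eye(3)
        adj, Tp, p = t_threshold(R, K=100)
        assert not adj.any()
        assert Tp[0, 1] == 0.0

    def test_hand_computed_t_value(self):
        """R = 0.5, K = 18 gives Tp = 0.5 sqrt(16 / 0.75) = 2.3094."""
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        _, Tp, _ = t_threshold(R, K=18)
        np.testing.assert_allclose(Tp[0, 1], 0.5 * np.sqrt(16 / 0.75), rtol=1e-12)
        np.testing.assert_allclose(Tp[0, 1], 2.3094, atol=1e-4)

    def test_minimal_retained_r_at_k540(self):
        """Inverting the t-threshold at K = 540, alpha = 0.01 gives a minimal
        retained |R| of about 0.111 (cross-checked by brute force over a grid)."""
        tcrit = stats.t.ppf(1 - 0.005, 538)
        r_min = tcrit / np.sqrt(538 + tcrit**2)
        np.testing.assert_allclose(r_min, 0.111, atol=5e-4)
        grid = np.linspace(0, 0.2, 2001)
        retained = []
        for r in grid:
            R = np.array([[1.0, r], [r, 1.0]])
            adj, _, _ = t_threshold(R, K=540, alpha=0.01)
            retained.append(adj[0, 1])
        boundary = grid[int(np.argmax(retained))]
        np.testing.assert_allclose(boundary, r_min, atol=1e-3)

    def test_k_at_most_2_rejected(self):
        with pytest.raises(ValueError):
            t_threshold(np.eye(2), K=2)

    def test_perfect_correlation_retained(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        adj, Tp, p = t_threshold(R, K=10)
        assert adj[0, 1] and np.isinf(Tp[0, 1]) and p[0, 1] == 0.0

    def test_threshold_equals_tcdf_rule(self, rng):
        """Retention via Tp is identical to direct two-sided t-CDF evaluation
        over random (R, K) pairs."""
        for _ in range(2000):
            r = rng.uniform(-0.999, 0.999)
            K = int(rng.integers(4, 1000))
            R = np.array([[1.0, r], [r, 1.0]])
            adj, Tp, _ = t_threshold(R, K, alpha=0.01)
            p_direct = 2 * (1 - stats.t.cdf(abs(Tp[0, 1]), K - 2))
            assert adj[0, 1] == (p_direct < 0.01)


class TestGranger:
    def test_planted_direction_recovered(self):
        hits = 0
        for seed in range(20):
            x = _var2(a_yx=0.5, n=2000, seed=seed)
            res = granger_direction(x, model_order_max=5)
            hits += res[(0, 1)]["direction"] == Direction.A_TO_B
        assert hits >= 18

    def test_null_pair_mostly_undirected(self):
        """Independent sources: fraction undirected stays within the binomial
        band implied by two independent F-tests at alpha = 0.05."""
        undirected = 0
        n_rep = 100
        for seed in range(n_rep):
            x = _var2(n=1500, seed=1000 + seed)
            res = granger_direction(x, model_order_max=4)
            undirected += res[(0, 1)]["direction"] == Direction.UNDIRECTED
        expected = 0.95**2
        se = np.sqrt(expected * (1 - expected) / n_rep)
        assert undirected / n_rep > expected - 3 * se

    def test_symmetric_coupling_recovered_as_bidirectional(self):
        x = _var2(a_xy=0.4, a_yx=0.4, n=4000, seed=5)
        res = granger_direction(x, model_order_max=5)
        assert res[(0, 1)]["direction"] == Direction.BIDIRECTIONAL

    def test_pairwise_equals_conditional_on_two_nodes(self):
        x = _var2(a_yx=0.4, n=1500, seed=9)
        cond = granger_direction(x, model_order_max=4, conditional=True, order=2)
        pair = granger_direction(x, model_order_max=4, conditional=False, order=2)
        np.testing.assert_allclose(cond[(0, 1)]["gc_ab"], pair[(0, 1)]["gc_ab"], rtol=1e-10)
        np.testing.assert_allclose(cond[(0, 1)]["gc_ba"], pair[(0, 1)]["gc_ba"], rtol=1e-10)

    def test_gc_nonnegative(self):
        for seed in range(10):
            x = _var2(a_yx=0.3, n=1000, seed=seed)
            res = granger_direction(x, model_order_max=3)[(0, 1)]
            assert res["gc_ab"] >= -1e-10 and res["gc_ba"] >= -1e-10

    def test_segments_respect_trial_boundaries(self, rng):
        """Fitting on trial segments must not use lags across segments: an
        explicit full-data design on concatenated trials gives a different
        (wrong) answer when the seam is informative."""
        segs = [
            _var2(a_yx=0.5, n=300, seed=s)
            for s in range(8)
        ]
        res = granger_direction(segs, model_order_max=3)
        assert res[(0, 1)]["direction"] == Direction.A_TO_B

    def test_degenerate_pair_flagged_undirected(self):
        x = np.zeros((2, 200))
        res = granger_direction(x, model_order_max=2, order=1)
        assert res[(0, 1)]["direction"] == Direction.UNDIRECTED
        assert res[(0, 1)].get("degenerate", False)

    def test_bic_selects_true_order(self):
        coupling = np.zeros((3, 2, 2))
        coupling[0] = [[0.4, 0.0], [0.3, 0.4]]
        coupling[2] = [[-0.3, 0.0], [0.0, -0.3]]
        spec = SourceNetworkSpec(2, coupling, np.eye(2), LABELS2)
        x = simulate_mvar(spec, 8000, seed=2)
        assert select_order_bic(x, max_order=6) == 3

    def test_fit_mvar_recovers_coefficients(self):
        x = _var2(a_yx=0.5, diag=0.3, n=50_000, seed=4)
        coef, sigma, _ = fit_mvar(x, order=1)
        np.testing.assert_allclose(
            coef[0], [[0.3, 0.0], [0.5, 0.3]], atol=0.02
        )
        np.testing.assert_allclose(sigma, np.eye(2), atol=0.02)


def _graph(edges, n=4, labels=("PFC", "PFC", "TL", "OTHER")):
    g = ConnectivityGraph(n_sources=n, edges=edges, region_labels=labels)
    return classify_edges_and_nodes(g)


class TestClassifyAndPattern:
    def test_single_directed_edge_roles_and_sign(self):
        e = ConnectivityEdge(0, 2, R=0.8, Tp=5.0, p_corr=0.001, direction=Direction.A_TO_B)
        g = _graph([e])
        assert e.sign == "excitatory"
        assert g.node_roles == ["driver", "isolated", "driven", "isolated"]

    def test_negative_correlation_is_inhibitory(self):
        e = ConnectivityEdge(0, 1, R=-0.7, Tp=-4.0, p_corr=0.001)
        assert e.sign == "inhibitory"

    def test_mixed_role_bookkeeping(self):
        edges = [
            ConnectivityEdge(0, 1, 0.5, 3.0, 0.001, Direction.A_TO_B),
            ConnectivityEdge(2, 0, 0.5, 3.0, 0.001, Direction.A_TO_B),
        ]
        g = _graph(edges)
        assert g.node_roles[0] == "mixed"

    def test_pattern_detection_direction_matters(self):
        fwd = _graph([ConnectivityEdge(0, 2, 0.8, 5.0, 1e-4, Direction.A_TO_B)])
        rev = _graph([ConnectivityEdge(0, 2, 0.8, 5.0, 1e-4, Direction.B_TO_A)])
        assert detect_pattern(fwd, "PFC", "TL")
        assert not detect_pattern(rev, "PFC", "TL")
        assert detect_pattern(rev, "TL", "PFC")

    def test_bidirectional_contains_forward_direction(self):
        g = _graph([ConnectivityEdge(0, 2, 0.8, 5.0, 1e-4, Direction.BIDIRECTIONAL)])
        assert detect_pattern(g, "PFC", "TL") and detect_pattern(g, "TL", "PFC")

    def test_undirected_edge_never_matches(self):
        g = _graph([ConnectivityEdge(0, 2, 0.8, 5.0, 1e-4, Direction.UNDIRECTED)])
        assert not detect_pattern(g, "PFC", "TL")

    def test_min_edges_threshold(self):
        edges = [ConnectivityEdge(0, 2, 0.8, 5.0, 1e-4, Direction.A_TO_B)]
        g = _graph(edges)
        assert not detect_pattern(g, "PFC", "TL", min_edges=2)

    def test_missing_labels_rejected(self):
        g = ConnectivityGraph(n_sources=2, edges=[])
        with pytest.raises(ValueError, match="labels"):
            detect_pattern(g)


class TestBuildGraph:
    def _vs(self, signals, labels):
        n = signals.shape[0]
        positions = np.column_stack([np.arange(n) * 0.05, np.zeros(n), np.zeros(n)])
        grid = SourceGrid(positions=positions, region_labels=labels)
        return VirtualSensorSet(signals=signals, grid=grid)

    def test_end_to_end_planted_edge(self):
        """A strongly coupled pair among independent sources yields exactly
        that edge, directed source -> sink."""
        coupling = np.zeros((1, 4, 4))
        np.fill_diagonal(coupling[0], 0.2)
        coupling[0, 2, 0] = 0.4
        cov = np.eye(4)
        cov[0, 2] = cov[2, 0] = 0.8
        spec = SourceNetworkSpec(
            4, coupling, cov, ("PFC", "PFC", "TL", "OTHER")
        )
        x = simulate_mvar(spec, 3000, seed=1)
        g = build_graph(self._vs(x, spec.region_labels), model_order_max=4)
        pairs = {(e.a, e.b) for e in g.edges}
        assert (0, 2) in pairs
        edge = next(e for e in g.edges if (e.a, e.b) == (0, 2))
        assert edge.direction in (Direction.A_TO_B, Direction.BIDIRECTIONAL)
        assert edge.sign == "excitatory"
        assert detect_pattern(g)

    def test_relabeling_equivariance(self, rng):
        """Permuting source order permutes the graph but not its content."""
        coupling = np.zeros((1, 4, 4))
        np.fill_diagonal(coupling[0], 0.2)
        cov = np.eye(4)
        cov[0, 3] = cov[3, 0] = 0.9
        labels = ("PFC", "OCC", "OTHER", "TL")
        spec = SourceNetworkSpec(4, coupling, cov, labels)
        x = simulate_mvar(spec, 2000, seed=8)
        perm = np.array([2, 0, 3, 1])
        g1 = build_graph(self._vs(x, labels), model_order_max=3)
        g2 = build_graph(
            self._vs(x[perm], tuple(labels[i] for i in perm)), model_order_max=3
        )
        inv = np.argsort(perm)
        edges1 = {tuple(sorted((e.a, e.b))): round(e.R, 10) for e in g1.edges}
        edges2 = {
            tuple(sorted((int(perm[e.a]), int(perm[e.b])))): round(e.R, 10)
            for e in g2.edges
        }
        assert edges1 == edges2
        del inv
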
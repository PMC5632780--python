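"""BIC scoring, hill climbing and bootstrap averaging for the DAG branch."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import symptomnet as sn
from symptomnet.bayesnet import (
    CyclicGraphError,
    GaussianBicScorer,
    _find_cycle,
    sn_optimal_t,
)
from symptomnet.simulate import topological_order


def gaussian_node_loglik(y, X):
    """Independent OLS route: maximized log-likelihood of y | X."""
    Z = np.column_stack([np.ones(len(y))] + ([X] if X is not None else []))
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    s2 = np.mean(resid**2)
    n = len(y)
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1)


def all_three_node_dags():
    """All 25 DAGs on 3 labelled nodes."""
    dags = []
    pairs = [(0, 1), (0, 2), (1, 2)]
    for states in itertools.product([0, 1, 2], repeat=3):  # none, i->j, j->i
        A = np.zeros((3, 3), bool)
        for (i, j), s in zip(pairs, states):
            if s == 1:
                A[i, j] = True
            elif s == 2:
                A[j, i] = True
        if topological_order(A) is not None:
            dags.append(A)
    assert len(dags) == 25
    return dags


class TestBicScore:
    def test_two_variable_fixture_assembled_by_hand(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = 0.8 * x + rng.normal(size=10)
        data = np.column_stack([x, y])
        n = 10
        # empty graph: two marginal Gaussians, k = 2 each
        expected_empty = (
            gaussian_node_loglik(x, None) - 1.0 * np.log(n)
            + gaussian_node_loglik(y, None) - 1.0 * np.log(n)
        )
        A = np.zeros((2, 2), bool)
        assert sn.bic_score(A, data) == pytest.approx(expected_empty, rel=1e-10)
        # x -> y: child gains a parent, k = 3 for the child
        A[0, 1] = True
        expected_edge = (
            gaussian_node_loglik(x, None) - 1.0 * np.log(n)
            + gaussian_node_loglik(y, x[:, None]) - 1.5 * np.log(n)
        )
        assert sn.bic_score(A, data) == pytest.approx(expected_edge, rel=1e-10)

    def test_decomposability_edge_touches_only_child(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(50, 4))
        scorer = GaussianBicScorer(data)
        A = np.zeros((4, 4), bool)
        base = [scorer.node_score(j, frozenset()) for j in range(4)]
        A[0, 2] = True
        for j in range(4):
            pa = frozenset(np.nonzero(A[:, j])[0].tolist())
            if j == 2:
                assert scorer.node_score(j, pa) != base[j]
            else:
                assert scorer.node_score(j, pa) == base[j]

    def test_markov_equivalent_orientations_tie(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y = 2.0 * x + rng.normal(size=500)
        data = np.column_stack([x, y])
        fwd = np.array([[0, 1], [0, 0]], bool)
        bwd = fwd.T
        empty = np.zeros((2, 2), bool)
        assert sn.bic_score(fwd, data) == pytest.approx(
            sn.bic_score(bwd, data), abs=1e-6
        )
        assert sn.bic_score(fwd, data) > sn.bic_score(empty, data)

    def test_cyclic_graph_rejected(self):
        A = np.array([[0, 1], [1, 0]], bool)
        with pytest.raises(CyclicGraphError):
            sn.bic_score(A, np.random.default_rng(0).normal(size=(20, 2)))


class TestHillClimb:
    def test_independent_columns_give_empty_graph(self):
        rng = np.random.default_rng(3)
        adj = sn.hill_climb(rng.normal(size=(1000, 5)), sn.SearchConfig(seed=1))
        assert adj.sum() == 0

    def test_chain_recovers_skeleton_without_shortcut(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=1000)
        y = 1.2 * x + rng.normal(size=1000)
        z = 1.2 * y + rng.normal(size=1000)
        adj = sn.hill_climb(np.column_stack([x, y, z]), sn.SearchConfig(seed=1))
        skel = adj | adj.T
        assert skel[0, 1] and skel[1, 2] and not skel[0, 2]

    def test_finds_exhaustive_optimum_on_three_nodes(self):
        dags = all_three_node_dags()
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            B = np.triu(rng.uniform(-1, 1, (3, 3)) * (rng.random((3, 3)) < 0.5), 1)
            e = rng.normal(size=(500, 3))
            X = np.zeros((500, 3))
            for j in range(3):
                X[:, j] = X @ B[:, j] + e[:, j]
            scorer = GaussianBicScorer(X)
            best = max(sn.bic_score(A, scorer) for A in dags)
            found = sn.bic_score(
                sn.hill_climb(X, sn.SearchConfig(restarts=5, seed=seed)), scorer
            )
            if found >= best - 1e-9:
                hits += 1
        assert hits >= 95

    def test_deterministic_under_seed(self):
        ds, _ = sn.csa_ptsd_preset(seed=5, n=120, n_missing_rows=0)
        a = sn.hill_climb(ds.values, sn.SearchConfig(restarts=3, seed=9))
        b = sn.hill_climb(ds.values, sn.SearchConfig(restarts=3, seed=9))
        np.testing.assert_array_equal(a, b)

    def test_output_always_acyclic(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            adj = sn.hill_climb(rng.normal(size=(200, 6)) +
                                rng.normal(size=(200, 1)),
                                sn.SearchConfig(restarts=3, seed=seed))
            assert topological_order(adj) is not None


class TestBootstrapDags:
    def test_single_bootstrap_strengths_binary(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = x + 0.5 * rng.normal(size=300)
        s, d = sn.bootstrap_dags(np.column_stack([x, y]),
                                 sn.SearchConfig(B=1, seed=1))
        assert set(s.values()) <= {0.0, 1.0}

    def test_accounting_identity(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(200, 3))
        data[:, 1] += data[:, 0]
        cfg = sn.SearchConfig(B=50, seed=2)
        s, d = sn.bootstrap_dags(data, cfg)
        for (a, b), frac in s.items():
            total = d.get((a, b), 0) + d.get((b, a), 0)
            assert total == pytest.approx(frac * cfg.B)

    def test_strong_dependence_has_high_strength(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=500)
        y = x + 0.4 * rng.normal(size=500)
        s, _ = sn.bootstrap_dags(np.column_stack([x, y]),
                                 sn.SearchConfig(B=200, seed=3))
        assert s.get((0, 1), 0.0) >= 0.95


class TestSnThreshold:
    def test_all_ones_retain_everything(self):
        cut, t = sn.sn_threshold([1.0, 1.0, 1.0])
        assert t == 0.0
        model = sn.averaged_network(
            {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0},
            {(0, 1): 10, (0, 2): 10, (2, 1): 10},
            sn.SearchConfig(B=10), ["a", "b", "c"],
        )
        assert model.n_edges == 3

    def test_all_zeros_retain_nothing(self):
        cut, t = sn.sn_threshold([0.0, 0.0])
        model = sn.averaged_network(
            {(0, 1): 0.0, (1, 2): 0.0}, {}, sn.SearchConfig(B=10), ["a", "b", "c"]
        )
        assert model.n_edges == 0

    def test_half_and_half_keeps_strength_one_edges(self):
        cut, t = sn.sn_threshold([1, 1, 1, 0, 0, 0])
        assert t == pytest.approx(0.5)
        assert cut == pytest.approx(0.5)
        strengths = {(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0,
                     (1, 2): 0.0, (1, 3): 0.0, (2, 3): 0.0}
        dirs = {(0, 1): 10, (0, 2): 10, (0, 3): 10}
        model = sn.averaged_network(strengths, dirs, sn.SearchConfig(B=10),
                                    ["a", "b", "c", "d"])
        assert model.edge_pairs() == {("a", "b"), ("a", "c"), ("a", "d")}

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_t_star_matches_dense_grid_oracle(self, strengths):
        s = np.asarray(strengths)
        t_star = sn_optimal_t(s)
        # numerically integrate the L1 distance on a fine x grid
        xs = np.linspace(0, 1, 2001)[:-1]
        Fhat = np.searchsorted(np.sort(s), xs, side="right") / s.size
        grid = np.linspace(0, 1, 1001)
        dists = [np.mean(np.abs(Fhat - t)) for t in grid]
        best = min(dists)
        mine = np.mean(np.abs(Fhat - t_star))
        assert mine <= best + 1e-3


class TestAveragedNetwork:
    def test_direction_probability_from_counts(self):
        s = {(0, 1): 1.0}
        model = sn.averaged_network(s, {(0, 1): 9950, (1, 0): 50},
                                    sn.SearchConfig(B=10_000), ["x", "y"])
        assert model.direction_prob[(0, 1)] == pytest.approx(0.995)
        weak = sn.averaged_network(s, {(0, 1): 5500, (1, 0): 4500},
                                   sn.SearchConfig(B=10_000), ["x", "y"])
        assert weak.direction_prob[(0, 1)] == pytest.approx(0.55)

    def test_exact_tie_broken_lexicographically_and_flagged(self):
        model = sn.averaged_network({(0, 1): 1.0}, {(0, 1): 50, (1, 0): 50},
                                    sn.SearchConfig(B=100), ["beta", "alpha"])
        # labels sort alpha < beta, so the edge runs alpha -> beta (1 -> 0)
        assert model.adjacency[1, 0]
        assert model.tie_breaks == [(1, 0)]

    def test_cycle_repair_produces_acyclic_graph(self):
        strengths = {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0}
        dirs = {(0, 1): 90, (1, 0): 10, (1, 2): 80, (2, 1): 20,
                (2, 0): 60, (0, 2): 40}
        model = sn.averaged_network(strengths, dirs, sn.SearchConfig(B=100),
                                    ["a", "b", "c"])
        assert _find_cycle(model.adjacency) is None
        assert len(model.repairs) >= 1

    def test_v_structure_orientation_recovered(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        z = x + y + 0.8 * rng.normal(size=n)
        cfg = sn.SearchConfig(B=200, seed=4)
        s, d = sn.bootstrap_dags(np.column_stack([x, y, z]), cfg)
        model = sn.averaged_network(s, d, cfg, ["x", "y", "z"])
        assert model.adjacency[0, 2] and model.adjacency[1, 2]
        assert model.direction_prob[(0, 2)] > 0.51
        assert model.direction_prob[(1, 2)] > 0.51

    def test_two_node_direction_unidentifiable(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=800)
        y = x + 0.7 * rng.normal(size=800)
        cfg = sn.SearchConfig(B=200, seed=5)
        s, d = sn.bootstrap_dags(np.column_stack([x, y]), cfg)
        model = sn.averaged_network(s, d, cfg, ["x", "y"])
        (edge,) = model.edges()
        # orientation hovers near chance for a Markov-equivalent pair
        assert 0.5 <= model.direction_prob[edge] <= 0.85


class TestEdgeBicImportance:
    def test_strong_edge_is_costly_null_edge_is_cheap(self):
        rng = np.random.default_rng(10)
        n = 2000
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # no true link to x or y
        data = np.column_stack([x, y, z])
        adj = np.zeros((3, 3), bool)
        adj[0, 1] = adj[0, 2] = True
        model = sn.DirectedModel(adj, ["x", "y", "z"],
                                 {(0, 1): 1.0, (0, 2): 0.6},
                                 {(0, 1): 0.9, (0, 2): 0.6}, threshold=0.5)
        imp = sn.edge_bic_importance(model, data)
        assert imp[(0, 1)] > 100
        # a null edge's removal only recoups (roughly) the k log n penalty
        assert imp[(0, 2)] < 3 * np.log(n)

    def test_absent_pair_is_an_error(self):
        adj = np.zeros((2, 2), bool)
        adj[0, 1] = True
        model = sn.DirectedModel(adj, ["x", "y"], {(0, 1): 1.0},
                                 {(0, 1): 1.0}, threshold=0.5)
        rng = np.random.default_rng(11)
        sn.edge_bic_importance(model, rng.normal(size=(50, 2)))
        with pytest.raises(KeyError):
            model.edge_bic[(1, 0)]
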
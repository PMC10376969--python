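"""Ground-truth graph generation and cohort simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import effconn as ec
from effconn.simulate import BURN_IN, StabilityError


class TestMakeGraph:
    def test_two_node_reciprocal_pair_is_unique(self):
        g = ec.make_graph(2, 2, 1, seed=0)
        np.testing.assert_array_equal(g.adjacency, [[0, 1], [1, 0]])

    def test_saturated_three_node_graph(self):
        g = ec.make_graph(3, 6, 3, seed=0)
        np.testing.assert_array_equal(g.adjacency, 1 - np.eye(3, dtype=int))

    def test_benchmark_shape_five_nodes_five_arcs(self):
        g = ec.make_graph(5, 5, 0, seed=42)
        assert g.n_arcs == 5
        assert np.trace(g.adjacency) == 0
        # no reciprocal pairs requested
        assert np.sum((g.adjacency == 1) & (g.adjacency.T == 1)) == 0

    def test_deterministic_for_fixed_seed(self):
        a = ec.make_graph(7, 10, 2, seed=9).adjacency
        b = ec.make_graph(7, 10, 2, seed=9).adjacency
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "n, arcs, bidir",
        [(3, 7, 0), (5, 4, 3), (3, 5, 1)],
    )
    def test_infeasible_counts_rejected(self, n, arcs, bidir):
        with pytest.raises(ValueError):
            ec.make_graph(n, arcs, bidir, seed=0)

    @given(
        n=st.integers(3, 8),
        extra=st.integers(0, 4),
        bidir=st.integers(0, 2),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=30, deadline=None)
    def test_counts_and_connectivity_hold(self, n, extra, bidir, seed):
        arcs = n - 1 + extra
        if arcs - 2 * bidir < 0 or bidir + (arcs - 2 * bidir) > n * (n - 1) // 2:
            return
        g = ec.make_graph(n, arcs, bidir, seed)
        assert g.n_arcs == arcs
        recip = np.sum((g.adjacency == 1) & (g.adjacency.T == 1)) // 2
        assert recip == bidir
        if arcs - bidir < n - 1:
            return  # too few touched pairs to span the nodes
        und = (g.adjacency + g.adjacency.T) > 0
        # weakly connected: BFS reaches every node
        seen = {0}
        frontier = [0]
        while frontier:
            i = frontier.pop()
            for j in np.flatnonzero(und[i]):
                if j not in seen:
                    seen.add(int(j))
                    frontier.append(int(j))
        assert len(seen) == n


class TestSimulateSubject:
    def test_unforced_linear_system_stays_at_rest(self):
        g = ec.make_graph(4, 4, 0, seed=1)
        opts = ec.SimOptions(noise_sd=0.0)
        x = ec.simulate_subject(g, 50, opts, seed=0)
        np.testing.assert_array_equal(x, np.zeros((4, 50)))

    def test_two_node_chain_matches_stepwise_recursion(self):
        """Node 2 = a * node 1 lagged by one, computed by a direct oracle."""
        g = ec.GroundTruthGraph(np.array([[0, 1], [0, 0]]))
        a = 0.7
        opts = ec.SimOptions(coupling_strength=a, noise_sd=[1.0, 0.0])
        x = ec.simulate_subject(g, 80, opts, seed=5)
        np.testing.assert_allclose(x[1, 1:], a * x[0, :-1], atol=1e-12)
        # oracle: replay the recursion from the same noise stream
        rng = np.random.default_rng(5)
        noise = rng.normal(size=(80 + BURN_IN, 2)) * np.array([1.0, 0.0])
        ref = np.zeros((80 + BURN_IN, 2))
        for t in range(1, 80 + BURN_IN):
            ref[t, 1] = a * ref[t - 1, 0]
            ref[t] += noise[t]
        ref[0] += noise[0]
        np.testing.assert_allclose(x, ref[BURN_IN:].T, atol=1e-12)

    def test_unstable_coupling_rejected(self):
        g = ec.GroundTruthGraph(np.array([[0, 1], [1, 0]]))
        with pytest.raises(StabilityError):
            ec.simulate_subject(g, 50, ec.SimOptions(coupling_strength=1.2), seed=0)

    def test_options_change_output(self):
        g = ec.make_stable_graph(5, 5, 0, 0.5, seed=2)
        base = ec.SimOptions(coupling_strength=0.5)
        x0 = ec.simulate_subject(g, 60, base, seed=3)
        for kw in ({"nonlinear": True}, {"shared_input": True},
                   {"global_confound": True}, {"hrf_smoothing": True}):
            opts = ec.SimOptions(coupling_strength=0.5, **kw)
            x1 = ec.simulate_subject(g, 60, opts, seed=3)
            assert x1.shape == (5, 60)
            assert not np.allclose(x0, x1)


class TestSimulateCohort:
    def test_benchmark_cohort_shape(self):
        g = ec.make_stable_graph(5, 5, 0, 0.5, seed=0)
        cohort, truths = ec.simulate_cohort(
            g, 50, 200, ec.SimOptions(subject_graph_flip_prob=0.0), seed=0
        )
        assert cohort.data.shape == (50, 5, 200)
        assert len(truths) == 50

    def test_zero_flip_prob_keeps_base_graph(self):
        g = ec.make_stable_graph(5, 5, 0, 0.5, seed=1)
        _, truths = ec.simulate_cohort(
            g, 8, 50, ec.SimOptions(subject_graph_flip_prob=0.0), seed=1
        )
        for t in truths:
            np.testing.assert_array_equal(t.adjacency, g.adjacency)

    def test_bitwise_determinism(self):
        g = ec.make_stable_graph(5, 6, 1, 0.5, seed=2)
        opts = ec.SimOptions(subject_graph_flip_prob=0.1, shared_input=True)
        c1, t1 = ec.simulate_cohort(g, 4, 60, opts, seed=7)
        c2, t2 = ec.simulate_cohort(g, 4, 60, opts, seed=7)
        np.testing.assert_array_equal(c1.data, c2.data)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.adjacency, b.adjacency)

    def test_flipped_subject_graphs_stay_near_base(self):
        g = ec.make_stable_graph(6, 7, 0, 0.4, seed=3)
        _, truths = ec.simulate_cohort(
            g, 20, 40, ec.SimOptions(coupling_strength=0.4, subject_graph_flip_prob=0.05),
            seed=3,
        )
        diffs = [np.sum(t.adjacency != g.adjacency) for t in truths]
        assert np.mean(diffs) < 6  # 30 off-diagonal slots * 0.05 = 1.5 expected


def test_variance_stationary_under_linear_dynamics():
    """Late-window variance is insensitive to doubling the series length."""
    ratios = []
    for seed in range(10):
        g = ec.make_stable_graph(5, 5, 0, 0.5, seed=seed)
        opts = ec.SimOptions(coupling_strength=0.5, noise_sd=1.0,
                             subject_graph_flip_prob=0.0)
        short = ec.simulate_subject(g, 200, opts, seed=seed)
        long = ec.simulate_subject(g, 400, opts, seed=seed + 1000)
        v_short = short[:, 100:].var(axis=1)
        v_long = long[:, 200:].var(axis=1)
        ratios.append(np.median(np.abs(v_long - v_short) / v_short))
    assert np.median(ratios) < 0.5


def test_lagged_regression_separates_arcs_from_non_arcs():
    """Pairwise lagged least squares (independent oracle) ranks true arcs first."""
    g = ec.make_stable_graph(5, 5, 0, 0.8, seed=4)
    opts = ec.SimOptions(coupling_strength=0.8, noise_sd=0.1,
                         subject_graph_flip_prob=0.0)
    x = ec.simulate_subject(g, 2000, opts, seed=4)
    coefs = {}
    for i in range(5):
        for j in range(5):
            if i == j:
                continue
            xi, xj = x[i, :-1], x[j, 1:]
            design = np.column_stack([xi, np.ones_like(xi)])
            beta, *_ = np.linalg.lstsq(design, xj, rcond=None)
            coefs[(i, j)] = abs(beta[0])
    arcs = set(map(tuple, np.argwhere(g.adjacency == 1)))
    wins = total = 0
    for arc in arcs:
        for other, c in coefs.items():
            if other in arcs:
                continue
            total += 1
            wins += coefs[arc] > c
    assert wins / total >= 0.9
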
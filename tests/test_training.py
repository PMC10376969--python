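"""Objective terms, amortized training, adaptation, and binarization."""

import numpy as np
import pytest

import effconn as ec
from effconn.model import DecoderConfig, EncoderConfig
from effconn.training import DivergenceError

TINY_ENC = EncoderConfig(n_layers=1, n_heads=2, hidden_dim=16)
TINY_DEC = DecoderConfig(hidden_dim=4)


def _uniform_graph(n):
    w = np.full((n, n), 1.0 / (n - 1))
    np.fill_diagonal(w, 0.0)
    return ec.ECGraph(w, normalized=True)


class TestElboLoss:
    def test_zero_for_perfect_fit_and_uniform_rows(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 4, 20))
        cfg = ec.TrainingConfig()
        loss = ec.elbo_loss(x, x[..., 5:], [_uniform_graph(4)] * 2, cfg)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_kl_of_concentrated_row_matches_direct_sum(self):
        # off-diagonal row [0.8, 0.2] against uniform [0.5, 0.5]
        w = np.array(
            [[0.0, 0.8, 0.2], [0.2, 0.0, 0.8], [0.8, 0.2, 0.0]]
        )
        g = ec.ECGraph(w, normalized=True)
        x = np.zeros((1, 3, 10))
        loss = ec.elbo_loss(x, x[..., 5:], [g], ec.TrainingConfig())
        kl_row = 0.8 * np.log(1.6) + 0.2 * np.log(0.4)  # = 0.19274...
        assert loss == pytest.approx(3 * kl_row, abs=1e-10)
        assert kl_row == pytest.approx(0.19274, abs=1e-5)

    def test_likelihood_sd_scales_reconstruction_quadratically(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 3, 20))
        x_hat = rng.normal(size=(1, 3, 15))
        g = [_uniform_graph(3)]
        l1 = ec.elbo_loss(x, x_hat, g, ec.TrainingConfig(likelihood_sd=1.0))
        l2 = ec.elbo_loss(x, x_hat, g, ec.TrainingConfig(likelihood_sd=2.0))
        assert l1 == pytest.approx(4.0 * l2, rel=1e-12)

    def test_misaligned_reconstruction_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            ec.elbo_loss(
                np.zeros((1, 3, 10)), np.zeros((1, 3, 12)), [_uniform_graph(3)],
                ec.TrainingConfig(),
            )


class TestSparsityPenalty:
    def test_zero_graph_and_zero_weight(self):
        zero = ec.ECGraph(np.zeros((4, 4)))
        assert ec.sparsity_penalty([zero], 1.0) == 0.0
        assert ec.sparsity_penalty([_uniform_graph(4)], 0.0) == 0.0

    def test_row_stochastic_graph_sums_to_n(self):
        assert ec.sparsity_penalty([_uniform_graph(5)], 1.0) == pytest.approx(5.0)


@pytest.fixture(scope="module")
def trained(small_cohort):
    cohort, _ = small_cohort
    cfg = ec.TrainingConfig(seed=3, epochs=40)
    return ec.train_amortized(cohort.zscore(), cfg, TINY_ENC, TINY_DEC)


@pytest.fixture(scope="module")
def adapted_base(small_cohort):
    cohort, _ = small_cohort
    cfg = ec.TrainingConfig(seed=5, epochs=40)
    state, _ = ec.train_amortized(cohort.zscore(), cfg, TINY_ENC, TINY_DEC)
    return state, cfg


class TestTrainAmortized:
    def test_loss_trace_full_length_and_finite(self, trained):
        _, report = trained
        assert len(report.loss_trace) == 40
        assert np.isfinite(report.loss_trace).all()

    def test_loss_decreases(self, trained):
        _, report = trained
        assert report.loss_trace[-1] < report.loss_trace[0]

    def test_returns_one_graph_per_subject(self, trained, small_cohort):
        cohort, _ = small_cohort
        _, report = trained
        assert len(report.graphs) == cohort.n_subjects
        for g in report.graphs:
            np.testing.assert_allclose(g.weights.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic_rerun(self, small_cohort, trained):
        cohort, _ = small_cohort
        cfg = ec.TrainingConfig(seed=3, epochs=40)
        _, report2 = ec.train_amortized(cohort.zscore(), cfg, TINY_ENC, TINY_DEC)
        _, report1 = trained
        assert report1.loss_trace == report2.loss_trace
        for a, b in zip(report1.graphs, report2.graphs):
            np.testing.assert_array_equal(a.weights, b.weights)


class TestAdaptSubject:
    def test_zero_epochs_is_zero_shot_encoding(self, adapted_base, small_cohort):
        state, cfg = adapted_base
        cohort, _ = small_cohort
        x = cohort.zscore().subject(0)
        g0 = ec.adapt_subject(
            state, x, ec.TrainingConfig(seed=5, adapt_epochs=0)
        )
        np.testing.assert_array_equal(
            g0.weights, state.model.encode_subject(x).weights
        )

    def test_original_state_unmodified(self, adapted_base, small_cohort):
        state, cfg = adapted_base
        cohort, _ = small_cohort
        before = [p.data.copy() for p in state.model.parameters()]
        ec.adapt_subject(state, cohort.zscore().subject(1), cfg)
        for b, p in zip(before, state.model.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_deterministic(self, adapted_base, small_cohort):
        state, cfg = adapted_base
        x = small_cohort[0].zscore().subject(2)
        g1 = ec.adapt_subject(state, x, cfg)
        g2 = ec.adapt_subject(state, x, cfg)
        np.testing.assert_array_equal(g1.weights, g2.weights)

    def test_region_count_mismatch_rejected(self, adapted_base):
        state, cfg = adapted_base
        with pytest.raises(ValueError, match="regions"):
            ec.adapt_subject(state, np.zeros((7, 40)), cfg)

    def test_time_length_mismatch_rejected(self, adapted_base):
        state, cfg = adapted_base
        with pytest.raises(ValueError, match="t="):
            ec.adapt_subject(state, np.zeros((5, 55)), cfg)

    def test_training_subject_moves_less_than_novel(self, small_cohort):
        """Adaptation barely shifts a subject the model already fits."""
        changes_seen, changes_novel = [], []
        for seed in (0, 1, 2):
            graph = ec.make_stable_graph(5, 5, 0, 0.6, seed=seed)
            opts = ec.SimOptions(
                coupling_strength=0.6, noise_sd=0.5, subject_graph_flip_prob=0.0
            )
            cohort, _ = ec.simulate_cohort(graph, 6, 60, opts, seed=seed)
            z = cohort.zscore()
            cfg = ec.TrainingConfig(seed=seed, epochs=60)
            state, _ = ec.train_amortized(
                ec.CohortTimeSeries(z.data[:5]), cfg, TINY_ENC, TINY_DEC
            )
            for s, bucket in ((0, changes_seen), (5, changes_novel)):
                x = z.data[s]
                zero = state.model.encode_subject(x).weights
                adapted = ec.adapt_subject(state, x, cfg).weights
                bucket.append(np.abs(adapted - zero).sum())
        assert np.median(changes_seen) < np.median(changes_novel)


class TestBinarize:
    def test_threshold_selects_dominant_target(self):
        w = np.array(
            [[0.0, 0.6, 0.25, 0.15],
             [0.6, 0.0, 0.25, 0.15],
             [0.25, 0.6, 0.0, 0.15],
             [0.25, 0.15, 0.6, 0.0]]
        )
        b = ec.binarize(ec.ECGraph(w, normalized=True), 0.3)
        np.testing.assert_array_equal(b, (w > 0.3).astype(int))
        assert b.sum() == 4

    def test_threshold_above_max_empties_graph(self):
        g = _uniform_graph(4)
        assert ec.binarize(g, 0.99).sum() == 0

    def test_zero_threshold_keeps_all_positive_arcs(self):
        g = _uniform_graph(4)
        b = ec.binarize(g, 0.0)
        assert b.sum() == 12 and np.trace(b) == 0


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_divergence_error_names_epoch():
    with pytest.raises(DivergenceError, match="epoch"):
        # a cohort with astronomically large values overflows the squared
        # residuals in the very first epochs
        data = np.full((1, 3, 30), 1e200)
        data[:, :, ::2] = -1e200
        cohort = ec.CohortTimeSeries(data)
        ec.train_amortized(
            cohort, ec.TrainingConfig(seed=0, epochs=3), TINY_ENC, TINY_DEC
        )
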
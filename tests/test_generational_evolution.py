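"""Mutation-selection engine: Fermi weights, resampling, mutation, generations."""

import numpy as np
import pytest

from synchrolek.binary_evolution import (
    BinaryPopulation,
    PayoffTriple,
    SelectionParams,
    replicator_step,
)
from synchrolek.generational_evolution import (
    EvolutionConfig,
    GenerationSummary,
    MutationParams,
    RandomStreams,
    apply_mutation,
    classify_outcome,
    detect_extinction,
    fermi_weights,
    lag_bin_edges,
    lag_mean_trend,
    run_evolution,
    run_generation,
    sample_offspring,
)

PI = np.pi


class TestFermiWeights:
    def test_equal_payoffs_give_uniform_probabilities(self):
        w = fermi_weights(np.full(8, 1.3))
        assert np.allclose(w, 1.0 / 8.0, atol=1e-14)

    def test_log_two_gap_gives_one_third_two_thirds(self):
        w = fermi_weights([0.0, np.log(2.0)])
        assert np.allclose(w, [1.0 / 3.0, 2.0 / 3.0], atol=1e-12)

    def test_shift_invariance(self, rng):
        p = rng.normal(0, 1, 30)
        assert np.allclose(fermi_weights(p), fermi_weights(p + 17.3), atol=1e-12)

    def test_large_payoffs_do_not_overflow(self):
        w = fermi_weights([1000.0, 1001.0])
        assert np.isfinite(w).all()
        assert w.sum() == pytest.approx(1.0)

    def test_non_finite_payoffs_rejected(self):
        with pytest.raises(ValueError):
            fermi_weights([0.0, np.nan])


class TestSampleOffspring:
    def test_degenerate_probabilities_clone_one_parent(self, rng):
        lags = np.array([0.1, 0.2, 0.3])
        prob = np.array([0.0, 1.0, 0.0])
        assert np.all(sample_offspring(lags, prob, rng) == 0.2)

    def test_uniform_sampling_preserves_mean(self, rng):
        n = 4000
        lags = rng.normal(0.5, 0.2, n)
        child = sample_offspring(lags, np.full(n, 1.0 / n), rng)
        se = lags.std() / np.sqrt(n)
        assert abs(child.mean() - lags.mean()) < 3 * se

    def test_seeded_replay_is_identical(self):
        lags = np.linspace(-1, 1, 50)
        prob = np.full(50, 0.02)
        a = sample_offspring(lags, prob, np.random.default_rng(3))
        b = sample_offspring(lags, prob, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_invalid_probabilities_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_offspring(np.zeros(3), np.array([0.5, 0.5, 0.5]), rng)


class TestApplyMutation:
    def test_zero_fraction_is_identity(self, rng):
        lags = rng.uniform(-1, 1, 40)
        out = apply_mutation(lags, MutationParams(0.0, 0.05), rng)
        assert np.array_equal(out, lags)

    def test_zero_scale_is_identity(self, rng):
        lags = rng.uniform(-1, 1, 40)
        out = apply_mutation(lags, MutationParams(0.1, 0.0), rng)
        assert np.array_equal(out, lags)

    def test_exact_subset_size(self, rng):
        lags = np.zeros(200)
        out = apply_mutation(lags, MutationParams(0.1, 0.05), rng)
        assert (out != lags).sum() == 20

    def test_outputs_wrapped(self, rng):
        lags = np.full(100, PI - 1e-4)
        out = apply_mutation(lags, MutationParams(1.0, 0.5), rng)
        assert np.all(out > -PI) and np.all(out <= PI)


class TestRunGeneration:
    CFG = EvolutionConfig(
        population_size=60,
        generations=5,
        strategy_kind="strong_policing",
        mutation=MutationParams(0.0, 0.0),
        seed=5,
    )

    def test_identical_lags_without_mutation_are_a_fixed_point(self):
        streams = RandomStreams.from_seed(5)
        lags = np.full(60, 0.3)
        summary, nxt = run_generation(lags, self.CFG, streams)
        assert np.array_equal(nxt, lags)
        # exchangeable individuals: payoffs equal up to integrator tolerance
        assert np.ptp(summary.payoffs) < 1e-6
        assert summary.mean_R > 0.999

    def test_seeded_replay_reproduces_summary(self):
        cfg = EvolutionConfig(population_size=50, generations=3, seed=9)
        lags = np.linspace(-0.3, 0.3, 50)
        s1, n1 = run_generation(lags, cfg, RandomStreams.from_seed(9))
        s2, n2 = run_generation(lags, cfg, RandomStreams.from_seed(9))
        assert np.array_equal(n1, n2)
        assert s1.mean_R == s2.mean_R
        assert np.array_equal(s1.payoffs, s2.payoffs)
        assert np.array_equal(s1.lag_histogram, s2.lag_histogram)

    def test_population_size_constant_and_histogram_sums(self):
        cfg = EvolutionConfig(population_size=40, generations=4, seed=2)
        summaries = run_evolution(cfg)
        for s in summaries:
            assert s.lag_histogram.sum() == 40
            assert s.payoffs.size == 40


class TestReplicatorConsistency:
    def test_fermi_sampling_matches_replicator_to_first_order(self):
        # With two lag values, no mutation and weak selection, the expected
        # offspring fractions from softmax selection + multinomial sampling
        # agree with one discrete replicator step (k1 = 1) to first order
        # in the payoff difference.
        n, n_ch = 500, 0.3
        eps = 0.02  # payoff gap; first-order error is O(eps^2)
        payoffs = np.r_[np.zeros(350), np.full(150, eps)]
        lags = np.r_[np.zeros(350), np.full(150, 1.0)]
        w = fermi_weights(payoffs)
        rng = np.random.default_rng(77)
        sampled = np.mean(
            [(sample_offspring(lags, w, rng) != 0).mean() for _ in range(1000)]
        )
        pbar = 0.7 * 0.0 + 0.3 * eps
        stepped = replicator_step(
            BinaryPopulation(0.7, 0.3, 0.0, 1.0),
            PayoffTriple(0.0, eps, pbar),
            SelectionParams(selection_strength=1.0),
        )
        # tolerance: 3 standard errors of the replicate mean + O(eps^2)
        se = np.sqrt(n_ch * (1 - n_ch) / n) / np.sqrt(1000)
        assert abs(sampled - stepped.frac_cheaters) < 3 * se + eps**2


class TestExtinctionAndClassification:
    def _summary(self, mean_r, hist=None, lag_mean=0.0):
        return GenerationSummary(
            0, hist if hist is not None else np.zeros(126, int),
            mean_r, np.zeros(4), lag_mean=lag_mean,
        )

    CFG = EvolutionConfig(population_size=200, generations=100,
                          extinction_R_threshold=0.2, extinction_patience=5)

    def test_healthy_runs_are_not_extinct(self):
        summaries = [self._summary(0.95) for _ in range(30)]
        assert not detect_extinction(summaries, self.CFG)

    def test_patience_window_triggers_extinction(self):
        summaries = [self._summary(0.9)] * 10 + [self._summary(0.05)] * 5
        assert detect_extinction(summaries, self.CFG)

    def test_recovery_resets_the_clock(self):
        summaries = [self._summary(0.05)] * 4 + [self._summary(0.9)]
        assert not detect_extinction(summaries, self.CFG)

    def test_bimodal_histogram_classified_as_split(self):
        edges = lag_bin_edges()
        hist = np.histogram(
            np.r_[np.random.default_rng(0).normal(-PI / 4, 0.08, 100),
                  np.random.default_rng(1).normal(PI / 4, 0.08, 100)],
            bins=edges,
        )[0]
        summaries = [self._summary(0.7, hist=hist) for _ in range(30)]
        assert classify_outcome(summaries, self.CFG) == "stable_bimodal"

    def test_drifting_mean_classified_as_drift(self):
        summaries = [self._summary(0.9, lag_mean=0.01 * g) for g in range(60)]
        assert lag_mean_trend(summaries) == pytest.approx(0.01, abs=1e-9)
        assert classify_outcome(summaries, self.CFG) == "drifting"

    def test_drift_trend_unwraps_through_pi(self):
        # a mean walking through the +-pi seam is drift, not a jump
        summaries = [
            self._summary(0.9, lag_mean=float(np.angle(np.exp(1j * (3.0 + 0.01 * g)))))
            for g in range(60)
        ]
        assert lag_mean_trend(summaries) == pytest.approx(0.01, abs=1e-6)

    def test_tight_unimodal_run_classified_stable(self):
        edges = lag_bin_edges()
        hist = np.histogram(
            np.random.default_rng(0).normal(0.0, 0.05, 200), bins=edges
        )[0]
        summaries = [self._summary(0.99, hist=hist) for _ in range(30)]
        assert classify_outcome(summaries, self.CFG) == "stable_unimodal"


class TestRunEvolutionSmoke:
    def test_strong_policing_small_run_stays_synchronous(self):
        cfg = EvolutionConfig(
            population_size=50, generations=30,
            strategy_kind="strong_policing", initial_lag_mean=0.0, seed=4,
        )
        summaries = run_evolution(cfg)
        assert len(summaries) == 30
        assert summaries[-1].mean_R > 0.99
        assert classify_outcome(summaries, cfg) == "stable_unimodal"
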
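"""Harmonic HMM: exact-inference oracle, posteriors, center of rest, recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from circaphase.core import TimeSeries, ValidationError, circular_distance
from circaphase.rest_hmm import (HarmonicHMM, StateProbabilityProfile,
                                 _fb_python, center_of_rest, fit_harmonic_hmm,
                                 forward_backward, state_posteriors)
from circaphase.simulate import generate_chest_data, generate_cohort


def toy_chain(seed=0, T=12, K=3):
    rng = np.random.default_rng(seed)
    B = rng.uniform(0.1, 1.0, (T, K))
    A_all = rng.uniform(0.1, 1.0, (T, K, K))
    A_all /= A_all.sum(axis=2, keepdims=True)
    pi = rng.dirichlet(np.ones(K))
    return B, np.arange(T), A_all, pi


def enumerate_oracle(B, A_all, pi):
    """Exact posteriors by summing over all 3^T state paths."""
    T, K = B.shape
    gamma = np.zeros((T, K))
    xi = np.zeros((T, K, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = pi[path[0]] * B[0, path[0]]
        for t in range(1, T):
            p *= A_all[t, path[t - 1], path[t]] * B[t, path[t]]
        total += p
        for t in range(T):
            gamma[t, path[t]] += p
        for t in range(1, T):
            xi[t, path[t - 1], path[t]] += p
    return gamma / total, xi / total, np.log(total)


class TestForwardBackward:
    @pytest.mark.parametrize("kernel", [forward_backward, _fb_python])
    def test_matches_path_enumeration(self, kernel):
        B, A_idx, A_all, pi = toy_chain(seed=4)
        g_o, xi_o, ll_o = enumerate_oracle(B, A_all, pi)
        g, xi_agg, ll = kernel(B, A_idx, A_all, pi)
        assert np.abs(g - g_o).max() < 1e-9
        # A_idx == t, so xi_agg[t] is exactly the step-t expected transition
        assert np.abs(xi_agg[1:] - xi_o[1:]).max() < 1e-9
        assert ll == pytest.approx(ll_o, abs=1e-9)

    def test_missing_emissions_marginalised(self):
        B, A_idx, A_all, pi = toy_chain(seed=5)
        B[4] = 1.0  # a missing observation contributes no evidence
        g_o, _, _ = enumerate_oracle(B, A_all, pi)
        g, _, _ = forward_backward(B, A_idx, A_all, pi)
        assert np.abs(g - g_o).max() < 1e-9
        assert np.allclose(g.sum(axis=1), 1.0, atol=1e-12)

    def test_agrees_with_hmmlearn_on_homogeneous_chain(self):
        """Independent cross-check: with a single transition matrix our
        smoother must match hmmlearn's Gaussian HMM posteriors."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 300) + rng.choice([0.0, 3.0, 6.0], 300)
        means = np.array([0.0, 3.0, 6.0])
        sds = np.array([1.0, 1.0, 1.0])
        A = np.array([[0.9, 0.08, 0.02], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        pi = np.array([0.5, 0.3, 0.2])
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = pi
        ref.transmat_ = A
        ref.means_ = means[:, None]
        ref.covars_ = np.ones((3, 1))
        _, post = ref.score_samples(x[:, None])
        z = (x[:, None] - means) / sds
        B = np.exp(-0.5 * z**2) / (np.sqrt(2 * np.pi) * sds)
        g, _, ll = forward_backward(B, np.arange(300) % 1, A[None, :, :], pi)
        assert np.abs(g - post).max() < 1e-8
        assert ll == pytest.approx(ref.score(x[:, None]), abs=1e-6)


class TestCenterOfRest:
    @staticmethod
    def rect_profile(start_min, end_min):
        rest = np.zeros(1440)
        idx = np.arange(1440)
        if start_min <= end_min:
            rest[(idx >= start_min) & (idx < end_min)] = 1.0
        else:
            rest[(idx >= start_min) | (idx < end_min)] = 1.0
        probs = np.column_stack([rest, 1 - rest, np.zeros(1440)])
        return StateProbabilityProfile(np.arange(1440), probs)

    def test_rectangle_midpoint(self):
        cor = center_of_rest(self.rect_profile(0, 8 * 60))
        assert circular_distance(cor, 4.0) < 1.0 / 60.0

    def test_wrapping_rectangle(self):
        cor = center_of_rest(self.rect_profile(22 * 60, 6 * 60))
        assert circular_distance(cor, 2.0) < 1.0 / 60.0

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(2)
        rest = rng.uniform(0, 1, 1440)
        probs = np.column_stack([rest, (1 - rest) / 2, (1 - rest) / 2])
        prof = StateProbabilityProfile(np.arange(1440), probs)
        cor = center_of_rest(prof)
        theta = 2 * np.pi * (np.arange(1440) + 0.5) / 1440
        z = np.sum(rest * np.exp(1j * theta)) / rest.sum()
        oracle = (np.angle(z) % (2 * np.pi)) * 24 / (2 * np.pi)
        assert circular_distance(cor, oracle) < 1e-9

    def test_zero_profile_undefined(self):
        probs = np.column_stack([np.zeros(1440), np.ones(1440), np.zeros(1440)])
        with pytest.raises(ValidationError):
            center_of_rest(StateProbabilityProfile(np.arange(1440), probs))


class TestPosteriorProfile:
    def test_separable_emissions_give_hard_posteriors(self):
        model = HarmonicHMM(
            means=np.array([0.0, 4.0, 8.0]), sds=np.array([0.1, 0.1, 0.1]),
            startprob=np.array([1 / 3] * 3),
            baseline=np.log(np.array([[0.9, 0.05, 0.05],
                                      [0.05, 0.9, 0.05],
                                      [0.05, 0.05, 0.9]]) / 0.9),
            alpha=np.zeros((1, 3, 3)), beta=np.zeros((1, 3, 3)), n_harmonics=1)
        rng = np.random.default_rng(1)
        day = rng.integers(0, 3, 1440)
        states = np.tile(day, 2)                # day-periodic regimes
        counts = np.expm1(model.means[states])  # exactly on the state means
        idx = pd.date_range("2024-01-01", periods=counts.size, freq="min")
        act = TimeSeries(idx, counts, "counts_per_min", "S1", "activity")
        prof = state_posteriors(model, act)
        assert np.allclose(prof.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((prof.probs > 0.999) | (prof.probs < 0.001))


class TestFit:
    def _subject_activity(self, seed=3, days=3.0):
        truth = generate_cohort(1, seed)[0]
        _, act = generate_chest_data(truth, days=days, seed=seed)
        return truth, act

    def test_same_seed_identical(self):
        _, act = self._subject_activity()
        m1 = fit_harmonic_hmm(act, seed=5, n_restarts=2, max_iter=15)
        m2 = fit_harmonic_hmm(act, seed=5, n_restarts=2, max_iter=15)
        assert np.array_equal(m1.means, m2.means)
        assert m1.loglik == m2.loglik

    def test_loglik_monotone(self):
        _, act = self._subject_activity(seed=6)
        m = fit_harmonic_hmm(act, seed=1, n_restarts=1, max_iter=25)
        trace = np.array(m.loglik_trace)
        assert np.all(np.diff(trace) > -1e-8 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_states_ordered_and_transitions_stochastic(self):
        _, act = self._subject_activity(seed=7)
        m = fit_harmonic_hmm(act, seed=2, n_restarts=1, max_iter=15)
        assert m.means[0] < m.means[1] < m.means[2]
        A = m.transition_matrices()
        assert np.allclose(A.sum(axis=2), 1.0, atol=1e-9)

    def test_constant_input_rejected(self):
        idx = pd.date_range("2024-01-01", periods=3000, freq="min")
        act = TimeSeries(idx, np.full(3000, 30.0), "counts_per_min")
        with pytest.raises(ValidationError):
            fit_harmonic_hmm(act)

    def test_too_short_rejected(self):
        idx = pd.date_range("2024-01-01", periods=600, freq="min")
        act = TimeSeries(idx, np.arange(600.0), "counts_per_min")
        with pytest.raises(ValidationError):
            fit_harmonic_hmm(act)

    def test_center_recovery_small_cohort(self):
        errs = []
        for t in generate_cohort(10, 41):
            _, act = generate_chest_data(t, days=3, seed=41)
            m = fit_harmonic_hmm(act, seed=1, n_restarts=1, max_iter=15)
            cor = center_of_rest(state_posteriors(m, act))
            errs.append(circular_distance(cor, t.true_center_of_rest) * 60)
        assert np.median(errs) < 20.0

    def test_shift_equivariance(self):
        # circular shift on a gap-free whole-day grid: the model class is
        # exactly clock-rotation symmetric
        truth = generate_cohort(1, 9)[0]
        import dataclasses as dc

        from circaphase.simulate import GeneratorConfig
        cfg = dc.replace(GeneratorConfig(), gap_fraction=0.0)
        _, act = generate_chest_data(truth, days=4.0, seed=9, config=cfg)
        rolled = act.replace(values=np.roll(act.values, 5 * 60))
        m1 = fit_harmonic_hmm(act, seed=3, n_restarts=1, max_iter=30)
        m2 = fit_harmonic_hmm(rolled, seed=3, n_restarts=1, max_iter=30)
        c1 = center_of_rest(state_posteriors(m1, act))
        c2 = center_of_rest(state_posteriors(m2, rolled))
        assert circular_distance(c2, c1.hours + 5.0) <= 1.0 / 60.0
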
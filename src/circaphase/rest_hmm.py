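"""Three-state harmonic hidden Markov model for minute-level activity counts.

Counts are transformed by log(1 + x) and modelled with Gaussian emissions in
three latent regimes — inactive/rest, moderately active, highly active —
ordered by ascending emission mean.  The chain is time-inhomogeneous: each
transition-row logit is a baseline plus sine/cosine terms of clock time at
the 24-hour period (optionally higher harmonics), so the propensity to enter
rest follows the clock.  Fitting is EM (Baum-Welch with a weighted
multinomial-logit M-step for the transition parameters) with seeded restarts.

The circadian readout is the *center-of-rest time*: the circular center of
mass of the 24-hour profile of the posterior inactive-state probability,
i.e. the angle of the resultant vector of minute-of-day angles weighted by
that probability.  Computing it circularly matters because rest spans
midnight for most subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .core import ClockPhase, TimeSeries, ValidationError

__all__ = [
    "HarmonicHMM",
    "StateProbabilityProfile",
    "fit_harmonic_hmm",
    "state_posteriors",
    "center_of_rest",
    "forward_backward",
]

_K = 3
_MINUTES_PER_DAY = 1440


# ---------------------------------------------------------------------------
# Forward-backward kernels
# ---------------------------------------------------------------------------

def _fb_python(B, A_idx, A_all, pi):
    """Scaled forward-backward with per-step transition matrices.

    B: (T, K) emission likelihoods (rows of ones marginalise missing data);
    A_idx[t] selects the transition matrix applied on the step t-1 -> t
    (A_idx[0] is unused); pi: initial distribution.
    Returns (gamma, xi_agg, loglik) where xi_agg[m] accumulates expected
    transition counts over all steps with A_idx == m.
    """
    T, K = B.shape
    M = A_all.shape[0]
    alpha = np.empty((T, K))
    c = np.empty(T)
    a0 = pi * B[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        a = alpha[t - 1] @ A_all[A_idx[t]] * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A_all[A_idx[t + 1]] @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_agg = np.zeros((M, K, K))
    for t in range(1, T):
        xi = (alpha[t - 1][:, None] * A_all[A_idx[t]]
              * (B[t] * beta[t])[None, :]) / c[t]
        xi_agg[A_idx[t]] += xi
    return gamma, xi_agg, float(np.log(c).sum())


def _make_numba_kernel():
    try:
        import numba
    except ImportError:  # pragma: no cover - numba is normally present
        return None

    @numba.njit(cache=False)
    def kernel(B, A_idx, A_all, pi):  # pragma: no cover - exercised via wrapper
        T, K = B.shape
        M = A_all.shape[0]
        alpha = np.empty((T, K))
        c = np.empty(T)
        s = 0.0
        for k in range(K):
            alpha[0, k] = pi[k] * B[0, k]
            s += alpha[0, k]
        c[0] = s
        for k in range(K):
            alpha[0, k] /= s
        for t in range(1, T):
            A = A_all[A_idx[t]]
            s = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[t - 1, i] * A[i, j]
                alpha[t, j] = acc * B[t, j]
                s += alpha[t, j]
            c[t] = s
            for j in range(K):
                alpha[t, j] /= s
        beta = np.empty((T, K))
        for k in range(K):
            beta[T - 1, k] = 1.0
        for t in range(T - 2, -1, -1):
            A = A_all[A_idx[t + 1]]
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += A[i, j] * B[t + 1, j] * beta[t + 1, j]
                beta[t, i] = acc / c[t + 1]
        gamma = np.empty((T, K))
        for t in range(T):
            s = 0.0
            for k in range(K):
                gamma[t, k] = alpha[t, k] * beta[t, k]
                s += gamma[t, k]
            for k in range(K):
                gamma[t, k] /= s
        xi_agg = np.zeros((M, K, K))
        for t in range(1, T):
            m = A_idx[t]
            A = A_all[m]
            for i in range(K):
                for j in range(K):
                    xi_agg[m, i, j] += (alpha[t - 1, i] * A[i, j]
                                        * B[t, j] * beta[t, j]) / c[t]
        ll = 0.0
        for t in range(T):
            ll += np.log(c[t])
        return gamma, xi_agg, ll

    return kernel


_NUMBA_KERNEL = _make_numba_kernel()


def forward_backward(B, A_idx, A_all, pi):
    """Dispatch to the compiled kernel when available (identical results)."""
    B = np.ascontiguousarray(B, dtype=np.float64)
    A_idx = np.ascontiguousarray(A_idx, dtype=np.int64)
    A_all = np.ascontiguousarray(A_all, dtype=np.float64)
    pi = np.ascontiguousarray(pi, dtype=np.float64)
    if _NUMBA_KERNEL is not None:
        gamma, xi_agg, ll = _NUMBA_KERNEL(B, A_idx, A_all, pi)
        return gamma, xi_agg, float(ll)
    return _fb_python(B, A_idx, A_all, pi)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class HarmonicHMM:
    """Fitted 3-state activity HMM with harmonic transition modulation.

    ``baseline`` / ``alpha`` / ``beta`` parameterise the transition logits:
    row i, column j of the minute-m transition matrix is the softmax of
    baseline[i, j] + sum_h alpha[h, i, j] cos(2 pi (h+1) m / 1440)
                   + beta[h, i, j] sin(2 pi (h+1) m / 1440),
    with the diagonal (staying) fixed at logit 0 as the reference.
    States are ordered by ascending emission mean; state 0 is inactive/rest.
    """

    means: np.ndarray            # (3,) emission means of log1p(counts)
    sds: np.ndarray              # (3,)
    startprob: np.ndarray        # (3,)
    baseline: np.ndarray         # (3, 3), diagonal 0
    alpha: np.ndarray            # (H, 3, 3)
    beta: np.ndarray             # (H, 3, 3)
    n_harmonics: int
    loglik: float = np.nan
    loglik_trace: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    def transition_matrices(self) -> np.ndarray:
        """(1440, 3, 3) stochastic matrices, one per minute of day."""
        m = np.arange(_MINUTES_PER_DAY)
        eta = np.broadcast_to(self.baseline, (_MINUTES_PER_DAY, _K, _K)).copy()
        for h in range(self.n_harmonics):
            w = 2 * np.pi * (h + 1) * m / _MINUTES_PER_DAY
            eta += (np.cos(w)[:, None, None] * self.alpha[h]
                    + np.sin(w)[:, None, None] * self.beta[h])
        eta -= eta.max(axis=2, keepdims=True)
        A = np.exp(eta)
        A /= A.sum(axis=2, keepdims=True)
        return A

    def emission_likelihood(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        """Scaled (T, 3) Gaussian likelihoods plus the log-offset removed.

        Each observed row is rescaled by its maximum (posteriors are
        invariant to per-row scaling; the summed log-offset restores the
        exact log-likelihood), which keeps far-apart states numerically
        separable.  NaN observations marginalise to a row of ones.
        """
        B = np.ones((x.size, _K))
        ok = np.isfinite(x)
        z = (x[ok, None] - self.means[None, :]) / self.sds[None, :]
        logB = -0.5 * z**2 - np.log(np.sqrt(2 * np.pi) * self.sds[None, :])
        row_max = logB.max(axis=1, keepdims=True)
        B[ok] = np.maximum(np.exp(logB - row_max), 1e-300)
        return B, float(row_max.sum())


@dataclass
class StateProbabilityProfile:
    """Posterior state probabilities averaged onto the 1440-minute clock grid."""

    minutes: np.ndarray          # 0..1439
    probs: np.ndarray            # (1440, 3); rows sum to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (_MINUTES_PER_DAY, _K):
            raise ValidationError("profile must be 1440 x 3")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("state probabilities must sum to 1 at every minute")

    @property
    def rest(self) -> np.ndarray:
        return self.probs[:, 0]


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def _prepare(activity: TimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Full-day minute grid (NaN where unobserved) and its minute-of-day index."""
    if activity.unit != "counts_per_min":
        raise ValidationError(f"expected activity counts, got unit {activity.unit!r}")
    start = activity.timestamps[0].normalize()
    end = activity.timestamps[-1].normalize() + pd.Timedelta(days=1)
    grid = pd.date_range(start, end, freq="min", inclusive="left")
    x = np.full(len(grid), np.nan)
    pos = ((activity.timestamps.asi8 - start.value) // 60_000_000_000).astype(int)
    x[pos] = np.log1p(np.maximum(activity.values, 0.0))
    mod = ((grid.asi8 - start.value) // 60_000_000_000 % _MINUTES_PER_DAY).astype(np.int64)
    return x, mod


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _phi(n_harmonics: int) -> np.ndarray:
    """Harmonic covariates of minute-of-day: (1440, 1 + 2H)."""
    m = np.arange(_MINUTES_PER_DAY)
    cols = [np.ones(_MINUTES_PER_DAY)]
    for h in range(n_harmonics):
        w = 2 * np.pi * (h + 1) * m / _MINUTES_PER_DAY
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


def _pack_row(baseline, alpha, beta, i, free):
    """Stack row-i parameters for the two free destinations into a vector."""
    H = alpha.shape[0]
    out = []
    for j in free:
        out.append(baseline[i, j])
        for h in range(H):
            out.extend([alpha[h, i, j], beta[h, i, j]])
    return np.array(out)


def _unpack_row(vec, H):
    """(n_free, 1 + 2H) coefficient matrix per destination."""
    return vec.reshape(2, 1 + 2 * H)


def _row_objective(vec, Phi, xi_row, i, free, H):
    """Negative expected complete-data log-likelihood for one transition row."""
    W = _unpack_row(vec, H)                       # (2, 1+2H): [const, cos1, sin1, ...]
    eta_free = Phi @ W.T                          # (1440, 2)
    eta = np.zeros((_MINUTES_PER_DAY, _K))
    eta[:, free] = eta_free
    lse = logsumexp(eta, axis=1)
    n_m = xi_row.sum(axis=1)                      # (1440,)
    f = np.sum(xi_row * eta) - np.sum(n_m * lse)
    # gradient
    P = np.exp(eta - lse[:, None])                # (1440, 3)
    G = xi_row[:, free] - n_m[:, None] * P[:, free]   # (1440, 2)
    grad = (G.T @ Phi).ravel()                    # per destination, per covariate
    return -f, -grad


def _optimize_transitions(baseline, alpha, beta, xi_agg, n_harmonics):
    Phi = _phi(n_harmonics)
    H = n_harmonics
    for i in range(_K):
        free = [j for j in range(_K) if j != i]
        x0 = _pack_row(baseline, alpha, beta, i, free)
        res = minimize(_row_objective, x0, args=(Phi, xi_agg[:, i, :], i, free, H),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": 60, "ftol": 1e-10})
        W = _unpack_row(res.x, H)
        for k, j in enumerate(free):
            baseline[i, j] = W[k, 0]
            for h in range(H):
                alpha[h, i, j] = W[k, 1 + 2 * h]
                beta[h, i, j] = W[k, 2 + 2 * h]
    return baseline, alpha, beta


def _initial_params(x, n_harmonics, rng, restart):
    obs = x[np.isfinite(x)]
    qs = np.quantile(obs, [0.15, 0.55, 0.90])
    means = qs.copy()
    if restart > 0:
        means = means + rng.normal(0.0, 0.25 * (obs.std() + 1e-3), size=_K)
        means.sort()
    # keep means distinct
    for k in range(1, _K):
        if means[k] - means[k - 1] < 1e-3:
            means[k] = means[k - 1] + 1e-3
    sds = np.full(_K, max(obs.std() / 2.0, 1e-2))
    baseline = np.full((_K, _K), -2.5)
    np.fill_diagonal(baseline, 0.0)
    if restart > 0:
        off = ~np.eye(_K, dtype=bool)
        baseline[off] += rng.normal(0.0, 0.5, size=off.sum())
    alpha = np.zeros((n_harmonics, _K, _K))
    beta = np.zeros((n_harmonics, _K, _K))
    pi = np.full(_K, 1.0 / _K)
    return means, sds, pi, baseline, alpha, beta


def _run_em(x, mod, n_harmonics, means, sds, pi, baseline, alpha, beta,
            max_iter, tol):
    model = HarmonicHMM(means, sds, pi, baseline, alpha, beta, n_harmonics)
    trace = []
    prev = -np.inf
    ok = np.isfinite(x)
    for it in range(max_iter):
        A_all = model.transition_matrices()
        B, log_offset = model.emission_likelihood(x)
        gamma, xi_agg, ll = forward_backward(B, mod, A_all, model.startprob)
        ll += log_offset
        trace.append(ll)
        if ll < prev - 1e-8 * max(1.0, abs(prev)):
            warnings.warn(f"EM log-likelihood decreased at iteration {it}", stacklevel=2)
        if it > 0 and abs(ll - prev) < tol * max(1.0, abs(prev)):
            prev = ll
            break
        prev = ll
        # M-step: emissions on observed minutes
        g = gamma[ok]
        xo = x[ok]
        wsum = g.sum(axis=0) + 1e-12
        model.means = (g * xo[:, None]).sum(axis=0) / wsum
        var = (g * (xo[:, None] - model.means[None, :]) ** 2).sum(axis=0) / wsum
        model.sds = np.sqrt(np.maximum(var, 1e-6))
        model.startprob = np.maximum(gamma[0], 1e-12)
        model.startprob /= model.startprob.sum()
        model.baseline, model.alpha, model.beta = _optimize_transitions(
            model.baseline, model.alpha, model.beta, xi_agg, n_harmonics)
    model.loglik = prev
    model.loglik_trace = trace
    model.n_iter = len(trace)
    model.converged = (len(trace) < max_iter or
                       (len(trace) >= 2 and abs(trace[-1] - trace[-2])
                        < tol * max(1.0, abs(trace[-2]))))
    return model


def _relabel(model: HarmonicHMM) -> HarmonicHMM:
    order = np.argsort(model.means)
    model.means = model.means[order]
    model.sds = model.sds[order]
    model.startprob = model.startprob[order]
    model.baseline = model.baseline[np.ix_(order, order)]
    model.alpha = model.alpha[:, order][:, :, order]
    model.beta = model.beta[:, order][:, :, order]
    return model


def fit_harmonic_hmm(activity: TimeSeries, n_harmonics: int = 1, seed: int = 0,
                     n_restarts: int = 5, max_iter: int = 50,
                     tol: float = 1e-6) -> HarmonicHMM:
    """Fit the 3-state harmonic HMM to minute-level counts by seeded EM.

    Runs ``n_restarts`` EM optimisations (the first from a deterministic
    quantile-based initialisation, the rest perturbed) and keeps the best
    log-likelihood; states are then relabelled by ascending emission mean.
    Requires at least 2 days of data; constant input is a degenerate fit and
    raises.  Non-convergence within ``max_iter`` sets ``converged=False``
    with a warning rather than raising.
    """
    x, mod = _prepare(activity)
    if x.size < 2 * _MINUTES_PER_DAY:
        raise ValidationError("need at least 2 days of activity data")
    obs = x[np.isfinite(x)]
    if obs.std() < 1e-8:
        raise ValidationError("constant activity input: degenerate fit")
    rng = np.random.default_rng(int(seed) % (2**31))
    best = None
    for r in range(max(1, n_restarts)):
        means, sds, pi, C, Al, Be = _initial_params(x, n_harmonics, rng, r)
        model = _run_em(x, mod, n_harmonics, means, sds, pi, C, Al, Be,
                        max_iter, tol)
        if best is None or model.loglik > best.loglik:
            best = model
    if not best.converged:
        warnings.warn("harmonic HMM did not converge within max_iter; "
                      "returning the best fit found", stacklevel=2)
    return _relabel(best)


def state_posteriors(model: HarmonicHMM, activity: TimeSeries
                     ) -> StateProbabilityProfile:
    """Forward-backward smoothing averaged onto the 24-hour clock grid.

    Gaps in the recording are marginalised over the missing emissions, so
    every minute of day carries a well-defined posterior.
    """
    x, mod = _prepare(activity)
    A_all = model.transition_matrices()
    B, _ = model.emission_likelihood(x)
    gamma, _, _ = forward_backward(B, mod, A_all, model.startprob)
    sums = np.zeros((_MINUTES_PER_DAY, _K))
    counts = np.zeros(_MINUTES_PER_DAY)
    np.add.at(sums, mod, gamma)
    np.add.at(counts, mod, 1.0)
    probs = sums / counts[:, None]
    return StateProbabilityProfile(np.arange(_MINUTES_PER_DAY), probs)


def center_of_rest(profile: StateProbabilityProfile) -> ClockPhase:
    """Circular center of mass of the inactive-state probability profile.

    The resultant vector of minute-of-day angles (bin centers) weighted by
    the rest probability gives the mean direction, converted to clock time.
    """
    w = profile.rest
    total = w.sum()
    if total <= 1e-12:
        raise ValidationError("inactive-state profile is identically zero")
    theta = 2 * np.pi * (profile.minutes + 0.5) / _MINUTES_PER_DAY
    z = np.sum(w * np.exp(1j * theta)) / total
    if np.abs(z) < 1e-12:
        raise ValidationError("rest profile has no defined circular mean")
    hours = (np.angle(z) % (2 * np.pi)) * 24.0 / (2 * np.pi)
    return ClockPhase(hours)
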
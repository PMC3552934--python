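"""Constrained (Monte-Carlo) EM for the measurement-error model.

Latent true exposures (and, for missing-exposure subjects, the unobserved
measurement) are treated as missing data.  The E-step computes posterior
moments of the latent exposure per record: closed-form normals for the linear
family, self-normalized importance sampling for the logistic family (proposal
= the Gaussian "prior x measurement" posterior, which is exact when beta1 = 0;
missing records use the group prior as proposal).  The M-step alternates a
weighted-PAVA-constrained update of the ordered group means with closed-form
(linear) or Newton (logistic) updates of the outcome parameters and the
between-subject variance.  The measurement-error variance sigma_eta^2 is a
required known input: it is not identifiable from single measurements.

Standard errors come from the empirical (Meilijson-style) information matrix:
per-subject observed-data scores are obtained by Fisher's identity as
conditional expectations of the complete-data scores, and their centered
outer-product sum is inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import expit, log_expit

from .group_estimators import EstimationResult, fit_naive
from .isotonic import pava
from .model import (
    LINEAR,
    LOGISTIC,
    GroupedDataset,
    Theta,
    _posterior_missing_linear,
    _posterior_obs_linear,
)

__all__ = ["CemOptions", "ExpectedStats", "ProposalFailure", "cem_estep",
           "cem_mstep", "expected_q", "fit_cem", "se_meilijson"]

_VAR_FLOOR = 1e-8
_LOG_2PI_ = float(np.log(2.0 * np.pi))


class ProposalFailure(RuntimeError):
    """Importance-sampling effective sample size fell below the floor."""


@dataclass
class CemOptions:
    """Tuning knobs for the (Monte-Carlo) EM iteration.

    ``tol`` is the convergence threshold on the maximum relative parameter
    change (defaults: 1e-5 linear, 1e-3 logistic — the Monte-Carlo noise
    floor); for the logistic family convergence is assessed on parameters
    averaged over the last ``smooth_window`` iterations to damp MC noise.
    ``mc_draws_initial`` importance draws are used per record until iteration
    ``draw_escalation_iter``, then ``mc_draws_final``.
    """

    max_iter: int = 500
    tol: Optional[float] = None
    mc_draws_initial: int = 200
    mc_draws_final: int = 2000
    draw_escalation_iter: int = 20
    seed: int = 0
    constrained: bool = True
    ess_floor: float = 20.0
    smooth_window: int = 5
    compute_se: bool = True

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (self.mc_draws_final >= self.mc_draws_initial >= 50):
            raise ValueError("need mc_draws_final >= mc_draws_initial >= 50")

    def effective_tol(self, family: str) -> float:
        if self.tol is not None:
            return self.tol
        return 1e-5 if family == LINEAR else 1e-3


@dataclass
class ExpectedStats:
    """Per-record posterior moments of the latent exposure at the current theta.

    ``ex``/``ex2`` are E[X] and E[X^2] per record.  For the logistic family,
    ``draws`` and row-normalized ``weights`` (shape n x K) retain the
    importance sample for the Newton M-step and the score computation.
    """

    ex: np.ndarray
    ex2: np.ndarray
    draws: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None


def cem_estep(
    dataset: GroupedDataset,
    theta: Theta,
    options: CemOptions,
    rng: np.random.Generator,
    n_draws: Optional[int] = None,
) -> ExpectedStats:
    """E-step: posterior moments of the latent exposure for every record."""
    obs = dataset.observed
    mu_g = theta.mu[dataset.gidx]
    if theta.family == LINEAR:
        ex = np.empty(dataset.n)
        ex2 = np.empty(dataset.n)
        m, v = _posterior_obs_linear(dataset.y[obs], dataset.w[obs], mu_g[obs], theta)
        ex[obs], ex2[obs] = m, m**2 + v
        if np.any(~obs):
            m, v, _, _ = _posterior_missing_linear(dataset.y[~obs], mu_g[~obs], theta)
            ex[~obs], ex2[~obs] = m, m**2 + v
        return ExpectedStats(ex=ex, ex2=ex2)

    K = int(n_draws if n_draws is not None else options.mc_draws_initial)
    s_b2, s_eta2 = theta.sigma_b2, theta.sigma_eta2
    # proposal: measurement posterior for observed records, group prior for missing
    prop_mean = np.where(obs, (s_b2 * np.nan_to_num(dataset.w) + s_eta2 * mu_g) / (s_b2 + s_eta2), mu_g)
    prop_var = np.where(obs, s_b2 * s_eta2 / (s_b2 + s_eta2), s_b2)
    draws = prop_mean[:, None] + np.sqrt(prop_var)[:, None] * rng.standard_normal((dataset.n, K))
    p = expit(theta.beta0 + theta.beta1 * draws)
    raw = np.where(dataset.y[:, None] > 0.5, p, 1.0 - p)
    totals = raw.sum(axis=1)
    if np.any(totals <= 0):
        raise ProposalFailure("importance weights vanished for some record")
    weights = raw / totals[:, None]
    ess = 1.0 / np.sum(weights**2, axis=1)
    if ess.min() < options.ess_floor:
        raise ProposalFailure(
            f"min effective sample size {ess.min():.1f} below floor {options.ess_floor}"
        )
    ex = np.sum(weights * draws, axis=1)
    ex2 = np.sum(weights * draws**2, axis=1)
    return ExpectedStats(ex=ex, ex2=ex2, draws=draws, weights=weights)


def expected_q(
    stats: ExpectedStats,
    dataset: GroupedDataset,
    theta: Theta,
    include_missing_measurement_terms: bool = True,
) -> float:
    """Expected complete-data log-likelihood Q at theta, given E-step moments.

    For missing-exposure records E[(W* - X*)^2 | y*] = sigma_eta^2 exactly,
    a constant in every estimated parameter; those measurement terms are
    excluded from the M-step objectives but included here by default so that
    reported Q values cover the full complete-data likelihood.  Set
    ``include_missing_measurement_terms=False`` to drop them.
    """
    obs = dataset.observed
    mu_rec = theta.mu[dataset.gidx]
    y, w = dataset.y, dataset.w
    ex, ex2 = stats.ex, stats.ex2
    q = 0.0
    if theta.family == LINEAR:
        e_res2 = (y - theta.beta0) ** 2 - 2 * theta.beta1 * (y - theta.beta0) * ex \
            + theta.beta1**2 * ex2
        q += float(np.sum(-0.5 * (_LOG_2PI_ + np.log(theta.sigma_eps2)
                                  + e_res2 / theta.sigma_eps2)))
    else:
        z = theta.beta0 + theta.beta1 * stats.draws
        ll = y[:, None] * log_expit(z) + (1.0 - y[:, None]) * log_expit(-z)
        q += float(np.sum(stats.weights * ll))
    e_dev2 = ex2 - 2.0 * mu_rec * ex + mu_rec**2
    q += float(np.sum(-0.5 * (_LOG_2PI_ + np.log(theta.sigma_b2)
                              + e_dev2 / theta.sigma_b2)))
    e_meas2 = w[obs] ** 2 - 2.0 * w[obs] * ex[obs] + ex2[obs]
    q += float(np.sum(-0.5 * (_LOG_2PI_ + np.log(theta.sigma_eta2)
                              + e_meas2 / theta.sigma_eta2)))
    if include_missing_measurement_terms:
        n_miss = int(np.sum(~obs))
        q += n_miss * (-0.5 * (_LOG_2PI_ + np.log(theta.sigma_eta2) + 1.0))
    return q


def _newton_logistic(y, draws, weights, beta0, beta1, max_iter=50, tol=1e-7):
    """Maximize the importance-weighted expected Bernoulli log-likelihood."""
    beta = np.array([beta0, beta1], dtype=float)
    for it in range(max_iter):
        z = beta[0] + beta[1] * draws
        p = expit(z)
        r = (y[:, None] - p) * weights
        grad = np.array([r.sum(), (r * draws).sum()])
        pq = p * (1.0 - p) * weights
        h01 = (pq * draws).sum()
        H = np.array([[pq.sum(), h01], [h01, (pq * draws**2).sum()]])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Hessian in logistic M-step") from exc
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True, it + 1
    return beta, False, max_iter


def cem_mstep(
    stats: ExpectedStats,
    dataset: GroupedDataset,
    theta: Theta,
    constrained: bool = True,
) -> Theta:
    """M-step: ordered-mean update by weighted PAVA, then outcome parameters.

    Group means are updated to per-group averages of E[X] over *all* records
    (observed and missing exposure alike) and, if constrained, isotonized by
    PAVA with the total group counts as weights.  Then sigma_b^2, the
    regression coefficients and (linear family) the residual variance are
    refreshed; sigma_eta^2 is known and untouched.
    """
    gidx = dataset.gidx
    counts = dataset.n_per_group.astype(float)
    mu_raw = np.bincount(gidx, weights=stats.ex, minlength=dataset.G) / counts
    mu_new = pava(mu_raw, counts).fitted if constrained else mu_raw

    mu_rec = mu_new[gidx]
    sigma_b2 = float(np.mean(stats.ex2 - 2.0 * mu_rec * stats.ex + mu_rec**2))
    sigma_b2 = max(sigma_b2, _VAR_FLOOR)

    y = dataset.y
    if theta.family == LINEAR:
        n = dataset.n
        s1, s2 = stats.ex.sum(), stats.ex2.sum()
        sy, sxy = y.sum(), float(np.sum(y * stats.ex))
        det = n * s2 - s1 * s1
        if abs(det) < 1e-12 * max(1.0, n * s2):
            raise np.linalg.LinAlgError("singular normal equations in M-step")
        beta1 = (n * sxy - s1 * sy) / det
        beta0 = (sy - beta1 * s1) / n
        resid2 = (y - beta0) ** 2 - 2.0 * beta1 * (y - beta0) * stats.ex + beta1**2 * stats.ex2
        sigma_eps2 = max(float(np.mean(resid2)), _VAR_FLOOR)
        return replace(theta, beta0=beta0, beta1=beta1, sigma_eps2=sigma_eps2,
                       mu=mu_new, sigma_b2=sigma_b2)

    if stats.draws is None or stats.weights is None:
        raise ValueError("logistic M-step requires posterior draws in ExpectedStats")
    beta, _, _ = _newton_logistic(y, stats.draws, stats.weights, theta.beta0, theta.beta1)
    return replace(theta, beta0=float(beta[0]), beta1=float(beta[1]),
                   mu=mu_new, sigma_b2=sigma_b2)


def _initial_theta(dataset: GroupedDataset, family: str, sigma_eta2: float,
                   constrained: bool) -> Theta:
    """Naive initialization: complete-case regression + moment starts."""
    naive = fit_naive(dataset, family)
    obs = dataset.observed
    means = dataset.observed_group_means()
    fallback = float(np.mean(dataset.w[obs]))
    means = np.where(np.isfinite(means), means, fallback)
    counts = np.maximum(dataset.n_g, 1).astype(float)
    mu0 = pava(means, counts).fitted if constrained else means
    # pooled within-group variance of observed w, minus the known error variance
    dev = dataset.w[obs] - means[dataset.gidx[obs]]
    within = float(np.sum(dev**2)) / max(int(obs.sum()) - int(np.sum(dataset.n_g > 0)), 1)
    sigma_b2 = max(within - sigma_eta2, 1e-4)
    sigma_eps2 = None
    if family == LINEAR:
        resid = dataset.y[obs] - naive.beta0_hat - naive.beta1_hat * dataset.w[obs]
        sigma_eps2 = max(float(np.var(resid)), 1e-4)
    return Theta(beta0=naive.beta0_hat, beta1=naive.beta1_hat, mu=mu0,
                 sigma_b2=sigma_b2, sigma_eta2=sigma_eta2, family=family,
                 sigma_eps2=sigma_eps2)


def fit_cem(
    dataset: GroupedDataset,
    family: str = LINEAR,
    sigma_eta2: float = None,
    options: Optional[CemOptions] = None,
) -> EstimationResult:
    """Constrained (Monte-Carlo) EM fit of the full measurement-error model.

    Starts from naive estimates, alternates E- and M-steps until the maximum
    relative parameter change (smoothed over the last iterations for the
    logistic family) drops below tolerance, escalating Monte-Carlo draws
    after ``draw_escalation_iter`` iterations.  Non-convergence at
    ``max_iter`` is flagged on the result, not raised.  The returned trace
    holds the parameter vector at every iteration (see ``Theta.to_vector``).
    """
    if sigma_eta2 is None or sigma_eta2 <= 0:
        raise ValueError("sigma_eta2 must be a known positive value")
    opts = options or CemOptions()
    tol = opts.effective_tol(family)
    rng = np.random.default_rng(np.random.SeedSequence(opts.seed))

    theta = _initial_theta(dataset, family, sigma_eta2, opts.constrained)
    trace = [theta.to_vector()]
    window = 1 if family == LINEAR else opts.smooth_window
    smoothed_prev = None
    converged = False
    n_iter = 0
    n_draws = opts.mc_draws_initial
    for t in range(1, opts.max_iter + 1):
        n_iter = t
        if t > opts.draw_escalation_iter:
            n_draws = opts.mc_draws_final
        try:
            stats = cem_estep(dataset, theta, opts, rng, n_draws=n_draws)
        except ProposalFailure:
            n_draws = opts.mc_draws_final
            stats = cem_estep(dataset, theta, opts, rng, n_draws=n_draws)
        theta = cem_mstep(stats, dataset, theta, opts.constrained)
        trace.append(theta.to_vector())
        hist = np.asarray(trace[-window:])
        smoothed = hist.mean(axis=0)
        if smoothed_prev is not None:
            rel = np.max(np.abs(smoothed - smoothed_prev)
                         / np.maximum(np.abs(smoothed_prev), 1e-3))
            if rel < tol:
                converged = True
                break
        smoothed_prev = smoothed

    if window > 1 and len(trace) > window:
        # report the MC-noise-damped estimate: average of the last window
        theta = theta.with_vector(np.asarray(trace[-window:]).mean(axis=0))

    se = None
    if opts.compute_se:
        try:
            se = se_meilijson(dataset, theta, opts)
        except np.linalg.LinAlgError:
            se = None
    return EstimationResult(
        method="cem", beta0_hat=theta.beta0, beta1_hat=theta.beta1,
        se_beta1=se, se_inflated=False, mu_hat=theta.mu.copy(),
        sigma_b2_hat=theta.sigma_b2, sigma_eps2_hat=theta.sigma_eps2,
        converged=converged, n_iterations=n_iter, trace=trace,
    )


def _score_matrix(dataset: GroupedDataset, theta: Theta, stats: ExpectedStats) -> np.ndarray:
    """Per-subject observed-data scores via Fisher's identity.

    The observed-data score equals the conditional expectation of the
    complete-data score given the observables; terms involving only the known
    sigma_eta^2 drop out.  Column order matches ``Theta.to_vector``.
    """
    n, G = dataset.n, dataset.G
    gidx = dataset.gidx
    mu_rec = theta.mu[gidx]
    y = dataset.y
    ex, ex2 = stats.ex, stats.ex2
    varx = ex2 - ex**2

    cols = []
    if theta.family == LINEAR:
        s_eps2 = theta.sigma_eps2
        s_b0 = (y - theta.beta0 - theta.beta1 * ex) / s_eps2
        s_b1 = (y * ex - theta.beta0 * ex - theta.beta1 * ex2) / s_eps2
        e_res2 = (y - theta.beta0) ** 2 - 2 * theta.beta1 * (y - theta.beta0) * ex \
            + theta.beta1**2 * ex2
        s_se = -0.5 / s_eps2 + e_res2 / (2.0 * s_eps2**2)
        cols = [s_b0, s_b1, s_se]
    else:
        el = np.sum(stats.weights * expit(theta.beta0 + theta.beta1 * stats.draws), axis=1)
        exl = np.sum(stats.weights * stats.draws
                     * expit(theta.beta0 + theta.beta1 * stats.draws), axis=1)
        cols = [y - el, y * ex - exl]

    s_mu = np.zeros((n, G))
    s_mu[np.arange(n), gidx] = (ex - mu_rec) / theta.sigma_b2
    e_dev2 = ex2 - 2.0 * mu_rec * ex + mu_rec**2
    s_sb = -0.5 / theta.sigma_b2 + e_dev2 / (2.0 * theta.sigma_b2**2)
    return np.column_stack(cols + [s_mu, s_sb])


def se_meilijson(
    dataset: GroupedDataset,
    theta_hat: Theta,
    options: Optional[CemOptions] = None,
) -> float:
    """Empirical-information standard error of the slope at a converged fit.

    Information = sum of outer products of the centered per-subject scores;
    SE(beta1) is the square root of the corresponding diagonal element of its
    inverse.  Raises ``numpy.linalg.LinAlgError`` if the matrix is singular.
    """
    opts = options or CemOptions()
    rng = np.random.default_rng(np.random.SeedSequence(opts.seed, spawn_key=(2**20,)))
    stats = cem_estep(dataset, theta_hat, opts, rng, n_draws=opts.mc_draws_final)
    S = _score_matrix(dataset, theta_hat, stats)
    sbar = S.mean(axis=0)
    info = S.T @ S - dataset.n * np.outer(sbar, sbar)
    cov = np.linalg.inv(info)
    var = cov[1, 1]
    if not np.isfinite(var) or var <= 0:
        raise np.linalg.LinAlgError("empirical information matrix not positive definite")
    return float(np.sqrt(var))
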
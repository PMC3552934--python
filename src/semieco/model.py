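"""Probabilistic model for grouped exposures measured with classical error.

The observed exposure of subject *i* in group *g* is

    W_gi = X_gi + eta_gi,      X_gi ~ N(mu_g, sigma_b^2),  eta_gi ~ N(0, sigma_eta^2),

where ``X_gi`` is the true (latent) exposure, ``mu_1 <= ... <= mu_G`` are the
ordered group mean exposures, ``sigma_b^2`` is the between-subject variance and
``sigma_eta^2`` the (known) measurement-error variance.  The health outcome is
fully observed and follows either a linear model

    Y_gi = beta0 + beta1 * X_gi + eps_gi,   eps_gi ~ N(0, sigma_eps^2),

or a logistic model ``P(Y_gi = 1 | X_gi) = expit(beta0 + beta1 * X_gi)``.

This module holds the parameter and data containers, the complete- and
observed-data log-likelihoods, and the closed-form conditional distributions of
the latent exposure that drive the EM machinery and serve as test oracles.
Exposure may be missing for part of the subjects (missing completely at
random); outcomes are never missing, matching the semi-ecological design where
health status is ascertained for everyone but exposure is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import log_expit, expit

LINEAR = "linear"
LOGISTIC = "logistic"

_LOG_2PI = float(np.log(2.0 * np.pi))


class ModelError(ValueError):
    """Invalid parameter values or model/family mismatch."""


@dataclass
class Theta:
    """Full parameter vector of the exposure/outcome model.

    Parameters
    ----------
    beta0, beta1
        Outcome-model intercept and slope.
    mu
        Group mean exposures, length ``G``.  Constrained estimators return a
        nondecreasing vector.
    sigma_b2
        Between-subject exposure variance (> 0).
    sigma_eta2
        Measurement-error variance (> 0).  Treated as *known* throughout:
        it is not identifiable from single measurements per subject.
    family
        ``"linear"`` or ``"logistic"``.
    sigma_eps2
        Residual outcome variance; required for the linear family, absent
        (``None``) for logistic.
    """

    beta0: float
    beta1: float
    mu: np.ndarray
    sigma_b2: float
    sigma_eta2: float
    family: str = LINEAR
    sigma_eps2: Optional[float] = None

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if self.family not in (LINEAR, LOGISTIC):
            raise ModelError(f"unknown family {self.family!r}")
        if not np.all(np.isfinite(self.mu)):
            raise ModelError("non-finite group means")
        for name in ("beta0", "beta1", "sigma_b2", "sigma_eta2"):
            if not np.isfinite(getattr(self, name)):
                raise ModelError(f"non-finite {name}")
        if self.sigma_b2 <= 0 or self.sigma_eta2 <= 0:
            raise ModelError("variance components must be positive")
        if self.family == LINEAR:
            if self.sigma_eps2 is None or self.sigma_eps2 <= 0:
                raise ModelError("linear family requires sigma_eps2 > 0")
        elif self.sigma_eps2 is not None:
            raise ModelError("logistic family has no residual variance")

    @property
    def G(self) -> int:
        return self.mu.size

    def to_vector(self) -> np.ndarray:
        """Flatten the estimated parameters (sigma_eta2 is known, excluded)."""
        head = [self.beta0, self.beta1]
        if self.family == LINEAR:
            head.append(self.sigma_eps2)
        return np.concatenate([head, self.mu, [self.sigma_b2]])

    def with_vector(self, vec: np.ndarray) -> "Theta":
        """Rebuild a Theta from :meth:`to_vector` output (inverse map)."""
        vec = np.asarray(vec, dtype=float)
        k = 3 if self.family == LINEAR else 2
        return replace(
            self,
            beta0=vec[0],
            beta1=vec[1],
            sigma_eps2=vec[2] if self.family == LINEAR else None,
            mu=vec[k : k + self.G].copy(),
            sigma_b2=vec[k + self.G],
        )


@dataclass
class GroupedDataset:
    """Subject-level records ``(group, y, w)`` with ``w = NaN`` meaning missing.

    Groups are labelled ``1..G`` (1-based, ordered by hypothesized increasing
    exposure) and must be contiguous.  Outcomes are always observed.  The true
    exposure ``x_true`` is an optional side channel filled by the simulator for
    oracle checks only; estimators never read it.
    """

    group: np.ndarray
    y: np.ndarray
    w: np.ndarray
    x_true: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        n = self.group.size
        if not (self.y.size == n == self.w.size):
            raise ValueError("group, y, w must have equal length")
        if n == 0:
            raise ValueError("empty dataset")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("every record must have an observed outcome y")
        labels = np.unique(self.group)
        if labels[0] < 1 or not np.array_equal(labels, np.arange(1, labels[-1] + 1)):
            raise ValueError("group labels must be contiguous 1..G")
        if self.x_true is not None:
            self.x_true = np.asarray(self.x_true, dtype=float)
            if self.x_true.size != n:
                raise ValueError("x_true length mismatch")

    @property
    def n(self) -> int:
        return self.group.size

    @property
    def G(self) -> int:
        return int(self.group.max())

    @property
    def gidx(self) -> np.ndarray:
        """0-based group index per record."""
        return self.group - 1

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of records with an observed exposure measurement."""
        return np.isfinite(self.w)

    @property
    def n_g(self) -> np.ndarray:
        """Per-group counts of observed exposures."""
        return np.bincount(self.gidx[self.observed], minlength=self.G)

    @property
    def n_g_star(self) -> np.ndarray:
        """Per-group counts of missing exposures."""
        return np.bincount(self.gidx[~self.observed], minlength=self.G)

    @property
    def n_per_group(self) -> np.ndarray:
        return np.bincount(self.gidx, minlength=self.G)

    def observed_group_means(self) -> np.ndarray:
        """Sample mean of observed w per group; NaN for unmeasured groups."""
        obs = self.observed
        sums = np.bincount(self.gidx[obs], weights=self.w[obs], minlength=self.G)
        counts = self.n_g
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


@dataclass
class PosteriorMoments:
    """Posterior moments of the latent exposure for a single subject.

    For subjects with observed ``(y, w)`` only ``mean``/``var`` are set.  For
    missing-exposure subjects the joint posterior of ``(X*, W*)`` given the
    outcome is bivariate normal with common mean ``mean``, variances
    ``v_x_star <= v_w_star`` and correlation ``rho``.
    """

    mean: float
    var: float
    v_x_star: Optional[float] = None
    v_w_star: Optional[float] = None
    rho: Optional[float] = None


def _check_group(g: int, theta: Theta) -> int:
    if not (1 <= g <= theta.G):
        raise ModelError(f"group index {g} outside 1..{theta.G}")
    return g - 1


# ---------------------------------------------------------------------------
# Closed-form conditionals (linear family)
# ---------------------------------------------------------------------------

def _posterior_obs_linear(y, w, mu_g, theta: Theta):
    """Vectorized N(mean, var) posterior of X given (y, w) for linear family.

    Combines the three Gaussian sources of information about X by precision
    weighting: prior N(mu_g, sigma_b2), measurement N(w, sigma_eta2) and the
    outcome, which seen as a likelihood in x is N((y-beta0)/beta1, ...)
    contributing precision beta1^2 / sigma_eps2.
    """
    prec = 1.0 / theta.sigma_b2 + 1.0 / theta.sigma_eta2 + theta.beta1**2 / theta.sigma_eps2
    num = (
        mu_g / theta.sigma_b2
        + w / theta.sigma_eta2
        + theta.beta1 * (y - theta.beta0) / theta.sigma_eps2
    )
    return num / prec, 1.0 / prec


def conditional_x_given_yw_linear(y: float, w: float, g: int, theta: Theta) -> PosteriorMoments:
    """Posterior of the true exposure X given observed (y, w), linear family."""
    if theta.family != LINEAR:
        raise ModelError("closed-form X | (y, w) posterior requires the linear family")
    if not (np.isfinite(y) and np.isfinite(w)):
        raise ModelError("non-finite inputs")
    gi = _check_group(g, theta)
    mean, var = _posterior_obs_linear(y, w, theta.mu[gi], theta)
    return PosteriorMoments(mean=float(mean), var=float(var))


def _posterior_missing_linear(y_star, mu_g, theta: Theta):
    """Vectorized joint posterior of (X*, W*) given y* for linear family."""
    b1, s_eps2, s_b2, s_eta2 = theta.beta1, theta.sigma_eps2, theta.sigma_b2, theta.sigma_eta2
    denom = s_eps2 + b1**2 * s_b2
    m = (s_eps2 * mu_g + b1 * s_b2 * (y_star - theta.beta0)) / denom
    v_x = s_eps2 * s_b2 / denom
    v_w = (s_eps2 * s_b2 + s_eps2 * s_eta2 + b1**2 * s_b2 * s_eta2) / denom
    rho = np.sqrt(s_eps2 * s_b2 / (s_eps2 * s_b2 + s_eps2 * s_eta2 + b1**2 * s_b2 * s_eta2))
    return m, v_x, v_w, rho


def conditional_xw_given_y_missing(y_star: float, g: int, theta: Theta) -> PosteriorMoments:
    """Joint posterior of (X*, W*) for a missing-exposure subject, linear family.

    W* = X* + eta is never observed for these subjects, so (X*, W*) | y* is
    bivariate normal with a common mean; W* just adds measurement noise, hence
    ``v_x_star <= v_w_star`` and ``rho = sqrt(v_x_star / v_w_star)``.
    """
    if theta.family != LINEAR:
        raise ModelError("closed-form missing-record posterior requires the linear family")
    if not np.isfinite(y_star):
        raise ModelError("non-finite inputs")
    gi = _check_group(g, theta)
    m, v_x, v_w, rho = _posterior_missing_linear(y_star, theta.mu[gi], theta)
    return PosteriorMoments(
        mean=float(m), var=float(v_x),
        v_x_star=float(v_x), v_w_star=float(v_w), rho=float(rho),
    )


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def _norm_logpdf(x, mean, var):
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def _outcome_loglik(y, x, theta: Theta):
    """log f(y | x) under the outcome model, vectorized."""
    lin = theta.beta0 + theta.beta1 * x
    if theta.family == LINEAR:
        return _norm_logpdf(y, lin, theta.sigma_eps2)
    return y * log_expit(lin) + (1.0 - y) * log_expit(-lin)


def complete_data_loglik(
    x: np.ndarray,
    dataset: GroupedDataset,
    theta: Theta,
    w_star: Optional[np.ndarray] = None,
) -> float:
    """Complete-data log-likelihood given latent exposures for every record.

    Sums log f(y|x) + log f(w|x) + log f(x) over records.  For records whose
    w is missing, the measurement term uses the supplied latent ``w_star``
    (aligned to the missing records in dataset order); if ``w_star`` is None
    those terms are dropped — they involve only the known ``sigma_eta2`` and
    are constant in every estimated parameter.
    """
    x = np.asarray(x, dtype=float)
    if x.size != dataset.n:
        raise ValueError("x must supply one latent exposure per record")
    mu_g = theta.mu[dataset.gidx]
    total = float(np.sum(_outcome_loglik(dataset.y, x, theta)))
    total += float(np.sum(_norm_logpdf(x, mu_g, theta.sigma_b2)))
    obs = dataset.observed
    total += float(np.sum(_norm_logpdf(dataset.w[obs], x[obs], theta.sigma_eta2)))
    if w_star is not None:
        w_star = np.asarray(w_star, dtype=float)
        n_miss = int(np.sum(~obs))
        if w_star.size != n_miss:
            raise ValueError("w_star must align with the missing-exposure records")
        total += float(np.sum(_norm_logpdf(w_star, x[~obs], theta.sigma_eta2)))
    return total


def _gh_nodes(quad_points: int):
    t, wts = np.polynomial.hermite.hermgauss(quad_points)
    return t, wts / np.sqrt(np.pi)


def observed_data_loglik(dataset: GroupedDataset, theta: Theta, quad_points: int = 61) -> float:
    """Observed-data log-likelihood, integrating the latent exposure out.

    Linear family: closed form.  Each observed record has (Y, W) jointly
    normal with means (beta0 + beta1*mu_g, mu_g), var(Y) = beta1^2*sigma_b2 +
    sigma_eps2, var(W) = sigma_b2 + sigma_eta2 and cov = beta1*sigma_b2;
    missing-exposure records contribute the Y marginal.

    Logistic family: Gauss-Hermite quadrature over the latent exposure
    (``quad_points`` nodes), exploiting that for observed records
    f(y, w) = N(w; mu_g, sigma_b2+sigma_eta2) * E[Bern(y | X)] with X drawn
    from its measurement posterior N(m0, v0).
    """
    if quad_points < 21:
        raise ValueError("quad_points must be at least 21")
    obs = dataset.observed
    mu_g = theta.mu[dataset.gidx]
    if theta.family == LINEAR:
        vy = theta.beta1**2 * theta.sigma_b2 + theta.sigma_eps2
        vw = theta.sigma_b2 + theta.sigma_eta2
        c = theta.beta1 * theta.sigma_b2
        dy = dataset.y - (theta.beta0 + theta.beta1 * mu_g)
        dw = dataset.w - mu_g
        det = vy * vw - c * c
        quad = (vw * dy**2 - 2.0 * c * dy * dw + vy * dw**2) / det
        ll_obs = -_LOG_2PI - 0.5 * np.log(det) - 0.5 * quad
        total = float(np.sum(ll_obs[obs]))
        total += float(np.sum(_norm_logpdf(dataset.y[~obs], theta.beta0 + theta.beta1 * mu_g[~obs], vy)))
        return total

    t, wts = _gh_nodes(quad_points)
    s_b2, s_eta2 = theta.sigma_b2, theta.sigma_eta2
    total = 0.0
    # observed records: x | w ~ N(m0, v0); marginal of w is free of the outcome
    if np.any(obs):
        w, y, mg = dataset.w[obs], dataset.y[obs], mu_g[obs]
        v0 = s_b2 * s_eta2 / (s_b2 + s_eta2)
        m0 = (s_b2 * w + s_eta2 * mg) / (s_b2 + s_eta2)
        xk = m0[:, None] + np.sqrt(2.0 * v0) * t[None, :]
        like = np.exp(_outcome_loglik(y[:, None], xk, theta))
        total += float(np.sum(np.log(like @ wts)))
        total += float(np.sum(_norm_logpdf(w, mg, s_b2 + s_eta2)))
    if np.any(~obs):
        y, mg = dataset.y[~obs], mu_g[~obs]
        xk = mg[:, None] + np.sqrt(2.0 * s_b2) * t[None, :]
        like = np.exp(_outcome_loglik(y[:, None], xk, theta))
        total += float(np.sum(np.log(like @ wts)))
    return total
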
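"""Naive, group-based (GBS) and constrained group-based (CGBS) estimators.

The naive estimator regresses the outcome on the error-prone exposure over
complete cases, ignoring measurement error; under classical error its slope is
attenuated by the reliability ratio lambda = var(X) / var(W).

The group-based strategy (GBS) assigns every subject the sample mean of the
observed exposures in their group (single imputation) and fits a standard
regression of all outcomes on these scores.  The constrained variant (CGBS)
first projects the observed group means onto the hypothesized nondecreasing
order by weighted isotonic regression, with the observed sample sizes as
weights, correcting order reversals caused by small measurement campaigns.

Standard errors from GBS/CGBS are model-based but *inflated*: these methods
treat all responses in a group as if observed at the group mean exposure, so
their SEs absorb within-group exposure variability; results carry an
``se_inflated`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .isotonic import pava
from .model import LINEAR, LOGISTIC, GroupedDataset

__all__ = [
    "ScoreAssignment",
    "EstimationResult",
    "SeparationError",
    "fit_naive",
    "assign_scores",
    "fit_group_based",
    "reliability_m",
    "exposure_given_group_mean",
]


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


@dataclass
class ScoreAssignment:
    """Per-group exposure scores: every subject of group g gets score[g-1]."""

    scores: np.ndarray
    constrained: bool
    group_weights: np.ndarray  # observed counts used as isotonic weights


@dataclass
class EstimationResult:
    """Point estimates and inference metadata from one fitting method."""

    method: str
    beta0_hat: float
    beta1_hat: float
    se_beta1: Optional[float] = None
    se_inflated: bool = False
    mu_hat: Optional[np.ndarray] = None
    sigma_b2_hat: Optional[float] = None
    sigma_eps2_hat: Optional[float] = None
    converged: bool = True
    n_iterations: Optional[int] = None
    trace: Optional[List[np.ndarray]] = field(default=None, repr=False)


def _fit_regression(y: np.ndarray, x: np.ndarray, family: str):
    """ML regression of y on a single regressor; returns (b0, b1, se_b1, converged)."""
    X = sm.add_constant(x)
    if family == LINEAR:
        res = sm.OLS(y, X).fit()
        return float(res.params[0]), float(res.params[1]), float(res.bse[1]), True
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(params)) or np.abs(params[1]) > 50:
        raise SeparationError("logistic fit diverged (separation suspected)")
    converged = bool(res.mle_retvals.get("converged", True))
    return float(params[0]), float(params[1]), float(bse[1]), converged


def fit_naive(dataset: GroupedDataset, family: str = LINEAR) -> EstimationResult:
    """Complete-case regression of y on the error-prone exposure w.

    Records with missing exposure are dropped; measurement error is ignored,
    so under classical error the linear slope is biased toward the null by
    the reliability ratio var(X)/var(W).
    """
    obs = dataset.observed
    if not np.any(obs):
        raise ValueError("no records with observed exposure")
    w, y = dataset.w[obs], dataset.y[obs]
    if np.ptp(w) == 0:
        raise ValueError("observed exposure is constant; slope not identifiable")
    b0, b1, se, conv = _fit_regression(y, w, family)
    return EstimationResult(
        method="naive", beta0_hat=b0, beta1_hat=b1, se_beta1=se,
        se_inflated=False, converged=conv,
    )


def assign_scores(dataset: GroupedDataset, constrained: bool = True) -> ScoreAssignment:
    """Group exposure scores: observed group means, isotonized if constrained.

    Isotonic weights are the observed per-group sample sizes.  Every group
    must have at least one observed exposure; unmeasured groups cannot be
    scored by GBS/CGBS (the EM estimator handles them instead).
    """
    counts = dataset.n_g
    if np.any(counts == 0):
        empty = np.nonzero(counts == 0)[0] + 1
        raise ValueError(f"groups {empty.tolist()} have no observed exposures")
    means = dataset.observed_group_means()
    if constrained:
        scores = pava(means, counts).fitted
    else:
        scores = means.copy()
    return ScoreAssignment(scores=scores, constrained=constrained,
                           group_weights=counts.astype(float))


def fit_group_based(
    dataset: GroupedDataset, family: str = LINEAR, constrained: bool = True
) -> EstimationResult:
    """GBS/CGBS fit: regress *all* outcomes on their group exposure scores.

    Subjects with missing exposure still contribute their outcome — the group
    score is a single imputation shared by the whole group.  The model-based
    SE is flagged as inflated.
    """
    assignment = assign_scores(dataset, constrained=constrained)
    x = assignment.scores[dataset.gidx]
    if np.ptp(assignment.scores) == 0:
        raise ValueError("all group scores equal; no exposure contrast")
    b0, b1, se, conv = _fit_regression(dataset.y, x, family)
    return EstimationResult(
        method="cgbs" if constrained else "gbs",
        beta0_hat=b0, beta1_hat=b1, se_beta1=se, se_inflated=True,
        mu_hat=assignment.scores.copy(), converged=conv,
    )


def reliability_m(sigma_b2: float, sigma_eta2: float) -> float:
    """Reliability m = cov(X_gi, Wbar_g) / var(Wbar_g) = sigma_b2 / (sigma_b2 + sigma_eta2).

    The group size cancels: cov(X_gi, Wbar_g) = sigma_b2 / n_g and
    var(Wbar_g) = (sigma_b2 + sigma_eta2) / n_g.  m near 1 means the
    assigned group mean behaves almost like a Berkson-error exposure.
    """
    if sigma_b2 <= 0 or sigma_eta2 <= 0:
        raise ValueError("variances must be positive")
    return sigma_b2 / (sigma_b2 + sigma_eta2)


def exposure_given_group_mean(wbar: float, mu_g: float, m: float) -> float:
    """Diagnostic E[X | Wbar_g] = Wbar_g + (m - 1) * (Wbar_g - mu_g)."""
    return wbar + (m - 1.0) * (wbar - mu_g)
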
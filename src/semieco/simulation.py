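"""Synthetic-data generation and the bias/MSE simulation experiment.

The generator emulates a semi-ecological cohort with G ordered exposure
groups: true exposures X ~ N(mu_g, sigma_b^2) with mu_g = mu_base + (g-1)*delta,
observed exposures W = X + N(0, sigma_eta^2) (classical error), and outcomes
from a linear or logistic model.  Exposure missingness is MCAR: a simple
random sample of n_x of the n_y subjects per group keeps its measurement.

``run_experiment`` fits the competing estimators (naive / GBS / CGBS / CEM,
plus an oracle regression on the true exposures) over replicated draws of
each scenario and tabulates the percent relative bias of the slope,
100 * (mean(beta1_hat) - beta1) / beta1, its Monte-Carlo standard error, and
the empirical MSE of the slope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cem import CemOptions, fit_cem
from .group_estimators import (
    EstimationResult,
    SeparationError,
    fit_group_based,
    fit_naive,
    _fit_regression,
)
from .model import LINEAR, LOGISTIC, GroupedDataset

__all__ = ["Scenario", "generate_dataset", "apply_missingness",
           "run_experiment", "generate_carbonblack_like", "CARBON_BLACK_GROUP_SIZES"]

#: group sizes of the carbon-black application (subjects per job category)
CARBON_BLACK_GROUP_SIZES = (245, 240, 129, 224, 157, 192, 174, 53)


@dataclass
class Scenario:
    """One cell of the simulation design.

    Defaults are the study conditions of the bias experiment: five ordered
    groups of 30 subjects, group means 0.2 + (g-1)*delta, outcome model with
    beta0 = -2 and beta1 = 0.3 (disease risk near 10% in the logistic case),
    200 replications.  ``sigma_eps2`` (linear residual variance) defaults to
    1.0; the slope's relative bias is insensitive to it.
    """

    G: int = 5
    n_y: int = 30
    n_x: Optional[int] = None  # None -> all exposures observed (n_x = n_y)
    delta: float = 0.3
    mu_base: float = 0.2
    sigma_b2: float = 0.6
    sigma_eta2: float = 0.5
    sigma_eps2: float = 1.0
    beta0: float = -2.0
    beta1: float = 0.3
    family: str = LINEAR
    n_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_x is None:
            self.n_x = self.n_y
        if not (1 <= self.n_x <= self.n_y):
            raise ValueError("need 1 <= n_x <= n_y")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if min(self.sigma_b2, self.sigma_eta2, self.sigma_eps2) <= 0:
            raise ValueError("variances must be positive")
        if self.family not in (LINEAR, LOGISTIC):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def mu(self) -> np.ndarray:
        return self.mu_base + self.delta * np.arange(self.G)


def generate_dataset(scenario: Scenario, rng: np.random.Generator) -> GroupedDataset:
    """Draw one complete dataset (all exposures measured) from the scenario.

    True exposures are retained in the ``x_true`` side channel for oracle
    checks; estimators never read it.
    """
    group = np.repeat(np.arange(1, scenario.G + 1), scenario.n_y)
    x = scenario.mu[group - 1] + np.sqrt(scenario.sigma_b2) * rng.standard_normal(group.size)
    w = x + np.sqrt(scenario.sigma_eta2) * rng.standard_normal(group.size)
    lin = scenario.beta0 + scenario.beta1 * x
    if scenario.family == LINEAR:
        y = lin + np.sqrt(scenario.sigma_eps2) * rng.standard_normal(group.size)
    else:
        y = (rng.random(group.size) < expit(lin)).astype(float)
    return GroupedDataset(group=group, y=y, w=w, x_true=x)


def apply_missingness(dataset: GroupedDataset, n_x: int, rng: np.random.Generator) -> GroupedDataset:
    """Keep a simple random sample of n_x exposure measurements per group.

    The remaining measurements are set missing; outcomes are untouched
    (missing completely at random, hence ignorable).
    """
    w = dataset.w.copy()
    for g in range(1, dataset.G + 1):
        idx = np.nonzero(dataset.group == g)[0]
        if n_x > idx.size:
            raise ValueError(f"n_x={n_x} exceeds group {g} size {idx.size}")
        keep = rng.choice(idx, size=n_x, replace=False)
        mask = np.ones(idx.size, dtype=bool)
        mask[np.searchsorted(idx, np.sort(keep))] = False
        w[idx[mask]] = np.nan
    return GroupedDataset(group=dataset.group, y=dataset.y, w=w, x_true=dataset.x_true)


def _fit_one(method: str, dataset: GroupedDataset, scenario: Scenario,
             cem_options: Optional[CemOptions], rep_seed: int) -> EstimationResult:
    if method == "naive":
        return fit_naive(dataset, scenario.family)
    if method == "gbs":
        return fit_group_based(dataset, scenario.family, constrained=False)
    if method == "cgbs":
        return fit_group_based(dataset, scenario.family, constrained=True)
    if method == "cem":
        opts = cem_options or CemOptions(compute_se=False)
        opts = replace(opts, seed=rep_seed, compute_se=False)
        return fit_cem(dataset, scenario.family, scenario.sigma_eta2, opts)
    if method == "oracle":
        b0, b1, se, conv = _fit_regression(dataset.y, dataset.x_true, scenario.family)
        return EstimationResult(method="oracle", beta0_hat=b0, beta1_hat=b1,
                                se_beta1=se, converged=conv)
    raise ValueError(f"unknown method {method!r}")


def run_experiment(
    scenarios: Sequence[Scenario],
    methods: Sequence[str] = ("naive", "gbs", "cgbs"),
    cem_options: Optional[CemOptions] = None,
) -> pd.DataFrame:
    """Replicate each scenario and tabulate slope bias and MSE per method.

    Every replication regenerates the full dataset and its missingness
    pattern from a seed derived deterministically from (scenario seed, cell
    index, replication index).  Replications where a fit fails (logistic
    separation or non-convergence) are dropped for that method and counted.

    Returns a tidy table with one row per (cell, method): percent relative
    bias of the slope, its Monte-Carlo SE, empirical MSE of the slope on the
    raw scale, replication and failure counts.
    """
    if len(scenarios) == 0 or len(methods) == 0:
        raise ValueError("need at least one scenario and one method")
    rows: List[Dict] = []
    for cell, sc in enumerate(scenarios):
        estimates: Dict[str, List[float]] = {m: [] for m in methods}
        failures: Dict[str, int] = {m: 0 for m in methods}
        for rep in range(sc.n_reps):
            ss = np.random.SeedSequence(sc.seed, spawn_key=(cell, rep))
            rng = np.random.default_rng(ss)
            data = generate_dataset(sc, rng)
            if sc.n_x < sc.n_y:
                data = apply_missingness(data, sc.n_x, rng)
            rep_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
            for m in methods:
                try:
                    res = _fit_one(m, data, sc, cem_options, rep_seed)
                except (SeparationError, ValueError, np.linalg.LinAlgError, RuntimeError):
                    failures[m] += 1
                    continue
                if not np.isfinite(res.beta1_hat):
                    failures[m] += 1
                    continue
                estimates[m].append(res.beta1_hat)
        for m in methods:
            b = np.asarray(estimates[m])
            n_ok = b.size
            bias_pct = 100.0 * (b.mean() - sc.beta1) / sc.beta1 if n_ok else np.nan
            mc_se = 100.0 * b.std(ddof=1) / (np.sqrt(n_ok) * abs(sc.beta1)) if n_ok > 1 else np.nan
            mse = float(np.mean((b - sc.beta1) ** 2)) if n_ok else np.nan
            rows.append({
                "family": sc.family, "delta": sc.delta, "sigma_b2": sc.sigma_b2,
                "sigma_eta2": sc.sigma_eta2, "n_y": sc.n_y, "n_x": sc.n_x,
                "method": m, "n_reps": n_ok, "n_failed": failures[m],
                "bias_pct": bias_pct, "mc_se_bias_pct": mc_se, "mse": mse,
            })
    return pd.DataFrame(rows)


def scenario_grid(
    base: Scenario,
    delta: Iterable[float] = (0.3, 0.5),
    sigma_b2: Iterable[float] = (0.3, 0.6, 0.9),
    sigma_eta2: Iterable[float] = (0.25, 0.5, 0.75),
    n_x: Iterable[int] = (10, 20, 30),
) -> List[Scenario]:
    """Full factorial grid of scenarios around a base configuration."""
    return [
        replace(base, delta=d, sigma_b2=sb, sigma_eta2=se, n_x=nx)
        for d, sb, se, nx in itertools.product(delta, sigma_b2, sigma_eta2, n_x)
    ]


def generate_carbonblack_like(
    rng: np.random.Generator,
    beta0: float = 0.0,
    beta1: float = 1.0,
    sigma_eps2: float = 1.0,
    mu_base: float = -0.9,
    delta: float = 0.36,
    sigma_b2: float = 0.41,
    sigma_eta2: float = 0.92,
    n_x: Optional[int] = None,
) -> GroupedDataset:
    """Synthetic fixture shaped like the carbon-black occupational cohort.

    Eight job-category groups with the published group sizes, nondecreasing
    log-exposure means spaced by 0.36 and the published variance components
    (between-subject 0.41, measurement error 0.92); linear outcome with
    user-set coefficients.  This is a *synthetic* structural stand-in for
    integration tests and documentation — the real exposure data are not
    deposited and its estimates are not reproduced here.
    """
    sizes = np.asarray(CARBON_BLACK_GROUP_SIZES)
    group = np.repeat(np.arange(1, sizes.size + 1), sizes)
    mu = mu_base + delta * np.arange(sizes.size)
    x = mu[group - 1] + np.sqrt(sigma_b2) * rng.standard_normal(group.size)
    w = x + np.sqrt(sigma_eta2) * rng.standard_normal(group.size)
    y = beta0 + beta1 * x + np.sqrt(sigma_eps2) * rng.standard_normal(group.size)
    data = GroupedDataset(group=group, y=y, w=w, x_true=x)
    if n_x is not None:
        data = apply_missingness(data, n_x, rng)
    return data
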
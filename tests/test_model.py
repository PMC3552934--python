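"""Closed-form conditionals and likelihoods against quadrature oracles."""

import dataclasses

import numpy as np
import pytest
from scipy.special import log_expit
from scipy.stats import norm

from semieco import (
    GroupedDataset,
    Theta,
    complete_data_loglik,
    conditional_x_given_yw_linear,
    conditional_xw_given_y_missing,
    observed_data_loglik,
)

from conftest import quad_posterior_moments_1d


def make_theta(**kw):
    base = dict(beta0=0.0, beta1=1.0, mu=np.array([0.0]), sigma_b2=1.0,
                sigma_eta2=1.0, family="linear", sigma_eps2=1.0)
    base.update(kw)
    return Theta(**base)


class TestConditionalObserved:
    def test_flat_outcome_averages_prior_and_measurement(self):
        theta = make_theta(beta1=0.0)
        post = conditional_x_given_yw_linear(y=5.0, w=2.0, g=1, theta=theta)
        assert post.mean == pytest.approx(1.0)
        assert post.var == pytest.approx(0.5)

    def test_unit_variance_case_against_quadrature(self):
        theta = make_theta()
        post = conditional_x_given_yw_linear(y=1.0, w=1.0, g=1, theta=theta)
        assert post.mean == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert post.var == pytest.approx(1.0 / 3.0, abs=1e-12)
        m, v = quad_posterior_moments_1d(1.0, 1.0, 0.0, theta)
        assert post.mean == pytest.approx(m, abs=1e-6)
        assert post.var == pytest.approx(v, abs=1e-6)

    def test_vanishing_error_recovers_the_measurement(self):
        theta = make_theta(sigma_eta2=1e-12)
        post = conditional_x_given_yw_linear(y=0.3, w=2.0, g=1, theta=theta)
        assert post.mean == pytest.approx(2.0, abs=1e-6)
        assert post.var == pytest.approx(0.0, abs=1e-6)

    def test_randomized_parameters_match_quadrature(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            theta = make_theta(
                beta0=rng.normal(), beta1=rng.normal(scale=1.5),
                mu=np.array([rng.normal()]),
                sigma_b2=rng.uniform(0.2, 2.0), sigma_eta2=rng.uniform(0.2, 2.0),
                sigma_eps2=rng.uniform(0.2, 2.0),
            )
            y, w = rng.normal(scale=2), rng.normal(scale=2)
            post = conditional_x_given_yw_linear(y, w, 1, theta)
            m, v = quad_posterior_moments_1d(y, w, theta.mu[0], theta)
            assert post.mean == pytest.approx(m, abs=1e-6)
            assert post.var == pytest.approx(v, abs=1e-6)
            # conditioning can only reduce uncertainty relative to the prior
            assert post.var <= theta.sigma_b2 + 1e-12

    def test_rejects_logistic_family_and_bad_inputs(self):
        with pytest.raises(ValueError):
            conditional_x_given_yw_linear(1.0, 1.0, 1, make_theta(family="logistic", sigma_eps2=None))
        with pytest.raises(ValueError):
            conditional_x_given_yw_linear(np.nan, 1.0, 1, make_theta())


def quad_posterior_missing_2d(y_star, mu_g, theta, span=10.0, npts=1201):
    """2-D trapezoidal oracle for the joint (X*, W*) posterior given y*."""
    sb, seta = np.sqrt(theta.sigma_b2), np.sqrt(theta.sigma_eta2)
    x = np.linspace(mu_g - span * sb, mu_g + span * sb, npts)
    wlo = x.min() - span * seta
    w = np.linspace(wlo, x.max() + span * seta, npts)
    X, W = np.meshgrid(x, w, indexing="ij")
    dens = (
        norm.pdf(y_star, theta.beta0 + theta.beta1 * X, np.sqrt(theta.sigma_eps2))
        * norm.pdf(W, X, seta)
        * norm.pdf(X, mu_g, sb)
    )
    z = np.trapezoid(np.trapezoid(dens, w, axis=1), x)

    def e(f):
        return np.trapezoid(np.trapezoid(f * dens, w, axis=1), x) / z

    mx, mw = e(X), e(W)
    vx, vw = e(X**2) - mx**2, e(W**2) - mw**2
    rho = (e(X * W) - mx * mw) / np.sqrt(vx * vw)
    return mx, mw, vx, vw, rho


class TestConditionalMissing:
    def test_flat_outcome_reduces_to_prior_plus_error(self):
        theta = make_theta(beta1=0.0, mu=np.array([0.7]), sigma_b2=0.5, sigma_eta2=1.5)
        post = conditional_xw_given_y_missing(3.0, 1, theta)
        assert post.mean == pytest.approx(0.7)
        assert post.v_x_star == pytest.approx(0.5)
        assert post.v_w_star == pytest.approx(2.0)
        assert post.rho == pytest.approx(np.sqrt(0.5 / 2.0))

    def test_unit_variance_case(self):
        post = conditional_xw_given_y_missing(1.0, 1, make_theta())
        assert post.mean == pytest.approx(0.5)
        assert post.v_x_star == pytest.approx(0.5)
        assert post.v_w_star == pytest.approx(1.5)
        assert post.rho == pytest.approx(1.0 / np.sqrt(3.0), abs=1e-4)

    def test_randomized_parameters_match_2d_quadrature(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            theta = make_theta(
                beta0=rng.normal(), beta1=rng.normal(),
                mu=np.array([rng.normal()]),
                sigma_b2=rng.uniform(0.3, 1.5), sigma_eta2=rng.uniform(0.3, 1.5),
                sigma_eps2=rng.uniform(0.3, 1.5),
            )
            y = rng.normal()
            post = conditional_xw_given_y_missing(y, 1, theta)
            mx, mw, vx, vw, rho = quad_posterior_missing_2d(y, theta.mu[0], theta)
            assert post.mean == pytest.approx(mx, abs=1e-5)
            assert post.mean == pytest.approx(mw, abs=1e-5)
            assert post.v_x_star == pytest.approx(vx, abs=1e-5)
            assert post.v_w_star == pytest.approx(vw, abs=1e-5)
            assert post.rho == pytest.approx(rho, abs=1e-5)
            assert post.v_x_star <= post.v_w_star

    def test_rho_is_one_without_measurement_error(self):
        theta = make_theta(sigma_eta2=1e-14)
        assert conditional_xw_given_y_missing(0.0, 1, theta).rho == pytest.approx(1.0, abs=1e-6)


class TestCompleteDataLoglik:
    def test_three_standard_kernels_at_their_modes(self):
        theta = make_theta(beta0=0.5, beta1=2.0, mu=np.array([1.0]))
        x = 1.0
        data = GroupedDataset(group=[1], y=[theta.beta0 + theta.beta1 * x], w=[x])
        val = complete_data_loglik(np.array([x]), data, theta)
        assert val == pytest.approx(-1.5 * np.log(2 * np.pi), abs=1e-12)

    def test_additive_over_records(self):
        theta = make_theta(mu=np.array([0.0, 1.0]))
        one = GroupedDataset(group=[1, 2], y=[0.3, -0.2], w=[0.1, 1.2])
        total = complete_data_loglik(np.array([0.2, 0.9]), one, theta)
        a = complete_data_loglik(np.array([0.2]), GroupedDataset(group=[1], y=[0.3], w=[0.1]),
                                 make_theta(mu=np.array([0.0])))
        b = complete_data_loglik(np.array([0.9]), GroupedDataset(group=[1], y=[-0.2], w=[1.2]),
                                 make_theta(mu=np.array([1.0])))
        assert total == pytest.approx(a + b, abs=1e-10)

    @pytest.mark.parametrize("family", ["linear", "logistic"])
    def test_matches_direct_density_sum(self, family):
        rng = np.random.default_rng(8)
        theta = make_theta(mu=np.array([0.0, 0.6]), family=family,
                           sigma_eps2=1.3 if family == "linear" else None,
                           beta0=-1.0, beta1=0.8, sigma_b2=0.7, sigma_eta2=0.4)
        g = rng.integers(1, 3, size=10)
        x = rng.normal(size=10)
        w = x + rng.normal(scale=0.6, size=10)
        y = rng.normal(size=10) if family == "linear" else rng.integers(0, 2, 10).astype(float)
        w[7] = np.nan  # one missing-exposure record, measurement term dropped
        data = GroupedDataset(group=g, y=y, w=w)
        expected = 0.0
        for i in range(10):
            lin = theta.beta0 + theta.beta1 * x[i]
            if family == "linear":
                expected += norm.logpdf(y[i], lin, np.sqrt(theta.sigma_eps2))
            else:
                expected += float(y[i] * log_expit(lin) + (1 - y[i]) * log_expit(-lin))
            if np.isfinite(w[i]):
                expected += norm.logpdf(w[i], x[i], np.sqrt(theta.sigma_eta2))
            expected += norm.logpdf(x[i], theta.mu[g[i] - 1], np.sqrt(theta.sigma_b2))
        assert complete_data_loglik(x, data, theta) == pytest.approx(expected, abs=1e-9)

    def test_length_mismatch_rejected(self):
        data = GroupedDataset(group=[1, 1], y=[0.0, 1.0], w=[0.1, 0.2])
        with pytest.raises(ValueError):
            complete_data_loglik(np.array([0.0]), data, make_theta())


def quad_observed_loglik(data, theta, npts=4001, span=10.0):
    """Record-wise 1-D quadrature oracle for the observed-data likelihood."""
    total = 0.0
    for i in range(data.n):
        mu_g = theta.mu[data.group[i] - 1]
        sb = np.sqrt(theta.sigma_b2)
        x = np.linspace(mu_g - span * sb, mu_g + span * sb, npts)
        lin = theta.beta0 + theta.beta1 * x
        if theta.family == "linear":
            f = norm.pdf(data.y[i], lin, np.sqrt(theta.sigma_eps2))
        else:
            f = np.exp(data.y[i] * log_expit(lin) + (1 - data.y[i]) * log_expit(-lin))
        if np.isfinite(data.w[i]):
            f = f * norm.pdf(data.w[i], x, np.sqrt(theta.sigma_eta2))
        total += np.log(np.trapezoid(f * norm.pdf(x, mu_g, sb), x))
    return total


class TestObservedDataLoglik:
    def test_zero_slope_factorizes_into_y_and_w_terms(self):
        theta = make_theta(beta1=0.0, beta0=0.4, mu=np.array([0.3]))
        data = GroupedDataset(group=[1, 1], y=[0.1, 0.9], w=[0.5, np.nan])
        got = observed_data_loglik(data, theta)
        expected = (
            norm.logpdf(0.1, 0.4, 1.0) + norm.logpdf(0.9, 0.4, 1.0)
            + norm.logpdf(0.5, 0.3, np.sqrt(2.0))
        )
        assert got == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("family", ["linear", "logistic"])
    def test_matches_quadrature_on_small_dataset(self, family):
        rng = np.random.default_rng(5)
        theta = make_theta(mu=np.array([0.0, 0.8]), family=family,
                           sigma_eps2=0.9 if family == "linear" else None,
                           beta0=-0.5, beta1=0.7, sigma_b2=0.5, sigma_eta2=0.8)
        y = rng.normal(size=6) if family == "linear" else rng.integers(0, 2, 6).astype(float)
        w = rng.normal(size=6)
        w[[1, 4]] = np.nan
        data = GroupedDataset(group=[1, 1, 1, 2, 2, 2], y=y, w=w)
        got = observed_data_loglik(data, theta, quad_points=81)
        assert got == pytest.approx(quad_observed_loglik(data, theta), abs=1e-8)

    def test_degenerate_error_reduces_to_plain_logistic_likelihood(self):
        theta = make_theta(family="logistic", sigma_eps2=None, sigma_eta2=1e-12,
                           beta0=-1.0, beta1=0.5, mu=np.array([0.2]), sigma_b2=0.7)
        w = np.array([0.3, -0.1, 1.1])
        y = np.array([1.0, 0.0, 1.0])
        data = GroupedDataset(group=[1, 1, 1], y=y, w=w)
        got = observed_data_loglik(data, theta, quad_points=95)
        lin = theta.beta0 + theta.beta1 * w
        expected = float(np.sum(y * log_expit(lin) + (1 - y) * log_expit(-lin)))
        expected += float(np.sum(norm.logpdf(w, 0.2, np.sqrt(0.7 + 1e-12))))
        assert got == pytest.approx(expected, abs=1e-5)

    def test_too_few_quadrature_points_rejected(self):
        data = GroupedDataset(group=[1], y=[1.0], w=[0.0])
        with pytest.raises(ValueError):
            observed_data_loglik(data, make_theta(), quad_points=11)


class TestContainers:
    def test_theta_family_variance_coupling(self):
        with pytest.raises(ValueError):
            make_theta(family="logistic")  # keeps sigma_eps2=1.0
        with pytest.raises(ValueError):
            make_theta(sigma_eps2=None)
        with pytest.raises(ValueError):
            make_theta(sigma_b2=-1.0)

    def test_vector_round_trip(self):
        theta = make_theta(mu=np.array([0.1, 0.2, 0.4]))
        again = theta.with_vector(theta.to_vector())
        assert dataclasses.asdict(theta).keys() == dataclasses.asdict(again).keys()
        np.testing.assert_allclose(again.to_vector(), theta.to_vector())

    def test_dataset_counts_and_validation(self):
        data = GroupedDataset(group=[1, 1, 2, 2, 2], y=[0, 1, 0, 1, 1],
                              w=[0.5, np.nan, 1.0, np.nan, np.nan])
        np.testing.assert_array_equal(data.n_g, [1, 1])
        np.testing.assert_array_equal(data.n_g_star, [1, 2])
        np.testing.assert_array_equal(data.n_g + data.n_g_star, data.n_per_group)
        with pytest.raises(ValueError):
            GroupedDataset(group=[1, 3], y=[0.0, 1.0], w=[0.1, 0.2])  # gap in labels
        with pytest.raises(ValueError):
            GroupedDataset(group=[1, 1], y=[0.0, np.nan], w=[0.1, 0.2])  # missing outcome
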
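import numpy as np
import pytest

from semieco import GroupedDataset, Scenario, Theta, generate_dataset

# Table of five observed group means with an order reversal in the first pair
# and the last pair, plus observed sample sizes, used across isotonic tests.
GROUP_MEANS = (0.7755, 0.6229, 1.8207, 2.2878, 1.7054)
GROUP_WEIGHTS = (4.0, 3.0, 5.0, 3.0, 4.0)
ISOTONIZED = (0.7101, 0.7101, 1.8207, 1.9550, 1.9550)


@pytest.fixture
def rng():
    return np.random.default_rng(20120904)


@pytest.fixture
def linear_theta():
    return Theta(beta0=-2.0, beta1=0.3, mu=np.array([0.2, 0.5, 0.8, 1.1, 1.4]),
                 sigma_b2=0.6, sigma_eta2=0.5, family="linear", sigma_eps2=1.0)


@pytest.fixture
def logistic_theta():
    return Theta(beta0=-2.0, beta1=0.3, mu=np.array([0.2, 0.5, 0.8, 1.1, 1.4]),
                 sigma_b2=0.6, sigma_eta2=0.5, family="logistic")


@pytest.fixture
def small_linear_dataset(rng, linear_theta):
    """30 records across 5 groups, a third with missing exposure."""
    sc = Scenario(n_y=6, n_x=4, seed=11)
    return _with_missing(sc, rng)


def _with_missing(scenario, rng):
    from semieco import apply_missingness

    data = generate_dataset(scenario, rng)
    if scenario.n_x < scenario.n_y:
        data = apply_missingness(data, scenario.n_x, rng)
    return data


def quad_posterior_moments_1d(y, w, mu_g, theta, span=12.0, npts=20001):
    """Brute-force posterior moments of X | (y, w) by trapezoidal quadrature."""
    from scipy.stats import norm
    from scipy.special import expit

    sd = np.sqrt(theta.sigma_b2)
    x = np.linspace(mu_g - span * sd, mu_g + span * sd, npts)
    lin = theta.beta0 + theta.beta1 * x
    if theta.family == "linear":
        ly = norm.pdf(y, lin, np.sqrt(theta.sigma_eps2))
    else:
        p = expit(lin)
        ly = p if y > 0.5 else 1.0 - p
    dens = ly * norm.pdf(w, x, np.sqrt(theta.sigma_eta2)) * norm.pdf(x, mu_g, sd)
    z = np.trapezoid(dens, x)
    m = np.trapezoid(x * dens, x) / z
    m2 = np.trapezoid(x**2 * dens, x) / z
    return m, m2 - m**2
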
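import numpy as np
import pytest
from scipy.special import ndtr

from obid import (
    ExpertRatings,
    MCMCSettings,
    analytic_prior_from_bias,
    build_lambda_prior,
    prior_from_expert_posterior,
    prior_sample_size,
    relevance_interval,
    sample_expert_posterior,
)
from obid.expert import flat_prior
from obid.transforms import fisher_z, lambda_from_rho


# ---------------------------------------------------------------------------
# relevance scale


@pytest.mark.parametrize(
    "rating, scale, interval",
    [
        (1, "cohen", (0.00, 0.10)),
        (2, "cohen", (0.10, 0.30)),
        (3, "cohen", (0.30, 0.50)),
        (4, "cohen", (0.50, 1.00)),
        (2, "equal", (0.25, 0.50)),
        (4, "equal", (0.75, 1.00)),
    ],
)
def test_relevance_interval(rating, scale, interval):
    assert relevance_interval(rating, scale) == interval


@pytest.mark.parametrize("bad", [0, 5, -1])
def test_relevance_interval_rejects_out_of_scale(bad):
    with pytest.raises(ValueError):
        relevance_interval(bad)


def test_ratings_validation():
    with pytest.raises(ValueError, match="row 1.*column 1|column 1.*row 1"):
        ExpertRatings([[4, 4], [4, 5]])
    r = ExpertRatings([[4, 4, 4], [4, 4, 4]])
    assert (r.n_experts, r.n_items) == (2, 3)


# ---------------------------------------------------------------------------
# prior construction


@pytest.mark.parametrize("K, n0", [(6, 30), (1, 5), (16, 80)])
def test_prior_sample_size(K, n0):
    assert prior_sample_size(K) == n0


def test_prior_sample_size_requires_experts():
    with pytest.raises(ValueError):
        prior_sample_size(0)


@pytest.mark.parametrize(
    "mu, n0, mean, var",
    [
        (0.0, 10, 0.0, 0.1),
        (0.5493061443340549, 30, 0.5773502691896258, 0.04444444444444444),
    ],
)
def test_build_lambda_prior_closed_form(mu, n0, mean, var):
    m, v = build_lambda_prior(mu, n0)
    assert m == pytest.approx(mean, abs=1e-12)
    assert v == pytest.approx(var, abs=1e-12)
    # same closed forms written via the exponential expression
    assert m == pytest.approx((np.exp(2 * mu) - 1) / (2 * np.exp(mu)), abs=1e-12)
    assert v == pytest.approx((np.exp(2 * mu) + 1) ** 2 / (4 * n0 * np.exp(2 * mu)),
                              abs=1e-12)


def test_lambda_prior_mean_matches_discrimination_transform():
    mu = np.linspace(-2.5, 2.5, 41)
    mean, _ = build_lambda_prior(mu, 12)
    assert np.allclose(mean, lambda_from_rho(np.tanh(mu)), atol=1e-12)


def test_lambda_prior_variance_scales_inversely_with_n0():
    _, v1 = build_lambda_prior(0.7, 5)
    _, v2 = build_lambda_prior(0.7, 50)
    assert v2 == pytest.approx(v1 / 10, rel=1e-12)
    with pytest.raises(ValueError):
        build_lambda_prior(0.7, 0)


def test_flat_prior_is_the_stated_noninformative_form():
    p = flat_prior(7)
    assert np.all(p.lambda_mean == 0) and np.all(p.lambda_var == 4.0)
    assert not p.informative and p.alpha_var == 1.0


# ---------------------------------------------------------------------------
# bias-conditioned analytic priors


def test_bias_vectors_for_six_items():
    rho_t = np.array([0.30, 0.50, 0.70, 0.70, 0.30, 0.50])
    mod = analytic_prior_from_bias(rho_t, "moderate", 6)
    high = analytic_prior_from_bias(rho_t, "high", 6)
    assert np.allclose(np.tanh(mod.mu0), [0.40, 0.60, 0.80, 0.80, 0.40, 0.60])
    assert np.allclose(np.tanh(high.mu0), [0.65, 0.75, 0.85, 0.85, 0.65, 0.75])
    unb = analytic_prior_from_bias(rho_t, "unbiased", 6)
    assert np.allclose(np.tanh(unb.mu0), rho_t)
    assert unb.n0 == 30


def test_high_bias_midpoint_never_reaches_one():
    rho = np.linspace(0.01, 0.999, 200)
    prior = analytic_prior_from_bias(rho, "high", 3)
    assert np.all(np.tanh(prior.mu0) < 1.0)


def test_moderate_bias_overflow_is_an_error():
    with pytest.raises(ValueError):
        analytic_prior_from_bias([0.95], "moderate", 6)


# ---------------------------------------------------------------------------
# expert posterior sampler vs an independent quadrature oracle


def _quadrature_posterior_mean_mu(z_lo, z_hi, n_experts):
    """Deterministic 2-D quadrature over (mu, log sigma^2) for one item.

    Independent oracle for the censored hierarchy: posterior
    propto N(mu; 0, 3) * IG(sigma^2; 1e-5, 1e-5) * prod_k P(z_k in [lo, hi]).
    """
    eps = 1e-5
    t = np.linspace(-20, 120, 3000)
    mu = np.linspace(-10, 12, 1100)
    T, M = np.meshgrid(t, mu, indexing="ij")
    sd = np.exp(T / 2)
    log_prior = -M**2 / 6 - eps * T - eps * np.exp(-T)
    p = np.maximum(ndtr((z_hi - M) / sd) - ndtr((z_lo - M) / sd), 0.0)
    w = np.exp(log_prior) * p**n_experts
    z = np.trapezoid(np.trapezoid(w, mu, axis=1), t)
    return np.trapezoid(np.trapezoid(w * M, mu, axis=1), t) / z


@pytest.mark.parametrize(
    "rating, rho_window",
    [(4, (0.50, 1.00)), (3, (0.25, 0.55))],
)
def test_unanimous_panel_matches_quadrature_oracle(rating, rho_window):
    lo, hi = relevance_interval(rating, "cohen")
    z_lo = fisher_z(lo)
    z_hi = fisher_z(min(hi, 1 - 1e-9))
    oracle_mu = _quadrature_posterior_mean_mu(z_lo, z_hi, n_experts=2)

    post = sample_expert_posterior(
        ExpertRatings([[rating], [rating]]),
        "cohen",
        MCMCSettings(chains=3, burn_in=2000, iterations=8000, seed=5),
    )
    assert post.mu0[0] == pytest.approx(oracle_mu, abs=0.08)
    assert rho_window[0] <= np.tanh(post.mu0[0]) <= rho_window[1]


def test_large_unanimous_panel_concentrates_in_rated_band():
    # with many agreeing experts the posterior mean lands inside the band
    post = sample_expert_posterior(
        ExpertRatings(np.full((32, 1), 3)),
        "cohen",
        MCMCSettings(chains=2, burn_in=1000, iterations=4000, seed=11),
    )
    assert 0.28 <= np.tanh(post.mu0[0]) <= 0.52


def test_posterior_bookkeeping_and_prior_handoff():
    ratings = ExpertRatings([[3, 4], [4, 4], [2, 3]])
    settings = MCMCSettings(chains=2, burn_in=200, iterations=500, seed=3)
    post = sample_expert_posterior(ratings, "cohen", settings)
    assert post.mu_draws.shape == (2 * 500, 2)
    assert post.sigma2_draws.shape == (1000,)
    assert np.all(post.sigma2_draws > 0)
    assert post.n0 == 15

    prior = prior_from_expert_posterior(post)
    mean, var = build_lambda_prior(post.mu0, post.n0)
    assert np.allclose(prior.lambda_mean, mean) and np.allclose(prior.lambda_var, var)
    override = prior_from_expert_posterior(post, n0=60)
    assert np.allclose(override.lambda_var, build_lambda_prior(post.mu0, 60)[1])


def test_expert_sampler_is_deterministic_given_seed():
    ratings = ExpertRatings([[1, 4], [2, 3]])
    s = MCMCSettings(chains=1, burn_in=50, iterations=100, seed=9)
    a = sample_expert_posterior(ratings, "equal", s)
    b = sample_expert_posterior(ratings, "equal", s)
    assert np.array_equal(a.mu_draws, b.mu_draws)
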
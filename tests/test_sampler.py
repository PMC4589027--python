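import numpy as np
import pytest

from obid import (
    MCMCSettings,
    ParticipantResponses,
    PriorSpec,
    factor_scores,
    fit_obid,
    flat_prior,
    percentile_cutpoints,
    recommended_tuning,
    rho_from_lambda,
    simulate_responses,
    true_rho,
)
from obid.transforms import lambda_from_rho


# ---------------------------------------------------------------------------
# deterministic pieces


@pytest.mark.parametrize(
    "C, expected",
    [
        (2, [0.0]),
        (4, [-0.6744897501960817, 0.0, 0.6744897501960817]),
        (5, [-0.8416212335729143, -0.2533471031357997, 0.2533471031357997,
             0.8416212335729143]),
    ],
)
def test_percentile_cutpoints(C, expected):
    got = percentile_cutpoints(C)
    assert np.allclose(got, expected, atol=1e-9)
    assert np.all(np.diff(got) > 0) or len(got) == 1


def test_percentile_cutpoints_requires_two_categories():
    with pytest.raises(ValueError):
        percentile_cutpoints(1)


@pytest.mark.parametrize(
    "N, override, expected",
    [(50, False, 1.0), (100, False, 0.7), (200, False, 0.5), (500, False, 0.3),
     (36, True, 2.0), (36, False, 1.0)],
)
def test_recommended_tuning(N, override, expected):
    assert recommended_tuning(N, small_sample_override=override) == expected


def test_responses_validation():
    with pytest.raises(ValueError, match="row 1.*column 1|column 1"):
        ParticipantResponses(np.array([[1, 2], [1, 0], [2, 2]]))
    with pytest.raises(ValueError, match="exceeds"):
        ParticipantResponses(np.array([[1, 2], [1, 6], [2, 2]]),
                             categories=[5, 5])
    with pytest.raises(ValueError, match="missing|integers"):
        ParticipantResponses(np.array([[1.0, 2.5], [1.0, 2.0]]))


def test_fit_rejects_degenerate_item():
    y = np.column_stack([np.full(30, 2), np.tile([1, 2, 3], 10)])
    data = ParticipantResponses(y, categories=[3, 3])
    with pytest.raises(ValueError, match="item1"):
        fit_obid(data, flat_prior(2), MCMCSettings(chains=1, burn_in=10, iterations=10))


# ---------------------------------------------------------------------------
# sampler behaviour on the shared workhorse fit (N=150, P=6, C=5, 3 chains)


def test_cutpoints_strictly_ordered_in_every_draw(recovery_fit):
    _, _, draws = recovery_fit
    cuts = draws.cut_draws  # (chains, draws, P, C-1); first column is the 0 anchor
    assert np.all(cuts[..., 0] == 0.0)
    assert np.all(np.diff(cuts, axis=-1) > 0)


def test_acceptance_reported_per_item_within_unit_interval(recovery_fit):
    _, _, draws = recovery_fit
    acc = draws.acceptance
    assert acc.shape == (3, 6)
    assert np.all((acc > 0) & (acc < 1))


def test_chains_agree_on_posterior_correlations(recovery_fit):
    _, _, draws = recovery_fit
    per_chain = rho_from_lambda(draws.lambda_draws).mean(axis=1)  # (chains, P)
    spread = per_chain.max(axis=0) - per_chain.min(axis=0)
    assert np.all(spread < 0.05)


def test_posterior_recovers_generating_correlations_loosely(recovery_fit):
    _, _, draws = recovery_fit
    assert np.all(np.abs(draws.posterior_mean_rho() - true_rho(6)) < 0.15)


def test_factor_scores_track_true_scores(recovery_fit):
    # mixed loadings (.3-.7) cap attainable score reliability; sqrt of the
    # test-score reliability is ~0.86 here, so 0.7 leaves room for one
    # unlucky dataset
    _, f_true, draws = recovery_fit
    scores = factor_scores(draws)
    assert scores.shape == f_true.shape
    assert np.corrcoef(scores, f_true)[0, 1] > 0.7


def test_summary_frame_contract(recovery_fit):
    _, _, draws = recovery_fit
    s = draws.summary()
    assert list(s.columns) == ["item", "alpha_mean", "lambda_mean", "rho_mean",
                               "rho_sd", "acceptance"]
    assert len(s) == 6 and np.all(s["rho_sd"] > 0)


# ---------------------------------------------------------------------------
# smaller targeted fits


def test_prior_dominance_limit():
    # a near-point-mass prior at lambda(rho=0.5) pins the posterior regardless of data
    data = simulate_responses(60, 3, 5, [0.7, 0.7, 0.7], seed=2)
    prior = PriorSpec(lambda_mean=np.full(3, lambda_from_rho(0.5)),
                      lambda_var=np.full(3, 1e-8))
    draws = fit_obid(data, prior, MCMCSettings(chains=1, burn_in=300,
                                               iterations=800, seed=4))
    assert np.allclose(draws.posterior_mean_rho(), 0.5, atol=0.01)


def test_binary_items_have_no_cutpoint_step():
    data = simulate_responses(80, 4, 2, [0.5, 0.5, 0.5, 0.5], seed=6)
    draws = fit_obid(data, flat_prior(4), MCMCSettings(chains=1, burn_in=200,
                                                       iterations=400, seed=8))
    assert np.all(np.isnan(draws.acceptance))
    assert draws.cut_draws.shape[-1] == 1  # only the anchored cut-point


def test_sampler_deterministic_given_seed():
    data = simulate_responses(40, 3, 4, [0.5, 0.6, 0.4], seed=12)
    s = MCMCSettings(chains=2, burn_in=50, iterations=120, seed=3)
    a = fit_obid(data, flat_prior(3), s)
    b = fit_obid(data, flat_prior(3), s)
    assert np.array_equal(a.lambda_draws, b.lambda_draws)
    assert np.array_equal(a.cut_draws, b.cut_draws)
    assert np.array_equal(a.f_mean, b.f_mean)


@pytest.mark.parametrize("N", [50, 100, 200, 500])
def test_recommended_tuning_yields_target_acceptance_band(N):
    # the N-matched tuning values keep mean cut-point acceptance in 20-50%
    data = simulate_responses(N, 6, 5, true_rho(6), seed=N)
    draws = fit_obid(data, flat_prior(6),
                     MCMCSettings(chains=1, burn_in=500, iterations=1500,
                                  tuning=recommended_tuning(N), seed=N + 1))
    assert 0.20 <= float(np.nanmean(draws.acceptance)) <= 0.50


def test_factor_scores_requires_draws():
    from obid.sampler import PosteriorDraws

    empty = PosteriorDraws(
        alpha_draws=np.empty((1, 0, 2)), lambda_draws=np.empty((1, 0, 2)),
        cut_draws=np.empty((1, 0, 2, 1)), f_mean=np.empty((1, 0)),
        acceptance=np.full((1, 2), np.nan), categories=np.array([2, 2]),
    )
    with pytest.raises(ValueError):
        factor_scores(empty)


def test_flat_prior_consistency_at_large_n():
    # posterior mean rho converges to the generating values as N grows;
    # averaged over datasets because a single N=1000 draw still carries
    # loading noise of sd ~ 0.03 per item.  The classical fit on the same
    # data provides a second, independent estimation route: at this N the
    # two must agree item by item.
    from obid import fit_ordinal_cfa

    means = []
    for seed in (21, 22, 23, 24, 25):
        data = simulate_responses(1000, 6, 5, true_rho(6), seed=seed)
        draws = fit_obid(data, flat_prior(6),
                         MCMCSettings(chains=1, burn_in=400, iterations=1000,
                                      seed=seed))
        rho_hat = draws.posterior_mean_rho()
        means.append(rho_hat)
        cfa = fit_ordinal_cfa(data)
        assert cfa.usable
        assert np.all(np.abs(rho_hat - cfa.loadings) < 0.03)
    assert np.all(np.abs(np.mean(means, axis=0) - true_rho(6)) < 0.05)
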
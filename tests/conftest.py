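import numpy as np
import pytest

from obid import MCMCSettings, fit_obid, flat_prior, simulate_responses, true_rho


@pytest.fixture(scope="session")
def recovery_fit():
    """Workhorse flat-prior fit on six-item five-category data (N = 150, 3 chains).

    Shared by sampler sanity checks (chain agreement, cut-point ordering,
    acceptance bookkeeping, factor-score recovery).
    """
    data, f_true = simulate_responses(150, 6, 5, true_rho(6), seed=42,
                                      return_true_scores=True)
    draws = fit_obid(
        data,
        flat_prior(6),
        MCMCSettings(chains=3, burn_in=800, iterations=1500, seed=7),
    )
    return data, f_true, draws
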
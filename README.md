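# obid — Ordinal Bayesian Instrument Development

`obid` is a toolkit for validating ordinal survey instruments — in
particular patient-reported outcome measures (PROMs) — when the available
participant sample is small (rare diseases, minority subpopulations,
pediatric cohorts).  It integrates the two kinds of validity evidence that
classical psychometrics keeps separate: subject experts' content-validity
ratings become informative priors for a Bayesian item response theory (IRT)
model of the participants' ordinal responses, so construct validity can be
established with far fewer participants than classical ordinal confirmatory
factor analysis (CFA) requires.

## The model

Participant `i`'s ordinal response to item `j` is a censored continuous
latent response (a two-parameter probit IRT model, equivalently a one-factor
ordinal factor model):

    y_ij = c        iff  y*_ij ∈ (T_{j,c-1}, T_jc]
    y*_ij = α_j + λ_j f_i + ε_ij,   f_i ~ N(0,1),  ε_ij ~ N(0,1)

where `α_j` is the (negative) item difficulty, `λ_j` the item
discrimination, `T_j` ordered cut-points and `f_i` the latent trait.  The
standardized loading — the **item-to-domain correlation** — is
`ρ_j = λ_j / √(1 + λ_j²)`, and `ρ_j²` is the item's reliability.

Experts rate each item's relevance on a four-point scale; a rating is read
as an interval statement about the expert's latent item-to-domain
correlation `ρ_jk` (Cohen bands 0.10/0.30/0.50 by default, or equally spaced
quarters).  A hierarchical model on the Fisher-z scale pools the panel,

    g(ρ_jk) = μ_j + e_jk,  e_jk ~ N(0, σ²),   g(ρ) = ½ log((1+ρ)/(1−ρ)),

with `μ_j ~ N(0, 3)` and `σ² ~ InvGamma(1e-5, 1e-5)`.  With a prior sample
size of `n0 = 5K` (each of the `K` experts counts as roughly five
participants), the delta method gives the discrimination prior

    λ_j ~ N( sinh(μ_j),  cosh(μ_j)² / n0 ),

which is updated with the participant data by a
Metropolis–Hastings-within-Gibbs sampler (Cowles-style cut-point proposals;
the tuning values 1.00/0.70/0.50/0.30 keep acceptance in the 20–50% band at
N = 50/100/200/500).  Predictive validity is summarized by
`γ = corr(E(f), f_true)`.

A classical comparator — one-factor ordinal CFA via two-stage polychoric
correlations and least squares — and a five-way factorial simulation engine
(P × C × N × K × expert bias, 432 cells) are included for benchmarking; the
simulation records MSE and squared bias of the `ρ_j` estimates, MSE of `γ`,
and the comparator's nonconvergence / out-of-bound (Heywood) rates.

## Worked example

Three experts rate six items; the elicited prior is combined with 60
participants' five-category responses (simulated here from the study's
six-item truth `ρ = (.3, .5, .7, .7, .3, .5)`):

```python
import numpy as np
from obid import (ExpertRatings, MCMCSettings, fit_obid,
                  prior_from_expert_posterior, sample_expert_posterior,
                  simulate_responses, true_rho)

ratings = ExpertRatings([[4, 3, 4, 3, 4, 4],
                         [3, 3, 4, 2, 4, 3],
                         [4, 4, 4, 3, 3, 4]])
post = sample_expert_posterior(ratings, "cohen",
                               MCMCSettings(chains=2, burn_in=500,
                                            iterations=2000, seed=1))
prior = prior_from_expert_posterior(post)     # n0 = 5 x 3 = 15
data = simulate_responses(60, 6, 5, true_rho(6), seed=8)
draws = fit_obid(data, prior, MCMCSettings(chains=3, burn_in=1000,
                                           iterations=3000, seed=2))
print(draws.summary().round(3).to_string(index=False))
```

```
 item  alpha_mean  lambda_mean  rho_mean  rho_sd  acceptance
item1       0.755        0.505     0.439   0.119       0.327
item2       0.820        0.624     0.516   0.110       0.318
item3       1.687        1.981     0.868   0.074       0.536
item4       0.466        0.900     0.658   0.079       0.376
item5       0.754        0.334     0.307   0.132       0.299
item6       0.895        0.615     0.511   0.110       0.292
```

`rho_mean` is the posterior mean item-to-domain correlation (the posterior
mean of the draw-wise transform of `λ_j`), `rho_sd` its posterior standard
deviation, and `acceptance` the per-item proportion of accepted cut-point
proposals.  With only 60 participants the informative prior keeps the
estimates in a plausible range; item 3, rated "highly relevant" by the whole
panel and strongly discriminating in the data, ends near 0.87.

The same pipeline is available from the shell:

```bash
obid elicit-prior --experts experts.csv --out prior.csv --seed 1
obid fit --data responses.csv --prior prior.csv --out summary.csv --seed 2
obid simulate --items 6 --categories 5 --n 50 --experts 6 \
              --bias unbiased --reps 100 --seed 7 --out cell.csv
obid compare --input responses.csv        # classical ordinal CFA, JSON out
```

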
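# Methods

This note records the statistical model the package implements, the
numerical choices behind the samplers, what the synthetic-data generator
does and does not emulate, and the design decisions that were genuinely
open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Model and scales

The participant model is the two-parameter ordinal-probit IRT model

    y_ij = c  iff  y*_ij ∈ (T_{j,c-1}, T_jc],
    y*_ij = α_j + λ_j f_i + ε_ij,   f_i ~ N(0,1),  ε_ij ~ N(0,1),

equivalent to a one-factor ordinal factor model after standardization:
z*_ij = ρ_j f_i + e_ij with e_ij ~ N(0, 1 − ρ_j²) and
ρ_j = λ_j/√(1+λ_j²).  Three scales are used interchangeably
(`obid.transforms`): the correlation ρ ∈ (−1,1), the discrimination
λ = ρ/√(1−ρ²) ∈ ℝ, and the Fisher z-value μ = atanh(ρ) ∈ ℝ.  Inputs at
|ρ| = 1 are rejected, never clamped; the one caller that must handle a
boundary (the closed top of the expert relevance scale) clips explicitly at
1 − 1e-9.

## 2. Expert elicitation

A rating x_jk ∈ {1..4} on the four-point relevance scale is interval
censoring for the expert's latent correlation ρ_jk: Cohen bands
[0,.1), [.1,.3), [.3,.5), [.5,1] by default, or equal quarters.  The
hierarchy g(ρ_jk) = μ_j + e_jk, e_jk ~ N(0, σ²) is estimated by Gibbs
sampling with μ_j ~ N(0, 3), σ² ~ InvGamma(1e-5, 1e-5):

* latent z_jk from the censored normal by inverse-CDF sampling (no
  rejection loops, so narrow intervals cannot stall);
* μ_j from its conjugate normal; σ² from its conjugate inverse gamma.

σ² is **shared across items**: the hierarchy's notation admits either
reading, and a single between-expert variance is the more parsimonious
model for a panel rating one instrument; a per-item σ² is a sensitivity
analysis, not the default.

The top relevance band's closed upper bound ρ = 1 is clipped to 1 − 1e-9
*before* the Fisher transform, making the censoring interval finite
(upper z ≈ 10.7).  This matters: with an infinite interval, a panel
unanimous in the top band leaves the vague inverse-gamma hyperprior to
dominate (its mass sits at astronomically large σ², where a half-infinite
interval costs nothing), and the posterior for μ_j collapses toward the
N(0,3) prior.  With the finite interval the posterior is stable; the Gibbs
sampler was checked against a deterministic 2-D quadrature oracle over
(μ, log σ²) for unanimous two-expert panels and agrees to ~0.01 on E[μ]
(see `tests/test_expert.py`).

The prior handed to the IRT stage uses the posterior mean of the μ_j draws
directly on the z-scale (not a back-and-forth through ρ), a prior sample
size n0 = 5K (five pseudo-participants per expert; an explicit `n0`
override accommodates variance-ratio estimates, since the five-participant
rule is an empirical convention), and the delta-method normal

    λ_j ~ N(sinh μ_j, cosh²(μ_j)/n0).

The prior is a plain normal — no truncation at 0 — so genuinely
uninformative or contrarian panels can pull discriminations negative.
The non-informative alternative is λ_j ~ N(0, 4); α_j ~ N(0, 1) always.

For the simulation study the expert MCMC is bypassed: biased panels are
modelled analytically as ρ0 = ρ^T (unbiased), ρ^T + 0.1 (moderate), and
ρ^T + (1 − ρ^T)/2 (high; the midpoint construction cannot reach 1).

## 3. The participant sampler

`fit_obid` runs Metropolis–Hastings-within-Gibbs with state carried on a
leading batch axis, so the chains of one fit — or all replicates of a
simulation cell — advance in lock-step vectorized sweeps.  One sweep:

1. **Cut-points** (items with C > 2): Cowles-style sequential
   truncated-normal proposals, one block per item, accepted/rejected
   against the y*-marginalized likelihood with the truncation-normalizer
   proposal correction.  Proposals whose reverse move has empty support,
   and numerically non-increasing proposals, are auto-rejected.
   Acceptance is counted per item over retained sweeps (the mean over
   items is also reported); binary items have no free cut-point and report
   NaN.
2. **Latent responses** y*_ij from N(α_j + λ_j f_i, 1) truncated to the
   cut-point interval of the observed category (inverse-CDF, with tail
   reflection and clipping into the interval so degenerate intervals
   return the nearest bound rather than ±inf).
3. **Factor scores** f_i from the conjugate normal under f_i ~ N(0,1).
4. **(α_j, λ_j)** jointly from the conjugate bivariate normal (closed-form
   2×2 Cholesky).

Identification.  The first cut-point of every item is anchored at 0 (for
C = 2 the single cut-point is the anchor) with α_j free — the convention
under which α_j ~ N(0,1) is meaningful.  The reflection invariance
(λ, f) → (−λ, −f) is resolved per chain after sampling by forcing the sum
of posterior-mean discriminations positive; within-chain label switching
is not a practical concern at the sample sizes the package targets, since
the posterior concentrates on one mode.

Initialization: cut-points at the percentile values rescaled by √2
(the latent scale at λ = 1) and shifted to the anchor; λ = 1; f from
standardized person totals; α from the anchored percentile shift.

**Tuning-parameter units.**  The user-facing tuning parameter follows the
field's guidance — 1.00, 0.70, 0.50, 0.30 for N = 50, 100, 200, 500 keep
mean cut-point acceptance in the 20–50% band, and 2.00 is exposed for very
small samples (N < 40) — and those values track the 1/√N scale on which
the cut-point posterior contracts.  Internally the random-walk proposal
standard deviation is `tuning × 0.25` (`sampler.PROPOSAL_UNIT`): the
single constant under which this sampler realizes the quoted band at all
four stated (N, tuning) pairs.  The constant is part of the tuning
parameter's unit definition, fixed once; passing `tuning` in
`MCMCSettings` overrides the N-based default but is always expressed in
the same units.

Defaults: 3 chains, 2000 burn-in + 10000 retained for standalone fits;
1 chain, 2000 + 5000 inside the simulation engine.  Missing responses are
a hard error (the model is for complete data); items with fewer than two
observed categories are an error naming the item.

Posterior summaries: ρ̂_j is the posterior mean of the draw-wise transform
λ/√(1+λ²) (the proper posterior functional), not the transform of the
posterior-mean λ; the two differ by Jensen-gap amounts that are small at
these sample sizes but the draw-wise version is reported everywhere.

## 4. Classical comparator

`fit_ordinal_cfa` is the standard two-stage pipeline for one-factor
ordinal CFA: univariate ML thresholds (inverse normal CDF of cumulative
proportions), pairwise-ML polychoric correlations given the thresholds,
then least squares of the one-factor structure λλ' on the polychoric
correlations.  Bivariate normal rectangle probabilities use the Owen's-T
closed form (validated against `scipy.stats.multivariate_normal` to
1e-10); polychoric asymptotic variances come from the pairwise Fisher
information.

Weighting.  Unit weights (ULS) are the default; inverse-asymptotic-
variance diagonal weights (DWLS) are available via
`weights="information"`.  The information weights strongly down-weight
exactly the extreme small-sample tetrachorics that produce Heywood cases,
which makes the comparator *more* stable than the classical estimators
whose small-sample fragility this package is designed to expose; unit
weights reproduce that documented fragility.  Point estimates from the
two weightings agree closely away from degeneracy (tested).

Failure bookkeeping (never exceptions): `converged=False` for degenerate
items, boundary polychorics (|r| ≥ 0.999 — an empty-cell contingency
table), or optimizer failure; `in_bounds=False` when any standardized
loading exceeds 1 in magnitude (strict |ρ̂| > 1).  Factor scores for a
usable fit are expected-a-posteriori values by grid quadrature under the
estimated loadings and thresholds.

## 5. Synthetic data and the simulation engine

`simulate_responses` draws f_i ~ N(0,1), forms z*_ij = ρ_j f_i + e_ij with
e_ij ~ N(0, 1 − ρ_j²), and discretizes z* at the standard-normal
percentile cut-points for C categories, so marginal category frequencies
are balanced in expectation.  This emulates the study conditions exactly —
a clean unidimensional instrument with known loadings — and deliberately
omits features of real PROM data: skewed category usage, local item
dependence, differential item functioning, missingness, and experts whose
opinions are bimodal.  Passing tests therefore certify the estimators
under the stated model, not robustness to those violations.

The factorial design crosses P ∈ {4,6,9}, C ∈ {2,5,7}, N ∈ {50,100,200,500},
K ∈ {2,3,6,16} and three bias types (432 cells); the fixed true-correlation
vectors are (.50,.30,.70,.50), (.30,.50,.70,.70,.30,.50) and
(.30,.50,.70,.70,.30,.50,.70,.50,.30).  Per replicate, the data stream is
seeded by (master seed, cell factors, replicate index), so the Bayesian fit
and the comparator see *identical* datasets — the paired design that makes
small MSE differences detectable.  Cell metrics over S replicates (default
S = 100; tests use S = 50 for single cells and smaller for smoke checks):

    MSE(ρ̂_j) = Σ_s (ρ̂_j(s) − ρ_j^T)²/S, averaged over items;
    bias²_j = (ρ̄_j − ρ_j^T)², averaged over items;
    MSE(γ) = Σ_s (γ̂(s) − 1)²/S,  γ̂(s) = corr(E(f̂), f^T).

All divisors are S, so MSE = bias² + variance holds exactly per item
(asserted to 1e-10 on stored estimates).  Comparator replicates that fail
(nonconverged, out-of-bound, or engine error) are excluded from the CFA
MSE and γ summaries and counted in the status proportions — mixing Heywood
estimates into an MSE would conflate efficiency with failure frequency,
which the design tracks separately.

Problem sizes in the shipped tests: the efficiency-ordering check runs the
unbiased N=50/C=5/P=6 cell at K ∈ {2,3,6,16} with S = 50 and the study's
2000 + 5000 sweeps; comparator fragility uses 100 binary replicates; the
full campaign is documented as a batch job, one cell per `obid simulate`
invocation.

## 6. Known limitations

* Unidimensional instruments only; multi-factor ("long form") models are
  out of scope.
* Expert disagreement is a single normal on the z-scale; bimodal or
  trimodal panels are not modelled.
* Complete data only.
* The comparator is a faithful two-stage polychoric least-squares
  estimator, not a line-by-line reimplementation of any particular CFA
  package; its failure *rates* in small binary samples are
  implementation-sensitive and should be read as orders of magnitude.
* The five-participants-per-expert prior weight is a convention; `n0` is
  overridable where better calibration evidence exists.
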
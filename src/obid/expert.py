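"""Expert prior elicitation: from ordinal relevance ratings to discrimination priors.

Content-validity panels rate each instrument item on a four-point relevance
scale (1 "not relevant" ... 4 "highly relevant").  Each rating is read as an
interval statement about the expert's latent item-to-domain correlation
rho_jk, using either Cohen's effect-size cut-points (0.10 / 0.30 / 0.50) or
equally spaced quarters of [0, 1].  A hierarchical normal model on the
Fisher-z scale pools experts,

    g(rho_jk) = g(rho_j) + e_jk,   e_jk ~ N(0, sigma^2),

with hyperpriors mu_j = g(rho_j) ~ N(0, 3) and sigma^2 ~ InvGamma(1e-5, 1e-5)
(sigma^2 shared across items).  The posterior mean of mu_j, together with a
prior sample size of five pseudo-participants per expert, yields a normal
prior for each item's IRT discrimination parameter via the delta method:

    lambda_j ~ N( sinh(mu_j),  cosh(mu_j)^2 / n0 ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._mcmc import MCMCSettings, truncated_normal
from .transforms import fisher_z

__all__ = [
    "COHEN_CUTPOINTS",
    "EQUAL_CUTPOINTS",
    "ExpertRatings",
    "RelevanceScaleSpec",
    "ExpertPosterior",
    "PriorSpec",
    "relevance_scale",
    "relevance_interval",
    "sample_expert_posterior",
    "prior_sample_size",
    "build_lambda_prior",
    "analytic_prior_from_bias",
    "flat_prior",
]

#: Correlation thresholds partitioning [0, 1] into the four relevance bands.
COHEN_CUTPOINTS = (0.0, 0.10, 0.30, 0.50, 1.0)
EQUAL_CUTPOINTS = (0.0, 0.25, 0.50, 0.75, 1.0)

# clip for mapping a closed upper bound of 1.0 onto the Fisher-z scale
_RHO_CLIP = 1.0 - 1e-9


@dataclass(frozen=True)
class RelevanceScaleSpec:
    """Mapping from the four-point relevance scale to correlation intervals."""

    style: str
    cutpoints: tuple[float, ...]

    def __post_init__(self):
        c = self.cutpoints
        if len(c) != 5 or c[0] != 0.0 or c[-1] != 1.0:
            raise ValueError("cutpoints must partition [0, 1] into 4 intervals")
        if any(c[i] >= c[i + 1] for i in range(4)):
            raise ValueError(f"cutpoints must be strictly increasing, got {c}")


def relevance_scale(style: str = "cohen") -> RelevanceScaleSpec:
    """Return the named relevance scale ('cohen' or 'equal')."""
    if style == "cohen":
        return RelevanceScaleSpec("cohen", COHEN_CUTPOINTS)
    if style == "equal":
        return RelevanceScaleSpec("equal", EQUAL_CUTPOINTS)
    raise ValueError(f"unknown relevance scale style {style!r}")


def relevance_interval(x: int, scale: RelevanceScaleSpec | str = "cohen"):
    """Correlation interval implied by a relevance rating.

    Ratings 1-3 map to half-open intervals [lo, hi); rating 4 maps to the
    closed interval [lo, 1.0].
    """
    if isinstance(scale, str):
        scale = relevance_scale(scale)
    x = int(x)
    if not 1 <= x <= 4:
        raise ValueError(f"relevance rating must be in 1..4, got {x}")
    return (scale.cutpoints[x - 1], scale.cutpoints[x])


@dataclass
class ExpertRatings:
    """K x P table of relevance ratings; rows are experts, columns are items."""

    x: np.ndarray
    items: list[str] | None = None

    def __post_init__(self):
        x = np.asarray(self.x)
        if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 1:
            raise ValueError(f"ratings must be a K x P table, got shape {x.shape}")
        if not np.issubdtype(x.dtype, np.integer):
            xi = x.astype(int)
            if np.any(xi != x):
                raise ValueError("ratings must be integers in 1..4")
            x = xi
        if x.min() < 1 or x.max() > 4:
            bad = np.argwhere((x < 1) | (x > 4))[0]
            raise ValueError(
                f"rating out of range 1..4 at expert row {bad[0]}, item column {bad[1]}"
            )
        self.x = x
        if self.items is None:
            self.items = [f"item{j + 1}" for j in range(x.shape[1])]
        elif len(self.items) != x.shape[1]:
            raise ValueError("items list length must match the number of columns")

    @property
    def n_experts(self) -> int:
        return self.x.shape[0]

    @property
    def n_items(self) -> int:
        return self.x.shape[1]


@dataclass
class ExpertPosterior:
    """Posterior draws for the expert hierarchy.

    ``mu_draws`` has shape (draws, P) on the Fisher-z scale; ``sigma2_draws``
    has shape (draws,).  ``mu0`` is the per-item posterior mean of mu_j and
    ``n0`` the prior sample size (5 per expert).
    """

    mu_draws: np.ndarray
    sigma2_draws: np.ndarray
    mu0: np.ndarray
    n0: float
    items: list[str] = field(default_factory=list)

    @property
    def rho_mean(self) -> np.ndarray:
        """Posterior mean of the item-to-domain correlation tanh(mu_j)."""
        return np.tanh(self.mu_draws).mean(axis=0)


@dataclass
class PriorSpec:
    """Per-item normal priors for the IRT parameters.

    The discrimination prior is lambda_j ~ N(lambda_mean[j], lambda_var[j]);
    the negative-difficulty prior is always alpha_j ~ N(0, 1).  The
    non-informative form is lambda_j ~ N(0, 4).
    """

    lambda_mean: np.ndarray
    lambda_var: np.ndarray
    informative: bool = True
    mu0: np.ndarray | None = None
    n0: float | None = None
    alpha_mean: float = 0.0
    alpha_var: float = 1.0

    def __post_init__(self):
        self.lambda_mean = np.atleast_1d(np.asarray(self.lambda_mean, dtype=float))
        self.lambda_var = np.atleast_1d(np.asarray(self.lambda_var, dtype=float))
        if self.lambda_mean.shape != self.lambda_var.shape:
            raise ValueError("lambda_mean and lambda_var must have equal length")
        if np.any(self.lambda_var <= 0):
            raise ValueError("lambda_var must be positive")

    @property
    def n_items(self) -> int:
        return self.lambda_mean.shape[0]


def flat_prior(n_items: int) -> PriorSpec:
    """Non-informative prior: lambda_j ~ N(0, 4) for every item."""
    return PriorSpec(
        lambda_mean=np.zeros(n_items),
        lambda_var=np.full(n_items, 4.0),
        informative=False,
    )


def prior_sample_size(n_experts: int) -> float:
    """Prior pseudo-sample size n0 = 5 * K: each expert counts as ~5 participants."""
    if n_experts < 1:
        raise ValueError(f"need at least one expert, got {n_experts}")
    return 5.0 * n_experts


def build_lambda_prior(mu0, n0):
    """Normal prior (mean, variance) for lambda_j given mu0 on the Fisher-z scale.

    mean = (exp(2 mu0) - 1) / (2 exp(mu0)) = sinh(mu0)
    var  = (exp(2 mu0) + 1)^2 / (4 n0 exp(2 mu0)) = cosh(mu0)^2 / n0
    """
    n0 = float(n0)
    if n0 <= 0:
        raise ValueError(f"prior sample size must be positive, got {n0}")
    mu0 = np.asarray(mu0, dtype=float)
    return np.sinh(mu0), np.cosh(mu0) ** 2 / n0


_BIASES = ("unbiased", "moderate", "high")


def analytic_prior_from_bias(rho_true, bias: str, n_experts: int) -> PriorSpec:
    """Construct the discrimination prior a biased expert panel would induce.

    Bypasses the expert MCMC: the prior-mean correlations are
    rho0 = rho_true (unbiased), rho_true + 0.1 (moderate), or
    rho_true + (1 - rho_true)/2 (high), with n0 = 5 * K.
    """
    rho_true = np.atleast_1d(np.asarray(rho_true, dtype=float))
    if np.any(rho_true <= 0) or np.any(rho_true >= 1):
        raise ValueError("true correlations must lie in (0, 1)")
    if bias == "unbiased":
        rho0 = rho_true.copy()
    elif bias == "moderate":
        rho0 = rho_true + 0.1
    elif bias == "high":
        rho0 = rho_true + (1.0 - rho_true) / 2.0
    else:
        raise ValueError(f"bias must be one of {_BIASES}, got {bias!r}")
    if np.any(rho0 >= 1.0):
        raise ValueError(f"biased prior correlation reaches 1: {rho0}")
    mu0 = fisher_z(rho0)
    n0 = prior_sample_size(n_experts)
    mean, var = build_lambda_prior(mu0, n0)
    return PriorSpec(lambda_mean=mean, lambda_var=var, informative=True,
                     mu0=mu0, n0=n0)


def _z_intervals(ratings: ExpertRatings, scale: RelevanceScaleSpec):
    """Fisher-z censoring bounds for every rating cell; shape (K, P) each.

    The top band's closed upper bound rho = 1 is clipped to 1 - 1e-9 before
    the transform, giving a finite censoring interval.  (An infinite interval
    would let the vague inverse-gamma hyperprior on sigma^2 dominate the
    posterior whenever a panel is unanimous in the top band.)
    """
    cut = np.asarray(scale.cutpoints)
    lo_rho = cut[ratings.x - 1]
    hi_rho = np.minimum(cut[ratings.x], _RHO_CLIP)
    return fisher_z(lo_rho), fisher_z(hi_rho)


def sample_expert_posterior(
    ratings: ExpertRatings,
    scale: RelevanceScaleSpec | str = "cohen",
    settings: MCMCSettings | None = None,
) -> ExpertPosterior:
    """Gibbs sampler for the interval-censored expert hierarchy.

    Latent per-expert correlations rho_jk are censored (on the Fisher-z
    scale) to the interval implied by the observed rating; the latent
    z-values, the item means mu_j and the shared between-expert variance
    sigma^2 are updated in turn.  Latent-value updates use inverse-CDF
    sampling of the censored normal, which cannot stall in narrow intervals.
    """
    if isinstance(scale, str):
        scale = relevance_scale(scale)
    if settings is None:
        settings = MCMCSettings()
    K, P = ratings.x.shape
    lo, hi = _z_intervals(ratings, scale)
    hyper_mu_var = 3.0
    ig_a = ig_b = 1e-5

    n_draws = settings.chains * settings.iterations
    mu_draws = np.empty((n_draws, P))
    sigma2_draws = np.empty(n_draws)

    for chain in range(settings.chains):
        seed = None if settings.seed is None else settings.seed + chain
        rng = np.random.default_rng(seed)
        # start from interval midpoints (finite stand-in for the open top band)
        z = np.where(np.isinf(hi), lo + 0.5, 0.5 * (lo + hi))
        mu = z.mean(axis=0)
        sigma2 = 1.0
        off = chain * settings.iterations
        for sweep in range(settings.burn_in + settings.iterations):
            sd = np.sqrt(sigma2)
            z = truncated_normal(rng, np.broadcast_to(mu, (K, P)), sd, lo, hi)
            prec = 1.0 / hyper_mu_var + K / sigma2
            mean = (z.sum(axis=0) / sigma2) / prec
            mu = mean + rng.standard_normal(P) / np.sqrt(prec)
            ss = np.sum((z - mu) ** 2)
            sigma2 = (ig_b + 0.5 * ss) / rng.gamma(ig_a + 0.5 * K * P)
            r = sweep - settings.burn_in
            if r >= 0:
                mu_draws[off + r] = mu
                sigma2_draws[off + r] = sigma2

    return ExpertPosterior(
        mu_draws=mu_draws,
        sigma2_draws=sigma2_draws,
        mu0=mu_draws.mean(axis=0),
        n0=prior_sample_size(K),
        items=list(ratings.items),
    )


def prior_from_expert_posterior(posterior: ExpertPosterior,
                                n0: float | None = None) -> PriorSpec:
    """Discrimination prior from elicited expert draws.

    ``n0`` defaults to the five-per-expert rule carried by the posterior; an
    explicit override accommodates variance-ratio estimates of the prior
    sample size.
    """
    n0 = posterior.n0 if n0 is None else float(n0)
    mean, var = build_lambda_prior(posterior.mu0, n0)
    return PriorSpec(lambda_mean=mean, lambda_var=var, informative=True,
                     mu0=posterior.mu0.copy(), n0=n0)
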
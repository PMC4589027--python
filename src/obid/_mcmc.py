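"""Shared MCMC plumbing: settings container and truncated-normal draws."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

_TINY = 1e-300
_UEPS = 1e-15


@dataclass(frozen=True)
class MCMCSettings:
    """Chain configuration shared by the expert and participant samplers.

    Parameters
    ----------
    chains : number of independent chains (batched internally).
    burn_in : discarded warm-up sweeps per chain.
    iterations : retained sweeps per chain.
    tuning : Metropolis-Hastings proposal scale for cut-point updates;
        ``None`` selects :func:`obid.sampler.recommended_tuning` from N.
    seed : master seed for all randomness in the run.
    """

    chains: int = 3
    burn_in: int = 2000
    iterations: int = 10_000
    tuning: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError(f"chains must be >= 1, got {self.chains}")
        if self.burn_in < 0:
            raise ValueError(f"burn_in must be >= 0, got {self.burn_in}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if self.tuning is not None and not self.tuning > 0:
            raise ValueError(f"tuning must be > 0, got {self.tuning}")


def truncated_normal(rng, mean, sd, lower, upper):
    """Vectorized inverse-CDF draw from N(mean, sd^2) truncated to (lower, upper).

    Bounds may be +/-inf.  Intervals far in a tail are reflected to the left
    tail before the CDF inversion and the result is clipped into the interval,
    so degenerate intervals return the nearest finite bound instead of inf.
    """
    mean = np.asarray(mean, dtype=float)
    a = (lower - mean) / sd
    b = (upper - mean) / sd

    # reflect intervals living in the right tail: midpoint criterion that is
    # well-defined with one infinite endpoint
    crit = np.where(np.isinf(a) & np.isinf(b), 0.0,
                    np.where(np.isinf(a), b, np.where(np.isinf(b), a, a + b)))
    flip = crit > 0
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)

    pa = ndtr(lo)
    pb = ndtr(hi)
    u = rng.uniform(size=np.broadcast(lo, hi).shape)
    p = pa + u * (pb - pa)
    x = ndtri(np.clip(p, _UEPS, 1.0 - _UEPS))
    x = np.clip(x, np.where(np.isfinite(lo), lo, -np.inf),
                np.where(np.isfinite(hi), hi, np.inf))
    x = np.where(flip, -x, x)
    return mean + sd * x


def log_interval_prob(lower_std, upper_std):
    """log(Phi(upper) - Phi(lower)) for standardized bounds, floored at log(tiny)."""
    d = ndtr(upper_std) - ndtr(lower_std)
    return np.log(np.maximum(d, _TINY))
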
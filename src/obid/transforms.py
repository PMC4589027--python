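"""Closed-form reparameterizations of the ordinal-probit factor model.

Three equivalent scales are used throughout the package for the strength of
an item's relationship to the latent domain:

* the item-to-domain correlation ``rho`` (the standardized factor loading,
  whose square is the item reliability),
* the IRT discrimination parameter ``lam = rho / sqrt(1 - rho**2)``, and
* the Fisher z-transform ``mu = atanh(rho)``, on which expert opinion is
  modelled because it is variance-stabilizing and unbounded.

All functions are elementwise and accept scalars or array-likes.  Inputs
with ``|rho| >= 1`` are rejected rather than clamped: callers that can
produce boundary values must clip explicitly so that silent distortion is
impossible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fisher_z", "inverse_fisher_z", "lambda_from_rho", "rho_from_lambda"]


def _as_open_unit_interval(rho, name: str = "rho") -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    bad = ~(np.abs(rho) < 1.0)  # catches NaN too
    if np.any(bad):
        offending = np.atleast_1d(rho)[np.atleast_1d(bad)][0]
        raise ValueError(
            f"{name} must satisfy |{name}| < 1; got {offending!r}"
        )
    return rho


def fisher_z(rho):
    """Fisher z-transform ``g(rho) = 0.5 * log((1 + rho) / (1 - rho))``.

    Strictly increasing and odd; undefined at ``|rho| = 1``.
    """
    rho = _as_open_unit_interval(rho)
    return np.arctanh(rho)


def inverse_fisher_z(mu):
    """Inverse Fisher transform ``tanh(mu)``; maps the real line to (-1, 1)."""
    mu = np.asarray(mu, dtype=float)
    if not np.all(np.isfinite(mu)):
        raise ValueError("mu must be finite")
    return np.tanh(mu)


def lambda_from_rho(rho):
    """Discrimination ``lam = rho / sqrt(1 - rho**2)`` from the correlation.

    Equivalently ``sinh(fisher_z(rho))``.  Strictly increasing on (-1, 1).
    """
    rho = _as_open_unit_interval(rho)
    return rho / np.sqrt(1.0 - rho * rho)


def rho_from_lambda(lam):
    """Item-to-domain correlation ``rho = lam / sqrt(1 + lam**2)``.

    Inverse of :func:`lambda_from_rho`; always lands in (-1, 1).
    """
    lam = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("lam must be finite")
    return lam / np.sqrt(1.0 + lam * lam)
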
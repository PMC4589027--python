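"""Classical ordinal CFA baseline: one-factor WLSMV-style fit on polychoric structure.

The comparator follows the standard two-stage estimation pipeline for
ordinal confirmatory factor analysis:

1. item thresholds from univariate ML (inverse normal CDF of cumulative
   category proportions);
2. pairwise-ML polychoric correlations given the thresholds, with
   asymptotic variances from the pairwise Fisher information;
3. standardized loadings of a one-factor model by least squares on the
   polychoric correlations -- unit weights by default (ULS, which matches
   the small-sample fragility classical ordinal CFA is known for), or
   diagonal weights equal to the inverse asymptotic variances of the
   polychorics (DWLS).

Small ordinal samples make this pipeline fragile: the polychoric step can
degenerate (boundary correlations from empty cells) and the unconstrained
factor fit can produce Heywood cases with standardized loadings outside
[-1, 1].  Both failure modes are recorded in :class:`CfaResult` rather than
raised, so simulation loops can keep failure-rate bookkeeping.

Bivariate normal rectangle probabilities use a closed form in Owen's
T-function (scipy.special.owens_t), which is fully vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import ndtr, ndtri, owens_t

from .sampler import ParticipantResponses

__all__ = ["CfaResult", "bvn_cdf", "polychoric_corr", "fit_ordinal_cfa",
           "cfa_factor_scores"]

_RHO_BOUND = 0.999


@dataclass
class CfaResult:
    """Outcome of one ordinal CFA fit.

    ``loadings`` are standardized one-factor loadings, interpretable as
    item-to-domain correlations; present only when the fit converged.
    ``in_bounds`` is False whenever any |loading| > 1 (a Heywood case).
    """

    loadings: np.ndarray | None
    converged: bool
    in_bounds: bool
    message: str = ""
    thresholds: list[np.ndarray] | None = None
    polychoric: np.ndarray | None = None
    items: list[str] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return self.converged and self.in_bounds

    def to_dict(self) -> dict:
        return {
            "loadings": None if self.loadings is None else [float(v) for v in self.loadings],
            "converged": bool(self.converged),
            "in_bounds": bool(self.in_bounds),
            "message": self.message,
        }


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF P(X <= h, Y <= k) with correlation rho.

    Owen (1956) closed form: Phi2(h,k,rho) = (Phi(h) + Phi(k))/2
    - T(h, a_h) - T(k, a_k) - beta, where a_h = (k - rho h)/(h sqrt(1-rho^2))
    and beta = 1/2 iff h*k < 0 or (h*k = 0 and h + k < 0).  Infinite
    arguments reduce to the univariate CDF; |rho| = 1 reduces to min/max.
    Vectorized over h and k (rho scalar).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)
    if abs(rho) >= 1.0 - 1e-12:
        if rho > 0:
            return ndtr(np.minimum(h, k))
        return np.maximum(ndtr(h) - ndtr(-k), 0.0)

    out = np.empty(h.shape)
    neg_inf = np.isneginf(h) | np.isneginf(k)
    h_inf = np.isposinf(h)
    k_inf = np.isposinf(k)
    finite = ~(neg_inf | h_inf | k_inf)

    out[neg_inf] = 0.0
    out[h_inf & ~neg_inf] = ndtr(k[h_inf & ~neg_inf])
    out[k_inf & ~neg_inf & ~h_inf] = ndtr(h[k_inf & ~neg_inf & ~h_inf])

    hf = h[finite]
    kf = k[finite]
    s = np.sqrt(1.0 - rho * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = (kf - rho * hf) / (hf * s)
        ak = (hf - rho * kf) / (kf * s)
    # h = 0 (or k = 0): T(0, a) with a -> sign * inf has limit sign/4
    big = 1e12
    ah = np.where(hf == 0.0, np.sign(kf) * big, ah)
    ak = np.where(kf == 0.0, np.sign(hf) * big, ak)
    both0 = (hf == 0.0) & (kf == 0.0)
    beta = np.where(
        (hf * kf < 0) | ((hf * kf == 0) & (hf + kf < 0)), 0.5, 0.0
    )
    val = 0.5 * (ndtr(hf) + ndtr(kf)) - owens_t(hf, ah) - owens_t(kf, ak) - beta
    val = np.where(both0, 0.25 + np.arcsin(rho) / (2.0 * np.pi), val)
    out[finite] = val
    return np.clip(out, 0.0, 1.0)


def _bvn_pdf(h, k, rho):
    """Standard bivariate normal density at (h, k); zero at infinite arguments."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    fin = np.isfinite(h) & np.isfinite(k)
    out = np.zeros(h.shape)
    s2 = 1.0 - rho * rho
    hf, kf = h[fin], k[fin]
    out[fin] = np.exp(-(hf * hf - 2 * rho * hf * kf + kf * kf) / (2 * s2)) / (
        2 * np.pi * np.sqrt(s2)
    )
    return out


def estimate_thresholds(column: np.ndarray, n_categories: int) -> np.ndarray:
    """Univariate ML thresholds: inverse normal CDF of cumulative proportions.

    Length C - 1; entries are +/-inf when outer categories are empty and may
    tie when an interior category is empty.
    """
    N = column.shape[0]
    counts = np.bincount(column, minlength=n_categories + 1)[1:]
    cum = np.cumsum(counts[:-1]) / N
    with np.errstate(divide="ignore"):
        return ndtri(cum)


def _cell_bounds(tau):
    return np.concatenate(([-np.inf], tau, [np.inf]))


def polychoric_corr(y1, y2, tau1, tau2):
    """Pairwise-ML polychoric correlation and its asymptotic variance.

    Thresholds are held fixed (two-stage estimation).  Returns
    ``(rho_hat, avar)``; raises RuntimeError if the likelihood optimization
    fails.  A boundary estimate (|rho| >= 0.999) is returned as-is -- the
    caller decides whether that constitutes a degenerate fit.
    """
    C1 = len(tau1) + 1
    C2 = len(tau2) + 1
    table = np.zeros((C1, C2))
    np.add.at(table, (y1 - 1, y2 - 1), 1.0)
    N = table.sum()
    a = _cell_bounds(tau1)
    b = _cell_bounds(tau2)
    A, B = np.meshgrid(a, b, indexing="ij")

    def cell_probs(r):
        F = bvn_cdf(A, B, r)
        p = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
        return np.maximum(p, 1e-12)

    def negll(r):
        return -np.sum(table * np.log(cell_probs(r)))

    res = minimize_scalar(negll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
                          options={"xatol": 1e-6})
    if not res.success:
        raise RuntimeError(f"polychoric likelihood optimization failed: {res.message}")
    r_hat = float(res.x)

    # Fisher information of the pairwise likelihood at r_hat
    F2 = _bvn_pdf(A, B, r_hat)
    dp = F2[1:, 1:] - F2[:-1, 1:] - F2[1:, :-1] + F2[:-1, :-1]
    p = cell_probs(r_hat)
    info = N * np.sum(dp * dp / p)
    avar = 1.0 / info if info > 0 and np.isfinite(info) else np.nan
    return r_hat, avar


def fit_ordinal_cfa(data: ParticipantResponses | np.ndarray,
                    weights: str = "unit") -> CfaResult:
    """One-factor ordinal CFA: two-stage polychorics + least-squares loadings.

    ``weights="unit"`` (default) fits by unweighted least squares on the
    polychoric correlations; ``weights="information"`` uses diagonal weights
    equal to the inverse asymptotic variances of the pairwise polychoric
    estimates.  Never raises on estimation failure; the failure mode is
    captured in the ``converged`` / ``in_bounds`` flags and ``message``.
    Deterministic given the data.
    """
    if weights not in ("unit", "information"):
        raise ValueError(f"weights must be 'unit' or 'information', got {weights!r}")
    if not isinstance(data, ParticipantResponses):
        try:
            data = ParticipantResponses(np.asarray(data))
        except ValueError as exc:
            return CfaResult(None, converged=False, in_bounds=False,
                             message=f"invalid data: {exc}")
    y = data.y
    P = data.n_items
    items = list(data.items)

    observed = [np.unique(y[:, j]).size for j in range(P)]
    if min(observed) < 2:
        j = int(np.argmin(observed))
        return CfaResult(None, converged=False, in_bounds=False,
                         message=f"item column {j} is degenerate (constant or single category)",
                         items=items)

    thresholds = [estimate_thresholds(y[:, j], int(data.categories[j])) for j in range(P)]

    R = np.eye(P)
    W = np.zeros((P, P))
    boundary = False
    for j in range(P):
        for l in range(j + 1, P):
            try:
                r, avar = polychoric_corr(y[:, j], y[:, l], thresholds[j], thresholds[l])
            except RuntimeError as exc:
                return CfaResult(None, converged=False, in_bounds=False,
                                 message=str(exc), thresholds=thresholds, items=items)
            R[j, l] = R[l, j] = r
            W[j, l] = W[l, j] = 1.0 / avar if np.isfinite(avar) and avar > 0 else len(y)
            if abs(r) >= _RHO_BOUND:
                boundary = True
    if boundary:
        return CfaResult(None, converged=False, in_bounds=False,
                         message="polychoric correlation at boundary (degenerate contingency table)",
                         thresholds=thresholds, polychoric=R, items=items)

    # starting values from the leading eigenpair of the polychoric matrix
    evals, evecs = np.linalg.eigh(R)
    v = evecs[:, -1]
    lam0 = v * np.sqrt(max(evals[-1], 0.0))
    if lam0.sum() < 0:
        lam0 = -lam0
    lam0 = np.clip(lam0, -0.95, 0.95)

    iu = np.triu_indices(P, k=1)
    r_vec = R[iu]
    w_sqrt = np.sqrt(W[iu]) if weights == "information" else np.ones(len(r_vec))

    def resid(lam):
        return w_sqrt * (r_vec - np.outer(lam, lam)[iu])

    try:
        sol = least_squares(resid, lam0, method="lm", xtol=1e-10, ftol=1e-10,
                            max_nfev=2000)
    except Exception as exc:  # pragma: no cover - defensive
        return CfaResult(None, converged=False, in_bounds=False, message=str(exc),
                         thresholds=thresholds, polychoric=R, items=items)
    if not (sol.status > 0 and np.all(np.isfinite(sol.x))):
        return CfaResult(None, converged=False, in_bounds=False,
                         message=f"DWLS optimization failed: {sol.message}",
                         thresholds=thresholds, polychoric=R, items=items)
    lam = sol.x
    if lam.sum() < 0:
        lam = -lam
    in_bounds = bool(np.all(np.abs(lam) <= 1.0))
    return CfaResult(lam, converged=True, in_bounds=in_bounds,
                     message="ok" if in_bounds else "standardized loading outside [-1, 1]",
                     thresholds=thresholds, polychoric=R, items=items)


def cfa_factor_scores(result: CfaResult, data: ParticipantResponses,
                      grid_half_width: float = 5.0, grid_points: int = 201) -> np.ndarray:
    """Expected a-posteriori factor scores under the fitted CFA.

    Uses the measurement model y*_j = lambda_j f + e_j with
    e_j ~ N(0, 1 - lambda_j^2) and the estimated thresholds; E(f | y) is
    computed by quadrature on a uniform grid against the N(0, 1) prior.
    Requires a usable fit (converged and loadings inside [-1, 1]).
    """
    if not result.usable or result.thresholds is None:
        raise ValueError("factor scores require a converged, in-bounds CFA fit")
    lam = np.asarray(result.loadings, dtype=float)
    sd = np.sqrt(np.maximum(1.0 - lam * lam, 1e-10))
    y = data.y
    N, P = y.shape
    fgrid = np.linspace(-grid_half_width, grid_half_width, grid_points)
    log_w = -0.5 * fgrid**2
    ll = np.zeros((N, grid_points))
    for j in range(P):
        bounds = _cell_bounds(result.thresholds[j])
        lo = bounds[y[:, j] - 1][:, None]
        hi = bounds[y[:, j]][:, None]
        mu = lam[j] * fgrid[None, :]
        pj = ndtr((hi - mu) / sd[j]) - ndtr((lo - mu) / sd[j])
        ll += np.log(np.maximum(pj, 1e-300))
    ll += log_w[None, :]
    ll -= ll.max(axis=1, keepdims=True)
    w = np.exp(ll)
    return (w * fgrid[None, :]).sum(axis=1) / w.sum(axis=1)
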
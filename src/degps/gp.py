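"""Generalized Poisson (GP) distribution: pmf, cdf, sampling and ML fitting.

The GP law has two parameters (theta, lambda)::

    P(X = x) = theta * (theta + x*lam)**(x-1) * exp(-theta - x*lam) / x!

for x = 0, 1, 2, ... with theta > 0 and max(-1, -theta/q) <= lam <= 1,
where q (>= 4) is the largest positive integer with theta + q*lam > 0 when
lam < 0; the pmf is 0 for x > q in that case.  The mean is
theta/(1-lam) and the variance theta/(1-lam)**3, so lam > 0 produces
overdispersion and lam = 0 recovers the Poisson distribution.

ML fitting solves the estimating equation

    sum_i  X_i (X_i - 1) / (Xbar + (X_i - Xbar) * lam)  -  n * Xbar  =  0

for lambda, then sets theta = Xbar * (1 - lambda).  (A widely circulated
statement of this equation carries a sign slip, printing X_i (1 - X_i) in
the numerator; that version is nonpositive for all X_i >= 1 and has no
root, so the corrected numerator is used here.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "GPParams",
    "GPDomainError",
    "GPFitError",
    "gp_pmf",
    "gp_cdf",
    "gp_loglik",
    "fit_gp_mle",
    "gp_rvs",
]

_EPS = 1e-6
_MIN_Q = 4


class GPDomainError(ValueError):
    """Raised when (theta, lambda) violate the GP parameter constraints."""


class GPFitError(RuntimeError):
    """Raised when ML fitting is impossible for the given counts."""


def _compute_q(theta: float, lam: float) -> int | None:
    """Largest integer q with theta + q*lam > 0 (only meaningful for lam < 0)."""
    if lam >= 0:
        return None
    # theta + q*lam > 0  <=>  q < theta / (-lam)
    ratio = theta / (-lam)
    q = int(math.ceil(ratio) - 1) if ratio == math.floor(ratio) else int(math.floor(ratio))
    return q


@dataclass(frozen=True)
class GPParams:
    """Validated generalized-Poisson parameter pair.

    Attributes
    ----------
    theta : float
        Rate of the underlying Poisson process (read-count units), > 0.
    lam : float
        Dispersion parameter; positive values give overdispersion.
    q : int or None
        Support truncation bound (largest integer with ``theta + q*lam > 0``);
        ``None`` unless ``lam < 0``.
    """

    theta: float
    lam: float
    q: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.theta > 0):
            raise GPDomainError(f"theta must be > 0, got {self.theta}")
        if self.lam > 1:
            raise GPDomainError(f"lambda must be <= 1, got {self.lam}")
        if self.lam < 0:
            q = _compute_q(self.theta, self.lam)
            if q is None or q < _MIN_Q:
                raise GPDomainError(
                    f"lambda={self.lam} with theta={self.theta} implies support "
                    f"bound q={q} < {_MIN_Q}; lambda must satisfy "
                    f"max(-1, -theta/q) <= lambda"
                )
            if self.lam < max(-1.0, -self.theta / q):
                raise GPDomainError(
                    f"lambda={self.lam} below admissible bound "
                    f"max(-1, -theta/q)={max(-1.0, -self.theta / q)}"
                )
            object.__setattr__(self, "q", q)
        else:
            object.__setattr__(self, "q", None)

    @property
    def mean(self) -> float:
        return self.theta / (1.0 - self.lam)

    @property
    def variance(self) -> float:
        return self.theta / (1.0 - self.lam) ** 3


def _log_pmf_array(x: np.ndarray, params: GPParams) -> np.ndarray:
    """Log pmf evaluated elementwise; -inf outside the support."""
    theta, lam = params.theta, params.lam
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = theta + x * lam
        logp = (
            math.log(theta)
            + (x - 1.0) * np.log(np.where(arg > 0, arg, 1.0))
            - theta
            - x * lam
            - special.gammaln(x + 1.0)
        )
    out_of_support = arg <= 0
    if params.q is not None:
        out_of_support |= x > params.q
    return np.where(out_of_support | (x < 0), -np.inf, logp)


def gp_pmf(x, params: GPParams):
    """GP probability mass at integer ``x`` (scalar or array).

    Computed in log space; returns 0 beyond the truncated support when
    ``lam < 0``.
    """
    x_arr = np.asarray(x)
    res = np.exp(_log_pmf_array(x_arr, params))
    return float(res) if np.isscalar(x) or x_arr.ndim == 0 else res


def _pmf_table(params: GPParams, upto: int) -> np.ndarray:
    return np.exp(_log_pmf_array(np.arange(upto + 1), params))


def _truncation_mass(params: GPParams) -> float:
    """Total pmf mass over the (possibly truncated) support."""
    if params.q is None:
        return 1.0
    return float(_pmf_table(params, params.q).sum())


def gp_cdf(x, params: GPParams, inclusive: bool = False):
    """GP cumulative probability P(X < x), or P(X <= x) if ``inclusive``.

    The strict-inequality convention is the default because the GP-based
    quantile normalization maps each count to P(X < x).  For ``lam < 0``
    the truncated pmf does not sum to 1; the cdf is renormalized by the
    total truncated mass so it is a proper cdf reaching 1 at x = q.
    """
    scalar = np.isscalar(x) or np.asarray(x).ndim == 0
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    hi = params.q if params.q is not None else int(np.nanmax(x_arr)) if x_arr.size else 0
    hi = max(int(hi), 0)
    table = _pmf_table(params, hi)
    cum = np.concatenate([[0.0], np.cumsum(table)])  # cum[k] = P(X < k)
    norm = _truncation_mass(params)
    idx = np.clip(np.floor(x_arr).astype(np.int64) + (1 if inclusive else 0), 0, hi + 1)
    idx = np.where(x_arr < 0, 0, idx)
    out = np.minimum(cum[idx] / norm, 1.0)
    return float(out[0]) if scalar else out


def gp_loglik(counts, params: GPParams) -> float:
    """Sum of log pmf over ``counts``; -inf if any count is outside the support."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("counts must be nonempty")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    return float(_log_pmf_array(counts, params).sum())


def _estimating_eq(lam: float, x: np.ndarray, xbar: float) -> float:
    """LHS of the (sign-corrected) lambda estimating equation."""
    denom = xbar + (x - xbar) * lam
    if np.any(denom <= 0):
        return np.nan
    return float(np.sum(x * (x - 1.0) / denom) - x.size * xbar)


def fit_gp_mle(counts, tol: float = 1e-10) -> GPParams:
    """Maximum-likelihood fit of (theta, lambda) from one sample's counts.

    Solves the estimating equation for lambda by bracketed root finding
    over the admissible range, falling back to bounded likelihood
    maximization when no sign change exists; theta = Xbar * (1 - lambda).

    Raises
    ------
    GPFitError
        If the counts are all zero or have zero variance (filter such
        samples before fitting).
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise GPFitError("need a 1-D sample with n >= 2 counts")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise GPFitError("counts must be nonnegative integers")
    xbar = float(x.mean())
    if xbar == 0.0:
        raise GPFitError("all counts are zero; filter this sample before fitting")
    if float(x.var()) == 0.0:
        raise GPFitError("zero sample variance; GP fit is degenerate")

    # Admissible lambda range: keep every Xbar + (Xi - Xbar)*lam positive and
    # lam within [-1, 1).  The most extreme count bounds lam from below.
    xmax = float(x.max())
    lo = -1.0
    if xmax > xbar:
        lo = max(lo, -xbar / (xmax - xbar))
    lo += _EPS
    hi = 1.0 - _EPS

    uniq, counts_u = np.unique(x, return_counts=True)

    def g(lam: float) -> float:
        denom = xbar + (uniq - xbar) * lam
        if np.any(denom <= 0):
            return np.nan
        return float(np.sum(counts_u * uniq * (uniq - 1.0) / denom) - x.size * xbar)

    lam_hat = _solve_lambda(g, lo, hi, tol)
    if lam_hat is None:
        lam_hat = _maximize_loglik(uniq, counts_u, xbar, lo, hi)
    lam_hat = min(lam_hat, 1.0 - _EPS)
    theta_hat = xbar * (1.0 - lam_hat)
    if theta_hat <= 0:
        raise GPFitError(f"fit produced theta={theta_hat} <= 0 (lambda={lam_hat})")
    try:
        return GPParams(theta=theta_hat, lam=lam_hat)
    except GPDomainError as exc:  # pragma: no cover - defensive
        raise GPFitError(f"fitted parameters inadmissible: {exc}") from exc


def _solve_lambda(g, lo: float, hi: float, tol: float) -> float | None:
    """Bracketed root of the estimating equation, or None if no sign change."""
    grid = np.linspace(lo, hi, 65)
    vals = np.array([g(l) for l in grid])
    ok = np.isfinite(vals)
    for i in range(len(grid) - 1):
        if ok[i] and ok[i + 1] and vals[i] * vals[i + 1] < 0:
            return float(
                optimize.brentq(g, grid[i], grid[i + 1], xtol=tol, maxiter=200)
            )
    return None


def _maximize_loglik(uniq, counts_u, xbar, lo, hi) -> float:
    """Fallback: bounded maximization of the profile log-likelihood in lambda."""

    def nll(lam: float) -> float:
        theta = xbar * (1.0 - lam)
        if theta <= 0:
            return np.inf
        arg = theta + uniq * lam
        if np.any(arg <= 0):
            return np.inf
        ll = counts_u * (
            math.log(theta)
            + (uniq - 1.0) * np.log(arg)
            - theta
            - uniq * lam
            - special.gammaln(uniq + 1.0)
        )
        return -float(ll.sum())

    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    if not res.success:  # pragma: no cover
        raise GPFitError(f"likelihood maximization failed over [{lo}, {hi}]: {res}")
    return float(res.x)


def gp_rvs(params: GPParams, size: int, seed=None) -> np.ndarray:
    """Draw ``size`` i.i.d. GP variates by cdf inversion.

    ``seed`` may be an int or a ``numpy.random.Generator``; identical
    seeds give identical draws.
    """
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if params.q is not None:
        hi = params.q
    else:
        # Adaptive support bound: extend until pmf mass within 1e-12 of 1.
        hi = max(int(params.mean + 20.0 * math.sqrt(params.variance) + 20), 50)
        while True:
            tail = 1.0 - _pmf_table(params, hi).sum()
            if tail < 1e-12 or hi > 100_000_000:
                break
            hi *= 2
    table = _pmf_table(params, hi)
    cum = np.cumsum(table) / _truncation_mass(params)
    u = rng.random(size)
    return np.searchsorted(cum, u, side="right").astype(np.int64)
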
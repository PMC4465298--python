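"""Per-sample normalization of count matrices.

Two normalizations are driven by a per-sample generalized-Poisson fit:

* ``gp-theta`` divides each sample's counts by the fitted theta, a
  shrunken library-size factor equal to the sample mean times
  ``(1 - lambda_hat)``.
* ``gp-quantile`` maps every count x to the fitted cumulative
  probability P(X < x), placing all samples on the [0, 1) scale.

Comparator methods (global library-size scaling, quantile, TMM, lowess)
are included so the permutation test can be run on any of them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .gp import GPFitError, GPParams, fit_gp_mle, gp_cdf
from .matrix import CountMatrix, NormalizedMatrix

__all__ = [
    "METHODS",
    "fit_gp_per_sample",
    "normalize_gp_theta",
    "normalize_gp_quantile",
    "normalize_global",
    "normalize_quantile",
    "normalize_tmm",
    "normalize_lowess",
    "normalize",
]


def fit_gp_per_sample(counts: CountMatrix) -> list[GPParams]:
    """Fit a GP distribution to each sample column, with sample context on error."""
    fits = []
    for j, sid in enumerate(counts.sample_ids):
        try:
            fits.append(fit_gp_mle(counts.values[:, j]))
        except GPFitError as exc:
            raise GPFitError(f"sample {sid!r}: {exc}") from exc
    return fits


def normalize_gp_theta(counts: CountMatrix) -> NormalizedMatrix:
    """Divide each sample by its fitted GP theta = Xbar * (1 - lambda_hat)."""
    fits = fit_gp_per_sample(counts)
    factors = np.array([f.theta for f in fits])
    return NormalizedMatrix(
        counts.values / factors[np.newaxis, :],
        list(counts.transcript_ids),
        list(counts.sample_ids),
        method="gp-theta",
        per_sample_factors=factors,
    )


def normalize_gp_quantile(
    counts: CountMatrix, convention: str = "strict"
) -> NormalizedMatrix:
    """Map each count x to its fitted-GP cumulative probability.

    ``convention`` selects P(X < x) (``"strict"``, the default),
    P(X <= x) (``"inclusive"``) or the mid-probability
    P(X < x) + pmf(x)/2 (``"mid"``).
    """
    if convention not in {"strict", "inclusive", "mid"}:
        raise ValueError(f"unknown convention {convention!r}")
    fits = fit_gp_per_sample(counts)
    out = np.empty(counts.values.shape, dtype=float)
    for j, params in enumerate(fits):
        col = counts.values[:, j]
        if convention == "strict":
            out[:, j] = gp_cdf(col, params)
        elif convention == "inclusive":
            out[:, j] = gp_cdf(col, params, inclusive=True)
        else:
            lo = gp_cdf(col, params)
            hi = gp_cdf(col, params, inclusive=True)
            out[:, j] = 0.5 * (lo + hi)
    return NormalizedMatrix(
        out,
        list(counts.transcript_ids),
        list(counts.sample_ids),
        method="gp-quantile",
        per_sample_factors=None,
    )


def normalize_global(counts: CountMatrix) -> NormalizedMatrix:
    """Scale every column to the grand mean of column totals."""
    totals = counts.values.sum(axis=0).astype(float)
    if np.any(totals == 0):
        bad = counts.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero total count")
    target = totals.mean()
    factors = totals / target
    return NormalizedMatrix(
        counts.values / factors[np.newaxis, :],
        list(counts.transcript_ids),
        list(counts.sample_ids),
        method="global",
        per_sample_factors=factors,
    )


def normalize_quantile(counts: CountMatrix) -> NormalizedMatrix:
    """Classic quantile normalization with average-rank tie handling.

    Each column's sorted values are replaced by the across-column means of
    sorted values; ties within a column receive the mean of the reference
    values they span, so tied entries stay tied.
    """
    x = counts.values.astype(float)
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, x.shape[0] + 1), ref)
    return NormalizedMatrix(
        out,
        list(counts.transcript_ids),
        list(counts.sample_ids),
        method="quantile",
        per_sample_factors=None,
    )


def tmm_factors(
    counts: CountMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors, geometric-mean-centred.

    Double-zero transcripts against the reference are dropped, then 30 %
    of each M (log-ratio) tail and 5 % of each A (log-abundance) tail are
    trimmed; remaining M values are combined with inverse asymptotic
    variance weights and exponentiated.
    """
    x = counts.values.astype(float)
    lib = x.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("TMM requires positive library sizes")
    if ref_sample is None:
        # Column whose upper-quartile of scaled counts is closest to the mean.
        f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.sample_ids.index(ref_sample)
    r, nr = x[:, ref_idx], lib[ref_idx]
    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        o, no = x[:, j], lib[j]
        keep = (o > 0) & (r > 0)
        if not np.any(keep):
            raise ValueError(
                f"no transcript expressed in both sample {counts.sample_ids[j]!r} "
                f"and the reference; use a larger matrix"
            )
        ok, rk = o[keep], r[keep]
        m = np.log2((ok / no) / (rk / nr))
        a = 0.5 * np.log2((ok / no) * (rk / nr))
        n = m.size
        m_lo, m_hi = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        a_lo, a_hi = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm = stats.rankdata(m, method="average")
        ra = stats.rankdata(a, method="average")
        sel = (rm >= m_lo) & (rm <= m_hi) & (ra >= a_lo) & (ra <= a_hi)
        if not np.any(sel):
            raise ValueError(
                f"no transcripts survive trimming for sample "
                f"{counts.sample_ids[j]!r}; use a larger matrix"
            )
        w = 1.0 / ((no - ok[sel]) / (no * ok[sel]) + (nr - rk[sel]) / (nr * rk[sel]))
        log_factors[j] = np.sum(w * m[sel]) / np.sum(w)
    factors = 2.0 ** log_factors
    return factors / np.exp(np.mean(np.log(factors)))


def normalize_tmm(counts: CountMatrix, ref_sample: str | None = None) -> NormalizedMatrix:
    """TMM scale factors multiplied into library-size scaling."""
    factors = tmm_factors(counts, ref_sample=ref_sample)
    lib = counts.values.sum(axis=0).astype(float)
    eff = lib * factors
    scale = eff / eff.mean()
    return NormalizedMatrix(
        counts.values / scale[np.newaxis, :],
        list(counts.transcript_ids),
        list(counts.sample_ids),
        method="tmm",
        per_sample_factors=factors,
    )


def normalize_lowess(
    counts: CountMatrix, frac: float = 0.4, it: int = 3
) -> NormalizedMatrix:
    """MA-style lowess normalization against a geometric-mean pseudo-reference.

    Works on log2(count + 1); for each sample the lowess trend of
    M = log(sample) - log(reference) against A = (log(sample) + log(reference))/2
    is subtracted, and values are mapped back to the count scale.
    """
    logx = np.log2(counts.values.astype(float) + 1.0)
    ref = logx.mean(axis=1)
    out = np.empty_like(logx)
    for j in range(logx.shape[1]):
        m = logx[:, j] - ref
        a = 0.5 * (logx[:, j] + ref)
        trend = _sm_lowess(m, a, frac=frac, it=it, return_sorted=False)
        out[:, j] = logx[:, j] - trend
    return NormalizedMatrix(
        np.maximum(2.0 ** out - 1.0, 0.0),
        list(counts.transcript_ids),
        list(counts.sample_ids),
        method="lowess",
        per_sample_factors=None,
    )


METHODS = {
    "gp-theta": normalize_gp_theta,
    "gp-quantile": normalize_gp_quantile,
    "global": normalize_global,
    "quantile": normalize_quantile,
    "tmm": normalize_tmm,
    "lowess": normalize_lowess,
}


def normalize(counts: CountMatrix, method: str) -> NormalizedMatrix:
    """Dispatch to a normalization method by name."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown normalization {method!r}; choose from {sorted(METHODS)}"
        ) from None
    return fn(counts)
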
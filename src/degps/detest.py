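"""Two-group differential expression via a pooled permutation null.

The observed statistic per transcript is the unpooled-variance (Welch)
T.  The null distribution is built by re-assigning sample labels,
recomputing T for every transcript under each re-assignment, and merging
all statistics — across transcripts and permutations, with no averaging
— into one pooled empirical distribution.  Because a typical experiment
measures thousands of transcripts, this pool is large even when the
per-group sample size is as small as two.  Two-sided empirical p-values
are referred to the pool and adjusted by Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from joblib import Parallel, delayed

from .matrix import CountMatrix, NormalizedMatrix
from .normalize import normalize

__all__ = [
    "GroupDesign",
    "PermutationNull",
    "DEResult",
    "filter_all_zero",
    "t_statistic",
    "group_t_statistics",
    "regularized_t_statistics",
    "build_null",
    "empirical_pvalues",
    "bh_adjust",
    "run_degps",
]


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to two groups, A and B."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if len(a) != len(self.group_a) or len(b) != len(self.group_b):
            raise ValueError("duplicate sample ids within a group")
        if a & b:
            raise ValueError(f"samples assigned to both groups: {sorted(a & b)}")
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs >= 2 samples for variance estimation")

    @property
    def n_a(self) -> int:
        return len(self.group_a)

    @property
    def n_b(self) -> int:
        return len(self.group_b)

    @property
    def samples(self) -> tuple[str, ...]:
        return self.group_a + self.group_b

    @classmethod
    def from_mapping(cls, assignment: dict[str, str]) -> "GroupDesign":
        labels = sorted(set(assignment.values()))
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 group labels, got {labels}")
        ga = tuple(s for s, g in assignment.items() if g == labels[0])
        gb = tuple(s for s, g in assignment.items() if g == labels[1])
        return cls(ga, gb)


@dataclass
class PermutationNull:
    """Pooled T-statistics from label permutations."""

    pooled_stats: np.ndarray
    n_perms: int
    exhaustive: bool
    n_undefined: int = 0
    #: |T| sorted ascending, for fast p-value lookups
    _sorted_abs: np.ndarray = field(default=None, repr=False)

    def sorted_abs(self) -> np.ndarray:
        if self._sorted_abs is None:
            self._sorted_abs = np.sort(np.abs(self.pooled_stats))
        return self._sorted_abs


@dataclass
class DEResult:
    """Per-transcript test output."""

    transcript_ids: list[str]
    t_obs: np.ndarray
    p_value: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    fdr_threshold: float
    n_perms: int
    exhaustive: bool
    filtered_ids: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "transcript_id": self.transcript_ids,
                "t_stat": self.t_obs,
                "p_value": self.p_value,
                "p_adjusted": self.p_adjusted,
                "significant": self.significant,
            }
        )


def filter_all_zero(
    counts: CountMatrix, design: GroupDesign
) -> tuple[CountMatrix, list[str]]:
    """Drop transcripts with zero counts in every sample of the comparison."""
    sub = counts.subset_samples(design.samples)
    keep = sub.values.sum(axis=1) > 0
    removed = [t for t, k in zip(sub.transcript_ids, keep) if not k]
    return sub.subset_transcripts(keep), removed


def t_statistic(x, y) -> float:
    """Welch-style unpooled-variance T; NaN when both group variances are 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    denom = vx / x.size + vy / y.size
    if denom == 0.0:
        return math.nan
    return float((x.mean() - y.mean()) / math.sqrt(denom))


def _t_matrix(values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Welch T per row for one or more column assignments.

    ``idx_a``/``idx_b`` have shape (P, n_a) and (P, n_b); returns (G, P).
    Rows where both group variances vanish give NaN.
    """
    xa = values[:, idx_a]  # (G, P, n_a)
    xb = values[:, idx_b]
    ma = xa.mean(axis=2)
    mb = xb.mean(axis=2)
    va = xa.var(axis=2, ddof=1)
    vb = xb.var(axis=2, ddof=1)
    denom = va / idx_a.shape[1] + vb / idx_b.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(denom)
    return np.where(denom == 0.0, np.nan, t)


def group_t_statistics(norm: NormalizedMatrix, design: GroupDesign) -> np.ndarray:
    """Observed Welch T per transcript for the given design."""
    idx_a = np.array([[norm.sample_ids.index(s) for s in design.group_a]])
    idx_b = np.array([[norm.sample_ids.index(s) for s in design.group_b]])
    return _t_matrix(norm.values, idx_a, idx_b)[:, 0]


def regularized_t_statistics(
    norm: NormalizedMatrix, design: GroupDesign, shrinkage_weight: float | None = None
) -> np.ndarray:
    """James-Stein regularized T: per-transcript variances shrunk to the median.

    Each group's per-transcript variance is replaced by
    ``w * median_variance + (1 - w) * variance``; ``w`` is estimated from
    the data (Opgen-Rhein/Strimmer-style) unless forced.  ``w = 0``
    reduces to the ordinary statistic.
    """
    idx_a = [norm.sample_ids.index(s) for s in design.group_a]
    idx_b = [norm.sample_ids.index(s) for s in design.group_b]
    xa = norm.values[:, idx_a]
    xb = norm.values[:, idx_b]

    def shrunk_var(x: np.ndarray) -> np.ndarray:
        n = x.shape[1]
        v = x.var(axis=1, ddof=1)
        target = np.median(v)
        if shrinkage_weight is None:
            w_centered = (x - x.mean(axis=1, keepdims=True)) ** 2
            var_of_v = n / (n - 1.0) ** 3 * np.sum(
                (w_centered - w_centered.mean(axis=1, keepdims=True)) ** 2, axis=1
            )
            denom = np.sum((v - target) ** 2)
            w = 1.0 if denom == 0.0 else min(1.0, float(np.sum(var_of_v) / denom))
        else:
            w = float(shrinkage_weight)
        return w * target + (1.0 - w) * v

    va = shrunk_var(xa)
    vb = shrunk_var(xb)
    denom = va / len(idx_a) + vb / len(idx_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (xa.mean(axis=1) - xb.mean(axis=1)) / np.sqrt(denom)
    return np.where(denom == 0.0, np.nan, t)


def _assignments(
    n: int, n_a: int, max_perms: int, seed, include_identity: bool
) -> tuple[np.ndarray, bool]:
    """Distinct group-A index sets (P, n_a) and whether they are exhaustive.

    The identity assignment (columns 0..n_a-1 as group A) is excluded by
    default so the null pool does not contain the observed statistics.
    """
    total = math.comb(n, n_a)
    n_available = total if include_identity else total - 1
    if n_available < 1:
        raise ValueError("no non-identity permutation exists for this design")
    identity = tuple(range(n_a))
    if n_available <= max_perms:
        combos = [c for c in combinations(range(n), n_a) if include_identity or c != identity]
        return np.array(combos, dtype=np.int64), True
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < max_perms:
        draw = tuple(sorted(rng.choice(n, size=n_a, replace=False).tolist()))
        if include_identity or draw != identity:
            chosen.add(draw)
    return np.array(sorted(chosen), dtype=np.int64), False


def build_null(
    norm: NormalizedMatrix,
    design: GroupDesign,
    max_perms: int = 1000,
    seed: int | None = None,
    include_identity: bool = False,
    n_workers: int = 1,
    chunk_size: int = 64,
) -> PermutationNull:
    """Pool Welch T-statistics over label permutations.

    All ``choose(n, n_a)`` distinct assignments are enumerated when they
    fit within ``max_perms`` (identity excluded unless requested);
    otherwise ``max_perms`` distinct assignments are sampled without
    replacement under ``seed``.  Transcripts whose statistic is undefined
    under a permutation (both group variances zero) are excluded from
    the pool and counted.  Results are independent of ``n_workers``.
    """
    if max_perms < 1:
        raise ValueError("max_perms must be >= 1")
    order = [norm.sample_ids.index(s) for s in design.samples]
    values = norm.values[:, order]
    n = len(order)
    idx_a, exhaustive = _assignments(n, design.n_a, max_perms, seed, include_identity)
    all_idx = np.arange(n)
    idx_b = np.array([np.setdiff1d(all_idx, row, assume_unique=True) for row in idx_a])

    chunks = [
        (idx_a[i : i + chunk_size], idx_b[i : i + chunk_size])
        for i in range(0, idx_a.shape[0], chunk_size)
    ]
    if n_workers > 1 and len(chunks) > 1:
        blocks = Parallel(n_jobs=n_workers)(
            delayed(_t_matrix)(values, ca, cb) for ca, cb in chunks
        )
    else:
        blocks = [_t_matrix(values, ca, cb) for ca, cb in chunks]
    stats = np.concatenate([b.ravel(order="F") for b in blocks])
    defined = np.isfinite(stats)
    return PermutationNull(
        pooled_stats=stats[defined],
        n_perms=idx_a.shape[0],
        exhaustive=exhaustive,
        n_undefined=int((~defined).sum()),
    )


def _regularized_null(
    norm: NormalizedMatrix,
    design: GroupDesign,
    max_perms: int,
    seed: int | None,
) -> PermutationNull:
    """Permutation pool built from regularized statistics (one pass per perm)."""
    order = [norm.sample_ids.index(s) for s in design.samples]
    n = len(order)
    idx_a, exhaustive = _assignments(n, design.n_a, max_perms, seed, False)
    all_idx = np.arange(n)
    samples = list(design.samples)
    stats_blocks = []
    for row in idx_a:
        comp = np.setdiff1d(all_idx, row, assume_unique=True)
        d = GroupDesign(
            tuple(samples[i] for i in row), tuple(samples[i] for i in comp)
        )
        stats_blocks.append(regularized_t_statistics(norm, d))
    stats = np.concatenate(stats_blocks)
    defined = np.isfinite(stats)
    return PermutationNull(
        pooled_stats=stats[defined],
        n_perms=idx_a.shape[0],
        exhaustive=exhaustive,
        n_undefined=int((~defined).sum()),
    )


def empirical_pvalues(t_obs: np.ndarray, null: PermutationNull) -> np.ndarray:
    """Two-sided pooled-permutation p-values with the add-one convention.

    ``p_g = (1 + #{|s| >= |t_g|}) / (1 + N)`` over the pooled statistics,
    guaranteeing p in (0, 1].  Undefined observed statistics (NaN) map
    to p = 1.
    """
    pool = null.sorted_abs()
    if pool.size == 0:
        raise ValueError("permutation null is empty")
    t_obs = np.asarray(t_obs, dtype=float)
    abs_t = np.abs(t_obs)
    n_ge = pool.size - np.searchsorted(pool, abs_t, side="left")
    p = (1.0 + n_ge) / (1.0 + pool.size)
    return np.where(np.isnan(t_obs), 1.0, p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def run_degps(
    counts: CountMatrix,
    design: GroupDesign,
    method: str = "gp-theta",
    max_perms: int = 1000,
    fdr_threshold: float = 0.05,
    seed: int | None = None,
    n_workers: int = 1,
    statistic: str = "ordinary",
) -> DEResult:
    """Full pipeline: filter, normalize, test, pool, adjust, call.

    ``statistic`` selects ``"ordinary"`` (Welch) or ``"regularized"``
    (variance-shrunk) T for the observed statistics; the pooled null
    always uses the same statistic family as the observed values.
    """
    if not (0.0 < fdr_threshold < 1.0):
        raise ValueError("fdr_threshold must be in (0, 1)")
    filtered, removed = filter_all_zero(counts, design)
    if filtered.n_transcripts == 0:
        raise ValueError("no transcripts remain after all-zero filtering")
    norm = normalize(filtered, method)
    if statistic == "ordinary":
        t_obs = group_t_statistics(norm, design)
        null = build_null(
            norm, design, max_perms=max_perms, seed=seed, n_workers=n_workers
        )
    elif statistic == "regularized":
        t_obs = regularized_t_statistics(norm, design)
        null = _regularized_null(norm, design, max_perms=max_perms, seed=seed)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    p = empirical_pvalues(t_obs, null)
    p_adj = bh_adjust(p)
    return DEResult(
        transcript_ids=list(norm.transcript_ids),
        t_obs=t_obs,
        p_value=p,
        p_adjusted=p_adj,
        significant=p_adj < fdr_threshold,
        fdr_threshold=fdr_threshold,
        n_perms=null.n_perms,
        exhaustive=null.exhaustive,
        filtered_ids=removed,
    )
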
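"""Synthetic count data for evaluating differential-expression methods.

Three generators are provided:

* ``make_source_matrix`` — an overdispersed, heavy-tailed count matrix
  with uneven library sizes, standing in for a large real study.
* ``resample_null`` plus ``apply_shift`` / ``apply_scale_shift`` —
  data-driven scenarios: sample columns from a source matrix into two
  groups (null), then optionally perturb a subset of transcripts by
  adding counts ("shift") and/or multiplying them ("scaling & shift")
  in one group, with the perturbation's spread fixed at one fifth of
  its magnitude.
* ``simulate_nb_counts`` — negative-binomial counts per group with a
  configurable fraction of differentially expressed transcripts (half
  upregulated by default) and random per-entry outliers that multiply a
  count by a factor in [5, 10].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detest import GroupDesign
from .matrix import CountMatrix

__all__ = [
    "ScenarioConfig",
    "SimulatedDataset",
    "make_source_matrix",
    "resample_null",
    "apply_shift",
    "apply_scale_shift",
    "simulate_nb_counts",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation scenario."""

    n_transcripts: int = 2000
    n_per_group: int = 5
    de_fraction: float = 0.0
    upregulated_fraction: float = 0.5
    outlier_prob: float = 0.0
    effect_size: float = 8.0
    outlier_factor_range: tuple[float, float] = (5.0, 10.0)
    log10_mean_loc: float = 2.0
    log10_mean_scale: float = 1.0
    dispersion_range: tuple[float, float] = (0.1, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "upregulated_fraction", "outlier_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")


@dataclass
class SimulatedDataset:
    """Counts, design and per-transcript truth for one simulated dataset."""

    counts: CountMatrix
    design: GroupDesign
    is_de: np.ndarray
    direction: np.ndarray  # +1 up in group A, -1 down in group A, 0 non-DE

    def __post_init__(self) -> None:
        self.is_de = np.asarray(self.is_de, dtype=bool)
        self.direction = np.asarray(self.direction, dtype=int)
        if self.is_de.shape[0] != self.counts.n_transcripts:
            raise ValueError("truth length does not match transcript count")

    @property
    def n_de(self) -> int:
        return int(self.is_de.sum())

    def truth_for(self, transcript_ids) -> np.ndarray:
        """DE indicator aligned to a (possibly filtered) transcript id list."""
        pos = {t: i for i, t in enumerate(self.counts.transcript_ids)}
        return self.is_de[[pos[t] for t in transcript_ids]]


def make_source_matrix(
    n_transcripts: int, n_samples: int, seed: int | None = None
) -> CountMatrix:
    """Overdispersed source matrix with a log-normal abundance profile.

    Per-transcript means span several orders of magnitude
    (log10 mean ~ N(2, 1)); per-sample library-size factors vary 4-fold;
    counts are gamma-Poisson (negative binomial) with moderate dispersion.
    """
    if n_transcripts < 1 or n_samples < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    mu = 10.0 ** rng.normal(2.0, 1.0, size=n_transcripts)
    phi = rng.uniform(0.1, 0.6, size=n_transcripts)
    lib = rng.uniform(0.5, 2.0, size=n_samples)
    lam = rng.gamma(
        shape=1.0 / phi[:, None],
        scale=(mu[:, None] * lib[None, :]) * phi[:, None],
    )
    values = rng.poisson(lam)
    return CountMatrix(
        values,
        [f"tx{i}" for i in range(n_transcripts)],
        [f"s{j}" for j in range(n_samples)],
    )


def resample_null(
    source: CountMatrix, n_per_group: int, seed: int | None = None
) -> SimulatedDataset:
    """Draw 2*n_per_group distinct columns and split them into two groups."""
    needed = 2 * n_per_group
    if source.n_samples < needed:
        raise ValueError(
            f"source has {source.n_samples} samples, need >= {needed}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(source.n_samples, size=needed, replace=False)
    ids = [source.sample_ids[i] for i in chosen]
    counts = source.subset_samples(ids)
    design = GroupDesign(tuple(ids[:n_per_group]), tuple(ids[n_per_group:]))
    g = counts.n_transcripts
    return SimulatedDataset(counts, design, np.zeros(g, bool), np.zeros(g, int))


def _draw_magnitudes(rng, magnitude: float, size: int, law: str) -> np.ndarray:
    """Positive perturbation sizes with spread = magnitude / 5."""
    sd = magnitude / 5.0
    if law == "normal":
        v = rng.normal(magnitude, sd, size=size)
    elif law == "uniform":
        half = sd * np.sqrt(3.0)
        v = rng.uniform(magnitude - half, magnitude + half, size=size)
    else:
        raise ValueError(f"unknown law {law!r}")
    return np.maximum(v, 0.0)


def _select_de(
    rng, n_transcripts: int, de_fraction: float, upregulated_fraction: float
):
    n_de = round(de_fraction * n_transcripts)
    if n_de > n_transcripts:
        raise ValueError("de_fraction selects more transcripts than available")
    sel = rng.choice(n_transcripts, size=n_de, replace=False)
    up = rng.random(n_de) < upregulated_fraction
    return sel, up


def apply_shift(
    data: SimulatedDataset,
    magnitude: float,
    de_fraction: float,
    upregulated_fraction: float = 0.5,
    seed: int | None = None,
    law: str = "normal",
) -> SimulatedDataset:
    """Add counts to selected transcripts in one group ("shift" alternative).

    For each selected transcript a quantity is drawn around ``magnitude``
    with standard deviation ``magnitude / 5``, rounded to a nonnegative
    integer, and added to every sample of one group; the receiving group
    is group A for "up" transcripts and group B otherwise.
    """
    if data.n_de:
        raise ValueError("apply_shift expects a null dataset")
    rng = np.random.default_rng(seed)
    values = data.counts.values.copy()
    g = data.counts.n_transcripts
    sel, up = _select_de(rng, g, de_fraction, upregulated_fraction)
    add = np.rint(_draw_magnitudes(rng, magnitude, sel.size, law)).astype(np.int64)
    idx_a = [data.counts.sample_ids.index(s) for s in data.design.group_a]
    idx_b = [data.counts.sample_ids.index(s) for s in data.design.group_b]
    for t, is_up, a in zip(sel, up, add):
        cols = idx_a if is_up else idx_b
        values[t, cols] += a
    is_de = np.zeros(g, bool)
    is_de[sel] = add > 0
    direction = np.zeros(g, int)
    direction[sel] = np.where(add > 0, np.where(up, 1, -1), 0)
    counts = CountMatrix(
        values, list(data.counts.transcript_ids), list(data.counts.sample_ids)
    )
    return SimulatedDataset(counts, data.design, is_de, direction)


def apply_scale_shift(
    data: SimulatedDataset,
    scale_magnitude: float,
    shift_magnitude: float,
    de_fraction: float,
    upregulated_fraction: float = 0.5,
    seed: int | None = None,
    law: str = "normal",
) -> SimulatedDataset:
    """Shift then multiply the affected group's counts ("scaling & shift").

    After ``apply_shift``, each selected transcript's counts in its
    affected group are multiplied by a factor drawn around
    ``scale_magnitude`` with standard deviation ``scale_magnitude / 5``
    and re-rounded to integers.
    """
    shifted = apply_shift(
        data, shift_magnitude, de_fraction, upregulated_fraction, seed=seed, law=law
    )
    rng = np.random.default_rng(None if seed is None else seed + 1)
    values = shifted.counts.values.copy()
    sel = np.flatnonzero(shifted.direction != 0)
    factors = _draw_magnitudes(rng, scale_magnitude, sel.size, law)
    idx_a = [shifted.counts.sample_ids.index(s) for s in shifted.design.group_a]
    idx_b = [shifted.counts.sample_ids.index(s) for s in shifted.design.group_b]
    for t, c in zip(sel, factors):
        cols = idx_a if shifted.direction[t] > 0 else idx_b
        values[t, cols] = np.rint(values[t, cols] * c).astype(np.int64)
    counts = CountMatrix(
        values, list(shifted.counts.transcript_ids), list(shifted.counts.sample_ids)
    )
    return SimulatedDataset(counts, shifted.design, shifted.is_de, shifted.direction)


def simulate_nb_counts(config: ScenarioConfig) -> SimulatedDataset:
    """Negative-binomial two-group counts with DE transcripts and outliers.

    Baseline means are log-normal on the count scale, dispersions uniform;
    DE transcripts have the mean of one group multiplied by
    ``effect_size`` (direction set by ``upregulated_fraction``).  Each
    matrix entry is independently replaced by an outlier — the count
    multiplied by a uniform factor in ``outlier_factor_range`` — with
    probability ``outlier_prob``.
    """
    rng = np.random.default_rng(config.seed)
    g, npg = config.n_transcripts, config.n_per_group
    mu = 10.0 ** rng.normal(
        config.log10_mean_loc, config.log10_mean_scale, size=g
    )
    phi = rng.uniform(*config.dispersion_range, size=g)
    sel, up = _select_de(rng, g, config.de_fraction, config.upregulated_fraction)
    fold = np.ones(g)
    fold[sel] = config.effect_size
    direction = np.zeros(g, int)
    direction[sel] = np.where(up, 1, -1)
    mu_a = np.where(direction >= 0, mu * fold, mu)
    mu_b = np.where(direction <= 0, mu * fold, mu)

    def draw(mu_g: np.ndarray) -> np.ndarray:
        lam = rng.gamma(
            shape=1.0 / phi[:, None],
            scale=np.broadcast_to((mu_g * phi)[:, None], (g, npg)),
        )
        return rng.poisson(lam)

    values = np.hstack([draw(mu_a), draw(mu_b)])
    if config.outlier_prob > 0:
        mask = rng.random(values.shape) < config.outlier_prob
        factors = rng.uniform(*config.outlier_factor_range, size=values.shape)
        values = np.where(mask, np.rint(values * factors).astype(np.int64), values)
    sample_ids = [f"a{j}" for j in range(npg)] + [f"b{j}" for j in range(npg)]
    counts = CountMatrix(values, [f"tx{i}" for i in range(g)], sample_ids)
    design = GroupDesign(tuple(sample_ids[:npg]), tuple(sample_ids[npg:]))
    is_de = np.zeros(g, bool)
    is_de[sel] = True
    return SimulatedDataset(counts, design, is_de, direction)
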
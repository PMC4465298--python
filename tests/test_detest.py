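import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from degps import CountMatrix, GroupDesign
from degps.detest import (
    DEResult,
    bh_adjust,
    build_null,
    empirical_pvalues,
    filter_all_zero,
    group_t_statistics,
    regularized_t_statistics,
    run_degps,
    t_statistic,
)
from degps.matrix import NormalizedMatrix
from degps.simulate import ScenarioConfig, simulate_nb_counts


def _norm(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        method="test",
    )


class TestDesign:
    def test_valid(self):
        d = GroupDesign(("a", "b"), ("c", "d", "e"))
        assert d.n_a == 2 and d.n_b == 3

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign(("a", "b"), ("b", "c"))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign(("a",), ("b", "c"))

    def test_from_mapping(self):
        d = GroupDesign.from_mapping({"s1": "x", "s2": "y", "s3": "x", "s4": "y"})
        assert set(d.group_a) == {"s1", "s3"}


class TestFilterAllZero:
    def test_removes_all_zero_row(self, toy_counts, toy_design):
        filtered, removed = filter_all_zero(toy_counts, toy_design)
        assert removed == ["t2"]
        assert filtered.n_transcripts == 5

    def test_identity_when_no_zero_rows(self, toy_design):
        m = CountMatrix(
            np.ones((3, 4), dtype=int), ["a", "b", "c"], ["s1", "s2", "s3", "s4"]
        )
        filtered, removed = filter_all_zero(m, toy_design)
        assert removed == []
        assert filtered.n_transcripts == 3

    def test_group_specific_zero_retained(self, toy_design):
        m = CountMatrix(
            np.array([[0, 0, 5, 7]]), ["a"], ["s1", "s2", "s3", "s4"]
        )
        filtered, removed = filter_all_zero(m, toy_design)
        assert filtered.n_transcripts == 1


class TestTStatistic:
    def test_equal_means_zero(self):
        assert t_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_arithmetic(self):
        # means 3, 2; variances 2, 2; T = 1/sqrt(1 + 1)
        assert t_statistic([2, 4], [1, 3]) == pytest.approx(1 / math.sqrt(2))

    def test_matches_textbook_welch(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 10))
            y = rng.normal(size=rng.integers(2, 10))
            want = (x.mean() - y.mean()) / math.sqrt(
                x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y)
            )
            assert t_statistic(x, y) == pytest.approx(want, abs=1e-12)

    def test_zero_variance_sentinel(self):
        assert math.isnan(t_statistic([2, 2], [3, 3]))

    def test_small_group_error(self):
        with pytest.raises(ValueError):
            t_statistic([1], [2, 3])


class TestBuildNull:
    def test_exhaustive_small_design(self):
        norm = _norm(np.arange(12).reshape(3, 4))
        d = GroupDesign(("s0", "s1"), ("s2", "s3"))
        null = build_null(norm, d, max_perms=1000, seed=0)
        assert null.exhaustive
        assert null.n_perms == 5  # choose(4,2) - identity
        assert null.pooled_stats.size == 15

    def test_identity_excluded(self):
        norm = _norm([[10.0, 11.0, 0.0, 1.0], [3.0, 4.0, 9.0, 8.0]])
        d = GroupDesign(("s0", "s1"), ("s2", "s3"))
        null = build_null(norm, d, max_perms=1000, seed=0)
        obs = group_t_statistics(norm, d)
        # the observed (identity) statistics are absent from the pool
        for t in obs:
            assert not np.any(np.isclose(null.pooled_stats, t))

    def test_seed_invariant_when_exhaustive(self, rng):
        norm = _norm(rng.poisson(20, size=(50, 10)))
        d = GroupDesign(tuple(f"s{j}" for j in range(5)), tuple(f"s{j}" for j in range(5, 10)))
        n1 = build_null(norm, d, max_perms=1000, seed=1)
        n2 = build_null(norm, d, max_perms=1000, seed=99)
        assert n1.exhaustive and n1.n_perms == 251
        assert np.array_equal(n1.pooled_stats, n2.pooled_stats)

    def test_random_subset_when_over_budget(self, rng):
        norm = _norm(rng.poisson(20, size=(20, 12)))
        d = GroupDesign(tuple(f"s{j}" for j in range(6)), tuple(f"s{j}" for j in range(6, 12)))
        null = build_null(norm, d, max_perms=100, seed=5)
        assert not null.exhaustive
        assert null.n_perms == 100
        again = build_null(norm, d, max_perms=100, seed=5)
        assert np.array_equal(null.pooled_stats, again.pooled_stats)

    def test_worker_count_independence(self, rng):
        norm = _norm(rng.poisson(20, size=(30, 8)))
        d = GroupDesign(tuple(f"s{j}" for j in range(4)), tuple(f"s{j}" for j in range(4, 8)))
        serial = build_null(norm, d, seed=3, n_workers=1)
        parallel = build_null(norm, d, seed=3, n_workers=2, chunk_size=16)
        assert np.array_equal(serial.pooled_stats, parallel.pooled_stats)

    def test_symmetry_on_exchangeable_data(self, rng):
        norm = _norm(rng.normal(10, 2, size=(400, 10)))
        d = GroupDesign(tuple(f"s{j}" for j in range(5)), tuple(f"s{j}" for j in range(5, 10)))
        null = build_null(norm, d, max_perms=1000, seed=0)
        pool = null.pooled_stats
        se = pool.std() / math.sqrt(pool.size)
        assert abs(pool.mean()) < 3 * se
        from scipy.stats import skew

        assert abs(skew(pool)) < 0.1


class TestEmpiricalPvalues:
    def test_boundary_most_extreme(self):
        null = build_null(
            _norm(np.arange(20).reshape(5, 4)),
            GroupDesign(("s0", "s1"), ("s2", "s3")),
        )
        n = null.pooled_stats.size
        p = empirical_pvalues(np.array([1e9]), null)
        assert p[0] == pytest.approx(1.0 / (n + 1))

    def test_zero_stat_p_near_one(self):
        null = build_null(
            _norm(np.random.default_rng(0).poisson(10, (50, 4))),
            GroupDesign(("s0", "s1"), ("s2", "s3")),
        )
        p = empirical_pvalues(np.array([0.0]), null)
        assert p[0] == 1.0

    def test_nan_maps_to_one(self):
        null = build_null(
            _norm(np.random.default_rng(0).poisson(10, (50, 4))),
            GroupDesign(("s0", "s1"), ("s2", "s3")),
        )
        p = empirical_pvalues(np.array([np.nan]), null)
        assert p[0] == 1.0

    def test_hand_enumeration_toy(self):
        """3 transcripts, 4 samples: p-values from explicit enumeration."""
        vals = np.array(
            [[4.0, 6.0, 1.0, 2.0], [10.0, 9.0, 11.0, 13.0], [0.0, 5.0, 3.0, 8.0]]
        )
        norm = _norm(vals)
        d = GroupDesign(("s0", "s1"), ("s2", "s3"))
        null = build_null(norm, d, max_perms=1000)

        def welch(x, y):
            x, y = np.asarray(x, float), np.asarray(y, float)
            den = x.var(ddof=1) / 2 + y.var(ddof=1) / 2
            return (x.mean() - y.mean()) / math.sqrt(den) if den else math.nan

        pool = []
        for combo in combinations(range(4), 2):
            if combo == (0, 1):
                continue
            rest = [j for j in range(4) if j not in combo]
            for g in range(3):
                t = welch(vals[g, list(combo)], vals[g, rest])
                if not math.isnan(t):
                    pool.append(t)
        assert len(pool) == null.pooled_stats.size == 15
        obs = [welch(vals[g, :2], vals[g, 2:]) for g in range(3)]
        want = [
            (1 + sum(abs(s) >= abs(t) for s in pool)) / (1 + len(pool)) for t in obs
        ]
        got = empirical_pvalues(np.array(obs), null)
        assert np.allclose(got, want)

    def test_monotone_in_abs_t(self, rng):
        null = build_null(
            _norm(rng.poisson(10, (100, 6))),
            GroupDesign(("s0", "s1", "s2"), ("s3", "s4", "s5")),
        )
        ts = np.linspace(0, 5, 50)
        p = empirical_pvalues(ts, null)
        assert np.all(np.diff(p) <= 0)


class TestBH:
    def test_three_values(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_value(self):
        assert bh_adjust(np.array([0.2]))[0] == 0.2

    def test_matches_statsmodels(self, rng):
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 50))
            want = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), want, atol=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(1e-6, 1, 200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= p - 1e-15)


class TestRegularizedT:
    def _setup(self, rng):
        norm = _norm(rng.normal(10, 2, size=(500, 8)))
        d = GroupDesign(tuple(f"s{j}" for j in range(4)), tuple(f"s{j}" for j in range(4, 8)))
        return norm, d

    def test_zero_weight_equals_ordinary(self, rng):
        norm, d = self._setup(rng)
        reg = regularized_t_statistics(norm, d, shrinkage_weight=0.0)
        ord_ = group_t_statistics(norm, d)
        assert np.allclose(reg, ord_, equal_nan=True)

    def test_full_weight_shares_pooled_variance(self, rng):
        norm, d = self._setup(rng)
        reg = regularized_t_statistics(norm, d, shrinkage_weight=1.0)
        xa = norm.values[:, :4]
        xb = norm.values[:, 4:]
        va = np.median(xa.var(axis=1, ddof=1))
        vb = np.median(xb.var(axis=1, ddof=1))
        want = (xa.mean(axis=1) - xb.mean(axis=1)) / np.sqrt(va / 4 + vb / 4)
        assert np.allclose(reg, want)

    def test_ranking_correlates_with_ordinary(self):
        data = simulate_nb_counts(
            ScenarioConfig(n_transcripts=2000, n_per_group=5, de_fraction=0.1, seed=17)
        )
        from degps.normalize import normalize

        norm = normalize(data.counts, "gp-theta")
        reg = regularized_t_statistics(norm, data.design)
        ord_ = group_t_statistics(norm, data.design)
        ok = np.isfinite(reg) & np.isfinite(ord_)
        from scipy.stats import spearmanr

        rho = spearmanr(reg[ok], ord_[ok]).statistic
        assert rho > 0.9


class TestRunDegps:
    def test_sample_order_invariance(self, rng):
        data = simulate_nb_counts(
            ScenarioConfig(n_transcripts=100, n_per_group=3, seed=8)
        )
        r1 = run_degps(data.counts, data.design, method="global", seed=0)
        perm = rng.permutation(data.counts.n_samples)
        shuffled = data.counts.subset_samples(
            [data.counts.sample_ids[i] for i in perm]
        )
        r2 = run_degps(shuffled, data.design, method="global", seed=0)
        assert np.allclose(r1.t_obs, r2.t_obs, equal_nan=True)
        assert np.allclose(r1.p_value, r2.p_value)

    def test_label_swap_antisymmetry(self):
        data = simulate_nb_counts(
            ScenarioConfig(n_transcripts=100, n_per_group=3, seed=9)
        )
        d = data.design
        swapped = GroupDesign(d.group_b, d.group_a)
        r1 = run_degps(data.counts, d, method="global", seed=0)
        r2 = run_degps(data.counts, swapped, method="global", seed=0)
        assert np.allclose(r1.t_obs, -r2.t_obs, equal_nan=True)
        assert np.allclose(r1.p_value, r2.p_value)

    def test_scale_invariance_of_test(self, rng):
        norm = _norm(rng.poisson(30, (200, 6)).astype(float))
        d = GroupDesign(("s0", "s1", "s2"), ("s3", "s4", "s5"))
        t1 = group_t_statistics(norm, d)
        null1 = build_null(norm, d, seed=0)
        # power-of-two factor keeps the float arithmetic exact, so the
        # |s| >= |t| tie comparisons are unaffected
        scaled = _norm(norm.values * 8.0)
        t2 = group_t_statistics(scaled, d)
        null2 = build_null(scaled, d, seed=0)
        assert np.allclose(t1, t2, equal_nan=True)
        assert np.allclose(
            empirical_pvalues(t1, null1), empirical_pvalues(t2, null2)
        )

    def test_significant_flag_matches_threshold(self):
        data = simulate_nb_counts(
            ScenarioConfig(n_transcripts=300, n_per_group=4, de_fraction=0.2, seed=10)
        )
        r = run_degps(data.counts, data.design, seed=1, fdr_threshold=0.1)
        assert np.array_equal(r.significant, r.p_adjusted < 0.1)

    def test_result_frame_columns(self):
        data = simulate_nb_counts(ScenarioConfig(n_transcripts=50, n_per_group=3, seed=2))
        r = run_degps(data.counts, data.design, seed=1)
        df = r.to_frame()
        assert list(df.columns) == [
            "transcript_id", "t_stat", "p_value", "p_adjusted", "significant",
        ]


@settings(max_examples=20, deadline=None)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
def test_bh_properties(pvals):
    p = np.array(pvals)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_null_pvalue_uniformity_aggregate():
    """Under exchangeable data, pooled-permutation p-values are ~uniform."""
    from scipy.stats import kstest

    rng = np.random.default_rng(33)
    pvals = []
    for _ in range(10):
        vals = rng.poisson(25, size=(500, 10)).astype(float)
        norm = _norm(vals)
        d = GroupDesign(tuple(f"s{j}" for j in range(5)), tuple(f"s{j}" for j in range(5, 10)))
        t = group_t_statistics(norm, d)
        null = build_null(norm, d, seed=0)
        pvals.append(empirical_pvalues(t, null))
    p = np.concatenate(pvals)
    assert kstest(p, "uniform").statistic < 0.05
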
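"""Tie-aware Spearman correlation and its permutation null."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from buffercrops import (
    BinSeries,
    BinStat,
    BinnedProxy,
    CROPS,
    average_ranks,
    exact_permutation_p,
    permutation_test,
    run_association_suite,
    spearman_rho,
    summary_table,
)


def brute_force_rho(x, y):
    """Independent oracle: midranks by counting, Pearson by explicit sums."""
    def ranks(v):
        return [
            1 + sum(1 for u in v if u < w) + sum(1 for j, u in enumerate(v) if u == w and j != i) / 2
            for i, w in enumerate(v)
        ]

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestAverageRanks:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ([10, 20, 30], [1, 2, 3]),
            ([5, 5, 9], [1.5, 1.5, 3]),
            ([7, 7, 7, 7], [2.5, 2.5, 2.5, 2.5]),
        ],
    )
    def test_midranks(self, x, expected):
        np.testing.assert_allclose(average_ranks(x), expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            average_ranks([1.0, np.inf, 2.0])


class TestSpearmanRho:
    def test_monotone_extremes(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tie_handling_against_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        assert spearman_rho(x, y) == pytest.approx(brute_force_rho(x, y), abs=1e-12)

    def test_matches_scipy_on_tied_data(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman_rho(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12
            )

    def test_pairwise_deletion_of_missing(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 1.0, 8.0, np.nan]
        assert spearman_rho(x, y) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman_rho([1, 2, 3], [5, 5, 5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=-50, max_value=50), min_size=4, max_size=15),
        st.randoms(use_true_random=False),
    )
    def test_symmetry_and_monotone_invariance(self, xs, rnd):
        ys = list(xs)
        rnd.shuffle(ys)
        x, y = np.array(xs, float), np.array(ys, float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        rho = spearman_rho(x, y)
        assert spearman_rho(y, x) == pytest.approx(rho, abs=1e-12)
        # strictly monotone transform of either side leaves rho unchanged
        assert spearman_rho(np.exp(x / 50.0), y) == pytest.approx(rho, abs=1e-12)
        assert spearman_rho(x, 3 * y + 7) == pytest.approx(rho, abs=1e-12)


class TestExactPermutationP:
    def test_three_points_two_sided(self):
        assert exact_permutation_p([1, 2, 3], [1, 2, 3]) == pytest.approx(2 / 6)

    def test_constant_y_error(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            exact_permutation_p([1, 2, 3], [1, 1, 1])

    def test_n4_matches_independent_enumeration(self):
        x = [1.0, 2.0, 2.0, 4.0]
        y = [3.0, 1.0, 4.0, 2.0]
        obs = stats.spearmanr(x, y).statistic
        hits = sum(
            abs(stats.spearmanr(x, perm).statistic) >= abs(obs) - 1e-12
            for perm in itertools.permutations(y)
        )
        assert exact_permutation_p(x, y) == pytest.approx(hits / 24)

    def test_large_n_refused(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            exact_permutation_p(list(range(9)), list(range(9)))


class TestPermutationTest:
    def test_perfect_monotone_association_is_extreme(self):
        x = list(range(1, 11))
        res = permutation_test(x, x, n_perm=999, seed=0)
        assert res.rho_obs == pytest.approx(1.0)
        assert res.p_value <= 5 / 1000
        assert res.p_value >= 1 / 1000  # add-one floor

    def test_determinism_and_seed_sensitivity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=15), rng.normal(size=15)
        a = permutation_test(x, y, n_perm=500, seed=7)
        b = permutation_test(x, y, n_perm=500, seed=7)
        assert a == b
        c = permutation_test(x, y, n_perm=2000, seed=8)
        se = math.sqrt(a.p_value * (1 - a.p_value) / 500)
        assert abs(c.p_value - a.p_value) <= 4 * se + 1e-9

    def test_monte_carlo_converges_to_exact(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0, 3.0]
        y = [2.0, 1.0, 4.0, 5.0, 6.0, 2.0]
        p_exact = exact_permutation_p(x, y)
        res = permutation_test(x, y, n_perm=4000, seed=3)
        k_over_b = (res.p_value * (res.n_perm + 1) - 1) / res.n_perm
        se = math.sqrt(p_exact * (1 - p_exact) / res.n_perm)
        assert abs(k_over_b - p_exact) <= 3 * se

    def test_one_sided_alternatives(self):
        x = list(range(8))
        res_g = permutation_test(x, x, n_perm=999, alternative="greater", seed=1)
        res_l = permutation_test(x, x, n_perm=999, alternative="less", seed=1)
        assert res_g.p_value < 0.05
        assert res_l.p_value > 0.9

    def test_null_quantiles_bracket_zero(self):
        rng = np.random.default_rng(1)
        res = permutation_test(rng.normal(size=17), rng.normal(size=17), n_perm=2000, seed=2)
        assert res.null_quantiles["q05"] < 0 < res.null_quantiles["q95"]
        assert abs(res.null_quantiles["q50"]) < 0.2


def tiny_series():
    rng = np.random.default_rng(12)
    bins = []
    for b in range(100, 600, 100):
        pct = rng.dirichlet(np.ones(5)) * 100
        bins.append(BinStat(b, dict(zip(CROPS, pct)), 3))
    return BinSeries(bins=bins)


class TestAssociationSuite:
    def test_cardinality_five_crops_two_proxies(self):
        series = tiny_series()
        proxies = [
            BinnedProxy("t", [(b, float(b % 7), 1) for b in series.bin_starts()]),
            BinnedProxy("p", [(b, float((b // 100) % 3), 1) for b in series.bin_starts()]),
        ]
        results = run_association_suite(series, proxies, n_perm=200, seed=0)
        assert len(results) == 10

    def test_pairwise_deletion_shrinks_n_bins(self):
        series = tiny_series()
        proxies = [BinnedProxy("t", [(b, float(b), 1) for b in series.bin_starts()[:4]])]
        results = run_association_suite(series, proxies, n_perm=100, seed=0)
        assert all(r.n_bins == 4 for r in results)

    def test_too_few_joint_bins_skipped(self, caplog):
        series = tiny_series()
        proxies = [BinnedProxy("t", [(100, 1.0, 1), (200, 2.0, 1)])]
        results = run_association_suite(series, proxies, n_perm=100, seed=0)
        assert results == []

    def test_rho_invariant_under_bin_relabeling(self):
        series = tiny_series()
        proxies = [BinnedProxy("t", [(b, float(b % 7), 1) for b in series.bin_starts()])]
        shifted = BinSeries(
            bins=[BinStat(b.bin_start + 1000, b.mean_percent, b.n_contexts) for b in series.bins]
        )
        proxies_shifted = [
            BinnedProxy("t", [(b + 1000, v, n) for b, v, n in proxies[0].bins])
        ]
        r1 = run_association_suite(series, proxies, n_perm=50, seed=0)
        r2 = run_association_suite(shifted, proxies_shifted, n_perm=50, seed=0)
        for a, b in zip(r1, r2):
            assert a.rho_obs == pytest.approx(b.rho_obs, abs=1e-12)

    def test_summary_table_rounds_and_adjusts(self):
        series = tiny_series()
        proxies = [BinnedProxy("t", [(b, float(b % 7), 1) for b in series.bin_starts()])]
        df = summary_table(run_association_suite(series, proxies, n_perm=200, seed=0))
        assert {"rho_2dp", "p_bh"} <= set(df.columns)
        assert (df["rho_2dp"] == df["rho_obs"].round(2)).all()
        assert (df["p_bh"] >= df["p_value"] - 1e-12).all()
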
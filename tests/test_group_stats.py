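"""Rank-sum tests, BH correction, effect sizes and magnitude labels."""

import math
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flysleep.group_stats import (
    bh_adjust,
    classify_magnitude,
    compare_parameter,
    effect_size_r,
    kruskal_wallis,
    wilcoxon_rank_sum,
)

DATA_DIR = Path(__file__).parent / "data"


def enumeration_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Independent oracle: for tie-free pooled data, enumerate all C(n1+n2, n1)
    ways to assign ranks to the first group and count assignments whose
    rank-sum is at least as extreme as observed.
    """
    pooled = sorted(x) + sorted(y)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    n1 = len(x)
    observed = sum(ranks[v] for v in x)
    mean = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for combo in combinations(range(1, len(pooled) + 1), n1):
        total += 1
        if abs(sum(combo) - mean) >= abs(observed - mean) - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_extreme_separation_small_n(self):
        # all 20 assignments enumerable; the 2 most extreme give p = 0.1
        _, p, z = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert z < 0

    def test_identical_samples(self):
        _, p, z = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)
        assert z == pytest.approx(0.0)

    def test_symmetric_under_swap(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=5)
        _, pxy, zxy = wilcoxon_rank_sum(x, y)
        _, pyx, zyx = wilcoxon_rank_sum(y, x)
        assert pxy == pytest.approx(pyx)
        assert zxy == pytest.approx(-zyx)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 13 - n1))
            pooled = rng.permutation(np.arange(n1 + n2, dtype=float))  # tie-free
            x, y = pooled[:n1], pooled[n1:]
            _, p, _ = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(enumeration_p(list(x), list(y)), abs=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_z_is_tie_corrected(self):
        # heavy ties shrink the rank variance; Z must use the corrected sigma
        x = [1, 1, 1, 2, 2]
        y = [2, 2, 3, 3, 3]
        _, _, z = wilcoxon_rank_sum(x, y)
        n1, n2 = 5, 5
        u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        pooled = np.array(x + y)
        _, t = np.unique(pooled, return_counts=True)
        sigma = math.sqrt(n1 * n2 / 12 * (11 - (t**3 - t).sum() / (10 * 9)))
        assert z == pytest.approx((u - n1 * n2 / 2) / sigma)


class TestEffectSize:
    def test_zero_z(self):
        assert effect_size_r(0.0, 10) == 0.0

    def test_arithmetic(self):
        assert effect_size_r(2.0, 16) == pytest.approx(0.5)
        assert effect_size_r(-2.0, 16) == pytest.approx(0.5)  # magnitude only

    def test_too_small_n_errors(self):
        with pytest.raises(ValueError):
            effect_size_r(1.0, 1)

    def test_monotone_in_location_shift(self, rng):
        rs = []
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            x = rng.normal(0, 1, 30)
            y = rng.normal(shift, 1, 30)
            _, _, z = wilcoxon_rank_sum(x, y)
            rs.append(effect_size_r(z, 60))
        assert rs == sorted(rs)

    def test_invariant_under_monotone_transform(self, rng):
        x, y = rng.normal(size=12), rng.normal(1.0, 1.0, size=15)
        _, _, z1 = wilcoxon_rank_sum(x, y)
        _, _, z2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert effect_size_r(z1, 27) == pytest.approx(effect_size_r(z2, 27))


class TestBHAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_order_preserving_and_dominates_raw(self, rng):
        p = rng.random(20)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_manual_rank_computation(self):
        # groups (1,2), (10,11), (20,21): ranks (1,2), (3,4), (5,6)
        # H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2 with N=6, rbar=3.5
        h, _ = kruskal_wallis([1, 2], [10, 11], [20, 21])
        manual = 12 / (6 * 7) * 2 * ((1.5 - 3.5) ** 2 + (3.5 - 3.5) ** 2 + (5.5 - 3.5) ** 2)
        assert h == pytest.approx(manual)

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3])

    def test_null_rejection_rate(self, rng):
        rejections = 0
        n_reps = 500
        for _ in range(n_reps):
            groups = [rng.normal(size=12) for _ in range(3)]
            _, p = kruskal_wallis(*groups)
            rejections += p < 0.05
        rate = rejections / n_reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_reps)


class TestMagnitude:
    def test_non_significant_is_blank(self):
        assert classify_magnitude(0.9, 0.06) == ""

    @pytest.mark.parametrize(
        "r,p,label",
        [
            (0.51, 1.0e-07, "large"),
            (0.27, 5.2e-03, "small"),
            (0.096, 0.35, ""),
            (0.29, 1.63e-02, "small"),
            (0.31, 1.6e-02, "moderate"),
            (0.42, 9.6e-06, "moderate"),
        ],
    )
    def test_published_examples(self, r, p, label):
        assert classify_magnitude(r, p) == label

    def test_reproduces_all_published_rows(self):
        """Every printed (p, r, magnitude) triple from the published statistics tables.

        Rows whose printed r sits exactly on a category cut-point (0.30 or
        0.50) are accepted with either adjacent label, since printed values
        are rounded to two decimals and classification acts on unrounded r.
        """
        rows = pd.read_csv(DATA_DIR / "published_comparison_rows.csv",
                           keep_default_na=False)
        assert len(rows) == 192
        for row in rows.itertuples():
            got = classify_magnitude(row.effect_size_r, row.p_value)
            if row.p_value < 0.05 and row.effect_size_r in (0.30, 0.50):
                lo, hi = (("small", "moderate") if row.effect_size_r == 0.30
                          else ("moderate", "large"))
                assert row.magnitude in (lo, hi)
                assert got in (lo, hi)
            else:
                assert got == row.magnitude, (
                    f"table {row.table} {row.parameter} {row.comparison}: "
                    f"classify({row.effect_size_r}, {row.p_value}) = {got!r}, "
                    f"published {row.magnitude!r}"
                )


class TestCompareParameter:
    def test_two_groups_skip_correction(self, rng):
        groups = {"a": rng.normal(size=10), "b": rng.normal(size=10)}
        (row,) = compare_parameter("day_sleep", groups)
        assert row.p_adj == row.p_raw
        assert row.kw_p is None

    def test_three_groups_get_kw_and_bh(self, rng):
        groups = {g: rng.normal(size=10) for g in "abc"}
        rows = compare_parameter("day_sleep", groups)
        assert len(rows) == 3  # C(3,2)
        assert all(r.kw_p is not None for r in rows)
        assert all(r.p_adj >= r.p_raw - 1e-12 for r in rows)

    def test_nan_values_are_dropped_from_n(self, rng):
        a = np.concatenate([rng.normal(size=8), [np.nan, np.nan]])
        b = rng.normal(size=9)
        (row,) = compare_parameter("day_waking_activity", {"a": a, "b": b})
        assert (row.n1, row.n2) == (8, 9)

    def test_undersized_group_names_genotype(self):
        with pytest.raises(ValueError, match="mutantX"):
            compare_parameter("day_sleep", {"ctrl": [1, 2, 3], "mutantX": [1.0]})

    def test_null_false_positive_rate(self, rng):
        significant = 0
        reps = 200
        for _ in range(reps):
            groups = {"a": rng.normal(size=15), "b": rng.normal(size=15)}
            (row,) = compare_parameter("day_sleep", groups)
            significant += row.significant
        assert significant / reps < 0.12  # ~alpha, generous margin
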
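"""Comparative-Ct quantification, fold-changes, ratios, and group tests."""

import itertools
import math

import numpy as np
import pytest

from splicedex.qpcr_expression import (
    CtRecord,
    ExpressionPanel,
    build_panel,
    compare_groups,
    delta_ct,
    dunn_posthoc,
    group_fold_change,
    long_short_ratio,
    relative_expression,
)


def exact_mann_whitney_p(x, y):
    """Brute-force two-sided Mann-Whitney p by enumerating all C(n1+n2, n1)
    assignments of the pooled values to the first group."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(g1, g2):
        return sum(
            (a > b) + 0.5 * (a == b) for a in g1 for b in g2
        )

    obs = u_stat(x, y)
    mu = n1 * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(g1, g2) - mu) >= abs(obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestComparativeCt:
    @pytest.mark.parametrize("t,r,expected", [(25.0, 25.0, 0.0), (28.0, 25.0, 3.0)])
    def test_delta_ct(self, t, r, expected):
        assert delta_ct(t, r) == expected

    def test_replicate_means_then_subtract(self):
        rec_t = CtRecord("s", "CTR", "long", (27.2, 27.6))
        rec_r = CtRecord("s", "CTR", "reference", (24.0, 24.2))
        assert delta_ct(rec_t.ct_mean, rec_r.ct_mean) == pytest.approx(3.3)

    @pytest.mark.parametrize("dct,expected", [(0, 1.0), (1, 0.5), (-2, 4.0)])
    def test_relative_expression(self, dct, expected):
        assert relative_expression(dct) == expected

    def test_one_cycle_doubles_expression(self):
        assert relative_expression(delta_ct(24.0, 25.0)) == 2 * relative_expression(
            delta_ct(25.0, 25.0)
        )

    def test_ct_outside_range_rejected(self):
        with pytest.raises(ValueError):
            CtRecord("s", "CTR", "long", (46.0,))

    def test_build_panel_requires_all_targets(self):
        recs = [CtRecord("s1", "CTR", "long", (25.0,)),
                CtRecord("s1", "CTR", "reference", (24.0,))]
        with pytest.raises(ValueError, match="short"):
            build_panel(recs)


class TestGroupFoldChange:
    def test_identical_groups_plus_one(self):
        assert group_fold_change([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_elementwise_division_recovers_planted(self):
        b = np.array([0.5, 1.0, 2.0, 4.0])
        assert group_fold_change(b / 3.3, b) == pytest.approx(-3.3)

    def test_matches_hand_computed_geometric_means(self):
        a = [1.0, 2.0, 4.0, 8.0]  # gm = 2*sqrt(2)
        b = [1.0, 1.0, 2.0, 2.0]  # gm = sqrt(2)
        assert group_fold_change(a, b) == pytest.approx(2.0)

    def test_arithmetic_flag(self):
        assert group_fold_change([1.0, 3.0], [1.0, 1.0], aggregation="arithmetic") == 2.0

    def test_antisymmetry(self):
        a, b = [0.3, 0.9, 0.5], [1.1, 2.0, 1.4]
        assert group_fold_change(a, b) == pytest.approx(-group_fold_change(b, a))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            group_fold_change([0.0, 1.0], [1.0, 1.0])


class TestLongShortRatio:
    def panel(self, long, short, group="CTR"):
        import pandas as pd

        return ExpressionPanel(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(long))],
            "group": group, "long_expr": long, "short_expr": short,
        }))

    def test_equal_targets_unit_ratio(self):
        r = long_short_ratio(self.panel([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert r.per_group["CTR"] == (1.0, 0.0)

    def test_hand_computed_mean_and_sample_sd(self):
        r = long_short_ratio(self.panel([2.0, 4.0, 6.0], [1.0, 1.0, 1.0]))
        assert r.per_group["CTR"] == (4.0, 2.0)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        res = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, "two_unpaired")
        assert res["test_name"] == "mann-whitney"
        assert res["p_value"] > 0.9

    def test_exact_u_test_on_separated_triples(self):
        res = compare_groups({"a": [1.0, 2.0, 3.0], "b": [10.0, 11.0, 12.0]}, "two_unpaired")
        assert res["statistic"] == 0.0
        assert res["p_value"] == pytest.approx(0.1)  # 2/C(6,3)

    @pytest.mark.parametrize("seed", range(12))
    def test_mann_whitney_agrees_with_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
        x = rng.integers(0, 15, size=n1).astype(float)
        y = (rng.integers(0, 15, size=n2) + rng.integers(0, 6)).astype(float)
        res = compare_groups({"a": x, "b": y}, "two_unpaired")
        # ties force the tie-corrected normal approximation; compare only
        # tie-free draws against the exact enumeration oracle
        if len(np.unique(np.concatenate([x, y]))) == n1 + n2:
            assert res["p_value"] == pytest.approx(exact_mann_whitney_p(x, y))

    def test_all_tied_pairs_give_p_one(self):
        res = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, "two_paired")
        assert res["p_value"] == 1.0

    def test_paired_detects_shift(self):
        x = np.arange(1.0, 11.0)
        res = compare_groups({"a": x, "b": x + 2}, "two_paired")
        assert res["test_name"] == "wilcoxon"
        assert res["p_value"] < 0.01

    def test_three_identical_groups_kruskal_p_one(self):
        g = [1.0, 2.0, 3.0]
        res = compare_groups({"a": g, "b": g, "c": g}, "k_groups")
        assert res["test_name"] == "kruskal-wallis"
        assert res["p_value"] == 1.0

    def test_kruskal_with_dunn_posthoc_flags_outlier_group(self):
        groups = {
            "a": [1.0, 2.0, 3.0, 4.0, 2.5],
            "b": [1.5, 2.5, 3.5, 2.0, 3.0],
            "c": [20.0, 21.0, 22.0, 23.0, 24.0],
        }
        res = compare_groups(groups, "k_groups")
        assert res["p_value"] < 0.01
        post = res["posthoc"]
        assert post[("a", "c")] < 0.05 and post[("b", "c")] < 0.05
        assert post[("a", "b")] > 0.5
        assert all(0 <= p <= 1 for p in post.values())

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]}, "two_paired")


class TestDunnAgainstNormalOracle:
    def test_two_group_dunn_matches_direct_z(self):
        # with two groups and no ties, Dunn's z equals the standardized
        # rank-sum difference; check against a direct computation
        from scipy import stats

        a = np.array([1.0, 4.0, 6.0])
        b = np.array([2.0, 8.0, 9.0, 11.0])
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        z = (ranks[:3].mean() - ranks[3:].mean()) / math.sqrt(
            n * (n + 1) / 12 * (1 / 3 + 1 / 4)
        )
        expected = min(1.0, 2 * stats.norm.sf(abs(z)))
        assert dunn_posthoc({"a": a, "b": b})[("a", "b")] == pytest.approx(expected)
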
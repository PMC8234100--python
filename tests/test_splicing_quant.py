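"""Normalization, background filter, splicing-index fold-change and filter."""

import numpy as np
import pandas as pd
import pytest

from splicedex.reference_tables import PUBLISHED_TOP_EVENTS, published_top_events_as_results
from splicedex.splicing_quant import (
    CountMatrix,
    NormalizationError,
    SampleDesign,
    background_threshold,
    expressed_filter,
    filter_significant,
    rpkm,
    size_factors,
    splicing_index,
    splicing_index_fc,
    test_event as welch_log_si_test,
)


def cm(data, lengths=None, samples=None):
    df = pd.DataFrame(data)
    if samples is not None:
        df.columns = samples
    lengths = pd.Series(
        lengths if lengths is not None else [100] * len(df), index=df.index
    )
    return CountMatrix(df, lengths)


def design_2v2():
    return SampleDesign(
        {"c1": "CTR", "c2": "CTR", "d1": "CAD", "d2": "CAD"}, reference_group="CTR"
    )


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = cm({"s1": [10, 30, 7], "s2": [10, 30, 7]})
        np.testing.assert_allclose(size_factors(m).to_numpy(), [1.0, 1.0])

    def test_doubled_column_doubles_factor(self):
        m = cm({"s1": [10, 30, 7], "s2": [20, 60, 14]})
        f = size_factors(m)
        np.testing.assert_allclose(f["s2"] / f["s1"], 2.0)

    def test_hand_computed_median_of_ratios(self):
        # 3 features x 2 samples; oracle: per-feature geometric means, then
        # per-sample median ratio, computed by hand
        counts = {"s1": [4, 9, 25], "s2": [16, 36, 1]}
        m = cm(counts)
        gm = [8.0, 18.0, 5.0]  # sqrt(4*16), sqrt(9*36), sqrt(25*1)
        expect_s1 = np.median([4 / 8, 9 / 18, 25 / 5])
        expect_s2 = np.median([16 / 8, 36 / 18, 1 / 5])
        f = size_factors(m)
        np.testing.assert_allclose(f.to_numpy(), [expect_s1, expect_s2])

    def test_agrees_with_deseq2_reference_implementation(self):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(42)
        counts = rng.poisson(50, size=(30, 4)) + 1
        m = cm({f"s{i}": counts[:, i] for i in range(4)})
        _, ref = pydeseq2.deseq2_norm(counts.T)  # samples x features
        np.testing.assert_allclose(size_factors(m).to_numpy(), ref, rtol=1e-10)

    def test_no_all_positive_row_is_an_error(self):
        m = cm({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(NormalizationError):
            size_factors(m)


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,mapped,expected",
        [(1000, 1000, 10**6, 1000.0), (0, 1000, 10**6, 0.0), (250, 500, 2 * 10**6, 250.0)],
    )
    def test_formula(self, count, length, mapped, expected):
        assert rpkm(count, length, mapped) == expected

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rpkm(10, 0, 10**6)
        with pytest.raises(ValueError):
            rpkm(10, 100, 0)


class TestExpressedFilter:
    def test_zero_background_keeps_expressed_gene(self):
        gene = pd.Series([5.0, 5.0, 0.0, 0.0], index=["c1", "c2", "d1", "d2"])
        s = expressed_filter(gene, design_2v2(), np.zeros(25))
        assert s.expressed == {"CTR": True, "CAD": False}
        assert s.retained

    def test_below_threshold_everywhere_dropped(self):
        gene = pd.Series([0.1] * 4, index=["c1", "c2", "d1", "d2"])
        s = expressed_filter(gene, design_2v2(), np.full(25, 10.0))
        assert not s.retained

    def test_percentile_matches_order_statistic_oracle(self):
        # 40 sorted values 1..40: linear interpolation lands at 0-based rank
        # h = 0.975*39 = 38.025, so x_[38] + 0.025*(x_[39]-x_[38]) = 39.025
        bg = np.arange(1.0, 41.0)
        assert background_threshold(bg) == pytest.approx(39.025)
        gene_hi = pd.Series([39.1, 39.1, 0.0, 0.0], index=["c1", "c2", "d1", "d2"])
        gene_lo = pd.Series([39.0, 39.0, 0.0, 0.0], index=["c1", "c2", "d1", "d2"])
        assert expressed_filter(gene_hi, design_2v2(), bg).retained
        assert not expressed_filter(gene_lo, design_2v2(), bg).retained

    def test_small_background_is_an_error(self):
        with pytest.raises(NormalizationError):
            background_threshold(np.ones(19))


class TestSplicingIndexFC:
    def idx(self):
        return ["c1", "c2", "d1", "d2"]

    def test_no_change_reports_unit_up(self):
        exon = pd.Series([100, 100, 100, 100], index=self.idx())
        const = pd.Series([400, 400, 400, 400], index=self.idx())
        f = pd.Series(1.0, index=self.idx())
        mag, reg, signed = splicing_index_fc(exon, const, f, design_2v2())
        assert (mag, reg, signed) == (1.0, "up", 1.0)

    def test_halved_case_counts_give_twofold_down(self):
        exon = pd.Series([1000, 1000, 500, 500], index=self.idx())
        const = pd.Series([4000, 4000, 4000, 4000], index=self.idx())
        f = pd.Series(1.0, index=self.idx())
        mag, reg, signed = splicing_index_fc(exon, const, f, design_2v2())
        assert reg == "down"
        assert signed == -mag
        assert mag == pytest.approx(2.0, rel=0.01)  # pseudocount nearly negligible

    def test_matches_hand_computed_ratio_of_means(self):
        # SI per sample with pseudocount 1 and unit factors:
        # ctr: (10+1)/(40+1), (20+1)/(40+1); cad: (5+1)/(40+1), (10+1)/(40+1)
        exon = pd.Series([10, 20, 5, 10], index=self.idx())
        const = pd.Series([40, 40, 40, 40], index=self.idx())
        f = pd.Series(1.0, index=self.idx())
        si_ctr = (11 / 41 + 21 / 41) / 2
        si_cad = (6 / 41 + 11 / 41) / 2
        ratio = si_cad / si_ctr
        mag, reg, signed = splicing_index_fc(exon, const, f, design_2v2())
        assert reg == "down"
        assert mag == pytest.approx(1 / ratio)
        assert signed == pytest.approx(-1 / ratio)

    def test_scale_invariance_exact_at_zero_pseudocount(self):
        exon = pd.Series([10, 20, 5, 10], index=self.idx())
        const = pd.Series([40, 50, 40, 30], index=self.idx())
        f = pd.Series([1.0, 1.0, 1.0, 1.0], index=self.idx())
        base = splicing_index_fc(exon, const, f, design_2v2(), pseudocount=0)
        # multiply one sample's counts by 7 and absorb it in its size factor
        exon2, const2, f2 = exon.copy(), const.copy(), f.copy()
        exon2["d1"] *= 7
        const2["d1"] *= 7
        f2["d1"] = 7.0
        scaled = splicing_index_fc(exon2, const2, f2, design_2v2(), pseudocount=0)
        assert scaled == pytest.approx(base)

    def test_group_swap_flips_sign(self):
        exon = pd.Series([10, 20, 5, 10], index=self.idx())
        const = pd.Series([40, 40, 40, 40], index=self.idx())
        f = pd.Series(1.0, index=self.idx())
        fwd = splicing_index_fc(exon, const, f, design_2v2())
        swapped_design = SampleDesign(
            {"c1": "CTR", "c2": "CTR", "d1": "CAD", "d2": "CAD"}, reference_group="CAD"
        )
        rev = splicing_index_fc(exon, const, f, swapped_design)
        assert fwd[0] == pytest.approx(rev[0])  # magnitude unchanged
        assert fwd[2] == pytest.approx(-rev[2])  # signed fc inverted

    def test_all_zero_constitutive_rejected_without_pseudocount(self):
        exon = pd.Series([10, 20, 5, 10], index=self.idx())
        const = pd.Series([0, 0, 40, 40], index=self.idx())
        f = pd.Series(1.0, index=self.idx())
        with pytest.raises(NormalizationError):
            splicing_index_fc(exon, const, f, design_2v2(), pseudocount=0)


class TestWelchOnLogSI:
    def test_identical_groups_p_one(self):
        si = pd.Series([2.0, 2.0, 2.0, 2.0], index=["c1", "c2", "d1", "d2"])
        assert welch_log_si_test(si, design_2v2()) == 1.0

    def test_separated_groups_significant(self):
        d = SampleDesign(
            {f"c{i}": "CTR" for i in range(3)} | {f"d{i}": "CAD" for i in range(3)},
            reference_group="CTR",
        )
        si = pd.Series([1.0, 1.1, 0.9, 8.0, 8.5, 7.5],
                       index=[f"c{i}" for i in range(3)] + [f"d{i}" for i in range(3)])
        assert welch_log_si_test(si, d) < 0.05

    def test_matches_textbook_welch_computation(self):
        # log2 SI: case [2, 3], reference [0, 1]; t = 2/sqrt(0.5) = 2.8284,
        # Welch df = 2, two-sided p = 1 - sqrt(0.8) = 0.1055728...
        si = pd.Series([1.0, 2.0, 4.0, 8.0], index=["c1", "c2", "d1", "d2"])
        assert welch_log_si_test(si, design_2v2()) == pytest.approx(1 - np.sqrt(0.8), abs=1e-10)


class TestFilterSignificant:
    def test_published_rows_all_pass_at_two(self):
        results = published_top_events_as_results()
        assert len(filter_significant(results, min_fc=2.0, max_p=0.05)) == 10

    def test_threshold_three_keeps_top_two_genes(self):
        results = published_top_events_as_results()
        kept = filter_significant(results, min_fc=3.0, max_p=0.05)
        assert [r.gene_id for r in kept] == ["CFAP44", "PLCB2"]

    def test_empty_input(self):
        assert filter_significant([]) == []

    def test_monotone_in_threshold(self):
        results = published_top_events_as_results()
        loose = filter_significant(results, 1.5, 0.05)
        strict = filter_significant(results, 2.5, 0.05)
        assert set(id(r) for r in strict) <= set(id(r) for r in loose)

    def test_min_fc_below_one_rejected(self):
        with pytest.raises(ValueError):
            filter_significant([], min_fc=0.5)
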
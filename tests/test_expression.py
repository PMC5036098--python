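"""TPM normalization, fold-change classification, Fisher gate, Venn logic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from cdmir.expression import (Category, build_expression_records,
                              category_counts, classify, cross_genotype,
                              significance, tpm)


class TestTpm:
    def test_zero_count_is_zero(self):
        assert tpm(0, 1_000_000) == 0.0

    def test_formula(self):
        assert tpm(5, 1_000_000) == 5.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            tpm(1, 0)

    def test_conservation_sums_to_one_million(self, small_run):
        manifest, result, _o = small_run
        for lib in manifest["libraries"]:
            total_counts = result.summaries[lib["id"]].clean_reads
            s = sum(tpm(t.counts.get(lib["id"], 0), total_counts)
                    for t in result.tags)
            assert s == pytest.approx(1e6, abs=1e-6)


class TestClassify:
    def test_published_down_regulated_row(self):
        # Yunyan 2 TPMs for one miR166 paralog: 51466.5 -> 6467.4
        log2n, cat = classify(51466.5, 6467.4)
        assert cat is Category.DOWN
        assert float(format(log2n, ".1f")) == -3.0

    def test_expressed_only_in_control(self):
        log2n, cat = classify(1.5, 0.0)
        assert (log2n, cat) == (None, Category.ONLY_CONTROL)

    def test_equal_nonzero_tpm_is_unchanged(self):
        log2n, cat = classify(7.0, 7.0)
        assert log2n == 0.0 and cat is Category.UNCHANGED

    def test_boundary_goes_to_up_down(self):
        assert classify(100.0, 100.0 * 2 ** 1.5)[1] is Category.UP
        assert classify(100.0, 100.0 * 2 ** -1.5)[1] is Category.DOWN

    def test_both_zero_absent_and_only_treated(self):
        assert classify(0.0, 0.0)[1] is Category.ABSENT
        assert classify(0.0, 3.2)[1] is Category.ONLY_TREATED

    def test_negative_tpm_errors(self):
        with pytest.raises(ValueError):
            classify(-1.0, 2.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(0, 1e5, allow_nan=False),
           st.floats(0, 1e5, allow_nan=False))
    def test_antisymmetry_under_condition_swap(self, a, b):
        swap = {Category.UP: Category.DOWN, Category.DOWN: Category.UP,
                Category.ONLY_TREATED: Category.ONLY_CONTROL,
                Category.ONLY_CONTROL: Category.ONLY_TREATED,
                Category.UNCHANGED: Category.UNCHANGED,
                Category.ABSENT: Category.ABSENT}
        _l1, c1 = classify(a, b)
        _l2, c2 = classify(b, a)
        assert c2 is swap[c1]


class TestSignificance:
    def test_identical_proportions_p_one(self):
        assert significance(10, 10, 1000, 1000) == pytest.approx(1.0)

    def test_extreme_table_is_essentially_zero(self):
        assert significance(0, 1000, 10 ** 6, 10 ** 6) < 1e-100

    def test_counts_above_totals_error(self):
        with pytest.raises(ValueError):
            significance(11, 1, 10, 1000)

    def test_matches_direct_hypergeometric_summation(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            n1, n2 = int(rng.integers(5, 40)), int(rng.integers(5, 40))
            k1 = int(rng.integers(0, n1 + 1))
            k2 = int(rng.integers(0, n2 + 1))
            p = significance(k1, k2, n1, n2)
            # two-sided Fisher: sum pmf of all tables at most as probable
            K = k1 + k2
            pmf_obs = hypergeom.pmf(k1, n1 + n2, K, n1)
            total = sum(
                hypergeom.pmf(x, n1 + n2, K, n1)
                for x in range(max(0, K - n2), min(K, n1) + 1)
                if hypergeom.pmf(x, n1 + n2, K, n1) <= pmf_obs * (1 + 1e-9))
            assert p == pytest.approx(total, rel=1e-7, abs=1e-12)


class TestBuildRecords:
    TOTALS = {"G-ctl": 10_000, "G-cd": 10_000, "Y-ctl": 10_000, "Y-cd": 10_000}
    PAIRS = {"G": ("G-ctl", "G-cd"), "Y": ("Y-ctl", "Y-cd")}

    def test_tpm_and_categories(self):
        counts = {"m1": {"G-ctl": 100, "G-cd": 400, "Y-ctl": 100, "Y-cd": 90}}
        (rec,) = build_expression_records(counts, self.TOTALS, self.PAIRS)
        assert rec.tpm["G-ctl"] == pytest.approx(10_000.0)
        assert rec.category["G"] is Category.UP
        assert rec.category["Y"] is Category.UNCHANGED

    def test_p_gate_demotes_insignificant_calls(self):
        counts = {"m1": {"G-ctl": 3, "G-cd": 9, "Y-ctl": 0, "Y-cd": 0}}
        (gated,) = build_expression_records(
            counts, self.TOTALS, self.PAIRS, p_gate=True)
        (ungated,) = build_expression_records(
            counts, self.TOTALS, self.PAIRS, p_gate=False)
        assert ungated.category["G"] is Category.UP
        assert gated.category["G"] is Category.UNCHANGED  # p ~ 0.15 >= 0.01
        assert gated.category["Y"] is Category.ABSENT


class TestCrossGenotype:
    def _records(self, design):
        counts, totals = {}, {"G-ctl": 10000, "G-cd": 10000,
                              "Y-ctl": 10000, "Y-cd": 10000}
        factor = {Category.UP: (50, 500), Category.DOWN: (500, 50),
                  Category.UNCHANGED: (100, 100),
                  Category.ONLY_TREATED: (0, 100),
                  Category.ONLY_CONTROL: (100, 0),
                  Category.ABSENT: (0, 0)}
        for i, (cg, cy) in enumerate(design):
            counts[f"m{i}"] = {
                "G-ctl": factor[cg][0], "G-cd": factor[cg][1],
                "Y-ctl": factor[cy][0], "Y-cd": factor[cy][1]}
        return build_expression_records(
            counts, totals, {"G": ("G-ctl", "G-cd"), "Y": ("Y-ctl", "Y-cd")})

    def test_up_in_one_genotype_is_tolerance_associated_under_both_rules(self):
        recs = self._records([(Category.UP, Category.UNCHANGED)])
        cross = cross_genotype(recs, "G", "Y")
        assert cross.strict_differential == ["m0"]
        assert cross.paper_union == ["m0"]

    def test_unchanged_in_both_excluded_under_both_rules(self):
        recs = self._records([(Category.UNCHANGED, Category.UNCHANGED)])
        cross = cross_genotype(recs, "G", "Y")
        assert cross.strict_differential == []
        assert cross.paper_union == []

    def test_changed_in_both_only_in_paper_union(self):
        recs = self._records([(Category.DOWN, Category.DOWN)])
        cross = cross_genotype(recs, "G", "Y")
        assert cross.strict_differential == []
        assert cross.paper_union == ["m0"]

    def test_planted_pair_table_recovered_exactly(self):
        design = [(Category.UP, Category.UNCHANGED)] * 3 \
            + [(Category.DOWN, Category.DOWN)] * 2 \
            + [(Category.ONLY_CONTROL, Category.ONLY_TREATED)] \
            + [(Category.UNCHANGED, Category.UNCHANGED)] * 4
        recs = self._records(design)
        cross = cross_genotype(recs, "G", "Y")
        assert cross.pair_table == {
            (Category.UP, Category.UNCHANGED): 3,
            (Category.DOWN, Category.DOWN): 2,
            (Category.ONLY_CONTROL, Category.ONLY_TREATED): 1,
            (Category.UNCHANGED, Category.UNCHANGED): 4}
        assert cross.venn[Category.DOWN]["shared"] == 2
        assert cross.venn[Category.UP]["only_G"] == 3

    def test_category_counts_sum_to_universe(self, small_run):
        _manifest, result, _o = small_run
        for genotype in ("G", "Y"):
            counts = category_counts(result.records, genotype)
            assert sum(counts.values()) == len(result.records)

    def test_universe_mismatch_errors(self):
        recs = self._records([(Category.UP, Category.UNCHANGED)])
        del recs[0].category["Y"]
        with pytest.raises(ValueError):
            cross_genotype(recs, "G", "Y")
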
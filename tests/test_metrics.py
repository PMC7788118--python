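"""Accuracy/repeatability metrics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from petseg import (BinaryMask, SegmentationResult, apply_discard_rule,
                    barycenter_distance, compare_methods, icc_agreement,
                    jaccard, repeatability_coefficient, trt_percent,
                    volume_ratio)
from petseg.errors import AlignmentError, InputError

from conftest import random_mask


def _mask(arr, spacing=(4, 4, 4)):
    return BinaryMask(np.asarray(arr, dtype=bool), spacing)


def _set_jaccard(a, b):
    """Brute-force oracle: Jaccard via python sets of voxel coordinates."""
    sa = {tuple(i) for i in np.argwhere(a.values)}
    sb = {tuple(i) for i in np.argwhere(b.values)}
    if not sa | sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


class TestJaccard:
    def test_identity_disjoint_and_fraction(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        b = np.zeros((4, 4, 4), bool)
        b[1:3] = True
        assert jaccard(_mask(a), _mask(a)) == 1.0
        assert jaccard(_mask(a), _mask(~a)) == 0.0
        # |A|=32, |B|=32, overlap 16 -> 16/48
        assert jaccard(_mask(a), _mask(b)) == pytest.approx(1 / 3)

    def test_matches_set_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = random_mask(rng, (5, 5, 5), rng.uniform(0, 1))
            b = random_mask(rng, (5, 5, 5), rng.uniform(0, 1))
            assert jaccard(a, b) == pytest.approx(_set_jaccard(a, b), abs=1e-12)

    def test_both_empty_is_agreement(self):
        e = _mask(np.zeros((3, 3, 3)))
        assert jaccard(e, e) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(AlignmentError):
            jaccard(_mask(np.zeros((3, 3, 3))), _mask(np.zeros((3, 3, 4))))


class TestVolumeRatio:
    def test_examples(self):
        big = _mask(np.ones((5, 5, 8)))        # 200 voxels = 12.8 ml
        half = np.zeros((5, 5, 8), bool)
        half[:, :, :4] = True                  # 100 voxels = 6.4 ml
        seg = SegmentationResult(_mask(half), "t")
        ref = SegmentationResult(big, "ref")
        assert volume_ratio(seg, ref) == pytest.approx(0.5)
        assert volume_ratio(ref, ref) == 1.0

    def test_zero_reference_flagged(self):
        empty = SegmentationResult(_mask(np.zeros((2, 2, 2))), "ref")
        seg = SegmentationResult(_mask(np.ones((2, 2, 2))), "t")
        with pytest.raises(InputError):
            volume_ratio(seg, empty)


class TestBarycenter:
    def test_single_voxel_offset(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[2, 2, 2] = True
        b[2, 2, 3] = True  # one index along x at 4 mm
        assert barycenter_distance(_mask(a), _mask(b)) == pytest.approx(4.0)
        assert barycenter_distance(_mask(a), _mask(a)) == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        a = np.zeros((8, 8, 8), bool)
        a[2:4, 2:5, 3:5] = True
        b = np.zeros((8, 8, 8), bool)
        b[3:5, 1:4, 2:4] = True
        d0 = barycenter_distance(_mask(a), _mask(b))
        d1 = barycenter_distance(_mask(np.roll(a, 2, 0)), _mask(np.roll(b, 2, 0)))
        assert d0 == pytest.approx(d1, abs=1e-9)

    def test_empty_mask_flagged(self):
        with pytest.raises(InputError):
            barycenter_distance(_mask(np.zeros((3, 3, 3))),
                                _mask(np.ones((3, 3, 3))))


class TestTrtAndRc:
    def test_printed_formula_values(self):
        assert trt_percent(10, 10) == 0.0
        assert trt_percent(10, 20) == pytest.approx(66.666667, abs=1e-4)
        assert trt_percent(20, 10) == trt_percent(10, 20)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.1, 10))
    def test_scale_invariance(self, v1, v2, c):
        assert trt_percent(c * v1, c * v2) == pytest.approx(trt_percent(v1, v2),
                                                            rel=1e-9)

    def test_rc_from_sd(self):
        # a two-value list with sample SD exactly 16 -> RC 31.36
        vals = [0.0, 16.0 * np.sqrt(2.0)]
        assert np.std(vals, ddof=1) == pytest.approx(16.0)
        assert repeatability_coefficient(vals) == pytest.approx(31.36)
        assert repeatability_coefficient([5.0, 5.0, 5.0]) == 0.0

    def test_both_zero_undefined(self):
        with pytest.raises(InputError):
            trt_percent(0.0, 0.0)


def _icc_anova_oracle(day1, day2):
    """Hand-computed two-way ANOVA -> ICC(A,1), written out longhand."""
    y = np.column_stack([day1, day2]).astype(float)
    n, k = y.shape
    grand = y.mean()
    ss_rows = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestIcc:
    def test_hand_anova_table(self):
        day1 = [10.0, 14.0, 18.0, 22.0]
        day2 = [11.0, 13.0, 19.0, 21.0]
        assert icc_agreement(day1, day2) == pytest.approx(
            _icc_anova_oracle(day1, day2), abs=1e-10)

    def test_perfect_agreement(self):
        assert icc_agreement([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_common_offset_invariance(self):
        rng = np.random.default_rng(2)
        d1 = rng.uniform(5, 20, 10)
        d2 = d1 + rng.normal(0, 1, 10)
        assert icc_agreement(d1 + 7, d2 + 7) == pytest.approx(
            icc_agreement(d1, d2), abs=1e-9)

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(3)
        icc = icc_agreement(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
        assert abs(icc) < 0.15

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        d1 = rng.uniform(5, 30, 12)
        d2 = d1 * rng.normal(1.0, 0.1, 12)
        table = pd.DataFrame({
            "subject": list(range(12)) * 2,
            "rater": ["a"] * 12 + ["b"] * 12,
            "score": np.concatenate([d1, d2]),
        })
        ref = pingouin.intraclass_corr(table, targets="subject", raters="rater",
                                       ratings="score")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])  # label varies by version
        icc2 = ref.loc[mask, "ICC"].iloc[0]
        assert icc_agreement(d1, d2) == pytest.approx(icc2, abs=1e-6)


def _friedman_oracle(values):
    """Friedman chi-square from mean ranks (no ties in the toy table)."""
    from scipy.stats import rankdata
    n, k = values.shape
    ranks = np.apply_along_axis(rankdata, 1, values)
    rbar = ranks.mean(axis=0)
    return 12 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2) ** 2)


class TestCompareMethods:
    def test_friedman_matches_rank_oracle(self):
        table = pd.DataFrame({"a": [1, 5, 9, 2], "b": [3, 4, 8, 6],
                              "c": [2, 7, 10, 11]}, dtype=float)
        cmp_ = compare_methods(table)
        assert cmp_.friedman_statistic == pytest.approx(
            _friedman_oracle(table.to_numpy()), abs=1e-9)
        assert 0 <= cmp_.friedman_p <= 1

    def test_benjamini_hochberg_stepup_by_hand(self):
        # alpha 0.01, m = 5: thresholds 0.002, 0.004, 0.006, 0.008, 0.01;
        # step-up over (0.001, 0.002, 0.008, 0.04, 0.2) flags the first two
        from statsmodels.stats.multitest import multipletests
        reject, *_ = multipletests([0.001, 0.002, 0.008, 0.04, 0.2],
                                   alpha=0.01, method="fdr_bh")
        assert list(reject) == [True, True, False, False, False]

    def test_flags_are_prefix_of_sorted_pvalues(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.uniform(0, 50, (12, 4)),
                             columns=list("abcd"))
        cmp_ = compare_methods(table, alpha=0.2)
        iu = np.triu_indices(4, 1)
        p = cmp_.nemenyi_p.to_numpy()[iu]
        flags = cmp_.significant.to_numpy()[iu]
        order = np.argsort(p)
        sorted_flags = flags[order]
        # once a p-value is not rejected, no larger p-value is rejected
        assert all(sorted_flags[i] or not sorted_flags[i + 1]
                   for i in range(len(sorted_flags) - 1))

    def test_exact_nemenyi_on_tiny_table(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0],
                              "c": [5.0, 6.0, 7.0]})
        approx = compare_methods(table)
        exact = compare_methods(table, exact_nemenyi=True)
        pa = approx.nemenyi_p.loc["a", "c"]
        pe = exact.nemenyi_p.loc["a", "c"]
        assert 0 <= pe <= 1 and 0 <= pa <= 1
        # the most-separated pair has the smallest p under both schemes
        assert exact.nemenyi_p.loc["a", "c"] <= exact.nemenyi_p.loc["a", "b"]

    def test_missing_cells_rejected(self):
        table = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1, 2, 3.0]})
        with pytest.raises(InputError):
            compare_methods(table)


class TestDiscardRule:
    def _table(self):
        return pd.DataFrame({
            "lesion_id": ["l1", "l1", "l2", "l2", "l3", "l3"],
            "method": ["suv4", "tf"] * 3,
            "day1_ml": [5.0, 6.0, 3.0, 3.5, 0.0, 4.0],
            "day2_ml": [5.5, 6.5, 3.2, 3.4, 2.0, 4.2],
        })

    def test_missed_lesion_removed_from_all_methods(self):
        kept, discarded = apply_discard_rule(self._table())
        assert discarded == ["l3"]
        assert set(kept["lesion_id"]) == {"l1", "l2"}
        assert len(kept) == 4  # 2 lesions x 2 methods

    def test_no_misses_is_identity(self):
        t = self._table()[lambda d: d["lesion_id"] != "l3"]
        kept, discarded = apply_discard_rule(t.reset_index(drop=True))
        assert discarded == []
        assert len(kept) == len(t)

    def test_all_lesions_missed(self):
        t = self._table()
        t.loc[:, "day1_ml"] = 0.0
        kept, discarded = apply_discard_rule(t)
        assert kept.empty and len(discarded) == 3
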
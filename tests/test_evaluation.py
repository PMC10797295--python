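"""Agreement metrics and error statistics against hand-computed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pkseg.evaluation import (bland_altman, compare_models, dice, error_stats,
                              evaluate_cases, pearson, summarize_eval,
                              volume_difference)
from pkseg.volume_io import DataError, LabelMap


class TestDice:
    def test_identical_masks_score_one(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[2:6, 2:6, 2:6] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[:2], b[6:] = True, True
        assert dice(a, b) == 0.0

    def test_voxel_count_example(self):
        # |G|=4, |S|=6, overlap 3 -> 2*3/(4+6) = 0.6
        g = np.zeros((4, 4, 4), dtype=bool)
        s = np.zeros((4, 4, 4), dtype=bool)
        g.reshape(-1)[:4] = True
        s.reshape(-1)[1:7] = True
        assert dice(s, g) == pytest.approx(0.6)

    def test_both_empty_is_perfect_agreement(self):
        e = np.zeros((4, 4, 4), dtype=bool)
        assert dice(e, e) == 1.0

    def test_shape_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(DataError, match="mismatch"):
            dice(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))
        with pytest.raises(DataError, match="binary"):
            dice(np.full((2, 2, 2), 3), np.zeros((2, 2, 2), bool))


class TestVolumeDifference:
    def test_equal_volumes_score_zero(self):
        g = np.zeros((4, 4, 4), bool)
        s = np.zeros((4, 4, 4), bool)
        g.reshape(-1)[:5] = True
        s.reshape(-1)[10:15] = True
        assert volume_difference(s, g) == 0.0

    def test_fifty_percent_oversegmentation(self):
        g = np.zeros((4, 4, 4), bool)
        s = np.zeros((4, 4, 4), bool)
        g.reshape(-1)[:4] = True
        s.reshape(-1)[:6] = True
        assert volume_difference(s, g) == pytest.approx(0.5)

    def test_empty_reference_rejected(self):
        s = np.ones((2, 2, 2), bool)
        with pytest.raises(DataError, match="empty"):
            volume_difference(s, np.zeros((2, 2, 2), bool))

    def test_asymmetry(self):
        g = np.zeros((4, 4, 4), bool)
        s = np.zeros((4, 4, 4), bool)
        g.reshape(-1)[:4] = True
        s.reshape(-1)[:8] = True
        assert volume_difference(s, g) != volume_difference(g, s)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_dice_and_vd_match_exhaustive_count_oracle(seed):
    rng = np.random.default_rng(seed)
    s = rng.random((8, 8, 8)) > 0.6
    g = rng.random((8, 8, 8)) > 0.6
    inter = sum(bool(s[i, j, k]) and bool(g[i, j, k])
                for i in range(8) for j in range(8) for k in range(8))
    ns, ng = int(s.sum()), int(g.sum())
    expected = 1.0 if ns + ng == 0 else 2 * inter / (ns + ng)
    assert dice(s, g) == expected
    assert dice(s, g) == dice(g, s)  # symmetry
    if ng:
        assert volume_difference(s, g) == abs(ns - ng) / ng


class TestErrorStats:
    def test_identity_gives_all_zero(self):
        es = error_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (es.mae, es.rmse, es.mare, es.rmsre, es.u95) == (0,) * 5

    def test_hand_computed_values(self):
        es = error_stats([1.0, 2.0], [1.1, 1.8])
        assert es.mae == pytest.approx(0.15)
        assert es.mare == pytest.approx(0.10)
        assert es.rmse == pytest.approx(np.sqrt(0.025))

    def test_singleton_series(self):
        es = error_stats([2.0], [3.0])
        assert es.mae == 1.0 and es.mare == 0.5 and es.n == 1

    def test_zero_reference_entries_skipped_and_counted(self):
        es = error_stats([0.0, 2.0], [1.0, 2.2])
        assert es.n_skipped_relative == 1
        assert es.mare == pytest.approx(0.1)
        assert es.mae == pytest.approx(0.6)  # absolute metrics keep all rows

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 100.0), st.integers(0, 2 ** 16))
    def test_scale_law(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 10, 8)
        y = x + rng.normal(0, 1, 8)
        a, b = error_stats(x, y), error_stats(c * x, c * y)
        assert b.mae == pytest.approx(c * a.mae, rel=1e-9)
        assert b.rmse == pytest.approx(c * a.rmse, rel=1e-9)
        assert b.mare == pytest.approx(a.mare, rel=1e-9)
        assert b.rmsre == pytest.approx(a.rmsre, rel=1e-9)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert pearson(3 * x + 2, 0.5 * y - 7) == pytest.approx(
            pearson(x, y), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identity_collapses_limits(self):
        table, bias, lo, hi = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert bias == lo == hi == 0.0
        assert (table["difference"] == 0).all()

    def test_hand_computed_rows(self):
        table, bias, lo, hi = bland_altman([0.0, 2.0], [1.0, 3.0])
        assert list(table["difference"]) == [1.0, 1.0]
        assert list(table["mean"]) == [0.5, 2.5]
        assert bias == 1.0
        assert len(table) == 2


class TestCompareModels:
    def test_identical_samples_are_null(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.9, 0.02, 20)
        cmp = compare_models(a, a.copy(), n_comparisons=5)
        assert cmp.p_one_sided == pytest.approx(0.5)
        assert not cmp.significant

    def test_clear_separation_survives_bonferroni(self):
        rng = np.random.default_rng(1)
        parent = 0.95 + rng.normal(0, 0.005, 20)
        subset = 0.80 + rng.normal(0, 0.005, 20)
        cmp = compare_models(parent, subset, n_comparisons=20)
        assert cmp.significant_adjusted
        assert cmp.adjusted_alpha == pytest.approx(0.05 / 20)

    def test_single_comparison_threshold_equals_alpha(self):
        rng = np.random.default_rng(2)
        cmp = compare_models(rng.normal(0.9, 0.01, 10),
                             rng.normal(0.9, 0.01, 10), n_comparisons=1)
        assert cmp.adjusted_alpha == cmp.alpha

    def test_paired_variant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.9, 0.05, 15)
        shift = rng.normal(0.02, 0.005, 15)
        cmp = compare_models(a, a - shift, n_comparisons=1, paired=True)
        assert cmp.significant


def test_evaluate_cases_long_format():
    shape = (6, 6, 6)
    ref = np.zeros(shape, np.int16)
    ref[1:4, 1:4, 1:4] = 1
    ref[4:6, 4:6, 4:6] = 3
    pred = ref.copy()
    pred[1, 1, 1] = 0
    ident = np.diag([1.0, 1.0, 1.0, 1.0])
    table = evaluate_cases([LabelMap(pred, (1, 1, 1), ident)],
                           [LabelMap(ref, (1, 1, 1), ident)], ["c0"])
    assert set(table["organ"]) == {"heart", "lungs", "liver", "spleen",
                                   "kidneys", "tumor"}
    heart = table[table["organ"] == "heart"].iloc[0]
    assert heart["dsc"] == pytest.approx(2 * 26 / (26 + 27))
    absent = table[table["organ"] == "spleen"].iloc[0]
    assert absent["dsc"] == 1.0 and np.isnan(absent["vd"])
    summary = summarize_eval(table)
    assert len(summary) == 6
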
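"""Agreement statistics: closed forms, invariances, and variance components."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from eatseg.ct_io import SegmentationMask, GridMismatchError
from eatseg.metrics import (
    bland_altman,
    bsa_index,
    dice,
    evaluate_pairs,
    icc_absolute,
    pearson,
    relative_volume_error,
)


class TestDice:
    def test_identical_nonempty_masks(self, rng):
        a = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
        assert dice(a, a.copy()) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10), dtype=np.uint8)
        b = np.zeros((10, 10, 10), dtype=np.uint8)
        a.ravel()[:100] = 1
        b.ravel()[50:150] = 1
        assert dice(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_symmetry(self, rng):
        a = (rng.random((6, 6, 6)) > 0.3).astype(np.uint8)
        b = (rng.random((6, 6, 6)) > 0.7).astype(np.uint8)
        assert dice(a, b) == dice(b, a)

    def test_both_empty_is_perfect_agreement(self):
        z = np.zeros((3, 3, 3), dtype=np.uint8)
        assert dice(z, z) == 1.0

    def test_grid_mismatch(self):
        a = SegmentationMask(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))
        b = SegmentationMask(np.zeros((4, 4, 4), dtype=np.uint8), (2, 2, 2))
        with pytest.raises(GridMismatchError):
            dice(a, b)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        a=hnp.arrays(np.uint8, (3, 3, 3), elements=st.integers(0, 1)),
        b=hnp.arrays(np.uint8, (3, 3, 3), elements=st.integers(0, 1)),
    )
    def test_symmetric_bounded_and_maximal_on_self(self, a, b):
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)
        assert dice(a, a) == 1.0


class TestRelativeVolumeError:
    @pytest.mark.parametrize(
        "pred,ref,expected",
        [(95.0, 100.0, 5.0), (100.0, 100.0, 0.0), (110.0, 100.0, 10.0),
         (90.0, 100.0, 10.0)],
    )
    def test_closed_form(self, pred, ref, expected):
        assert relative_volume_error(pred, ref) == pytest.approx(expected, abs=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_volume_error(10.0, 0.0)


class TestBlandAltman:
    def test_constant_shift(self):
        x = np.array([1.0, 5.0, 9.0, 13.0])
        bias, lo, hi = bland_altman(x, x + 2.0)
        assert bias == pytest.approx(-2.0, abs=1e-12)
        assert lo == pytest.approx(-2.0, abs=1e-12)
        assert hi == pytest.approx(-2.0, abs=1e-12)

    def test_two_point_closed_form(self):
        # differences {−1, +1}: bias 0, sample sd = √2, limits = ∓1.96·√2
        bias, lo, hi = bland_altman([0.0, 1.0], [1.0, 0.0])
        assert bias == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(-1.96 * np.sqrt(2.0), abs=1e-10)
        assert hi == pytest.approx(+1.96 * np.sqrt(2.0), abs=1e-10)

    def test_identical_arrays(self):
        x = np.array([3.0, 4.0, 5.0])
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_limits_bracket_bias_with_correct_width(self, rng):
        x = rng.normal(100, 30, size=50)
        y = x + rng.normal(-3, 8, size=50)
        bias, lo, hi = bland_altman(x, y)
        assert lo <= bias <= hi
        d = x - y
        assert hi - lo == pytest.approx(2 * 1.96 * d.std(ddof=1), rel=1e-12)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestPearson:
    def test_perfect_positive_affine(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([3.0, 1.0, 7.0, 2.0, 9.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r0 = pearson(x, y)
        assert pearson(3.5 * x + 11, y) == pytest.approx(r0, abs=1e-12)
        assert pearson(x, 0.1 * y - 4) == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        icc, lo, hi = icc_absolute(x, x)
        assert icc == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(123)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        icc, _, _ = icc_absolute(x, y)
        assert abs(icc) < 0.15

    def test_variance_components_recovery(self):
        """ICC(2,1) ≈ σ_subject² / (σ_subject² + σ_reader²) for additive noise."""
        rng = np.random.default_rng(7)
        sd_subj, sd_noise = 40.0, 4.0
        target = sd_subj**2 / (sd_subj**2 + sd_noise**2)
        vals = []
        for _ in range(20):
            subj = rng.normal(125, sd_subj, size=100)
            x = subj + rng.normal(0, sd_noise, size=100)
            y = subj + rng.normal(0, sd_noise, size=100)
            vals.append(icc_absolute(x, y)[0])
        assert np.mean(vals) == pytest.approx(target, abs=0.02)

    def test_monotone_decreasing_in_reader_noise(self):
        rng = np.random.default_rng(11)
        subj = rng.normal(100, 30, size=400)
        iccs = []
        for sd in (1.0, 5.0, 15.0):
            x = subj + rng.normal(0, sd, size=400)
            y = subj + rng.normal(0, sd, size=400)
            iccs.append(icc_absolute(x, y)[0])
        assert iccs[0] > iccs[1] > iccs[2]

    def test_matches_pingouin(self):
        """Cross-check against an independent ICC implementation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        subj = rng.normal(120, 40, size=40)
        x = subj + rng.normal(0, 6, size=40)
        y = subj + rng.normal(1.5, 6, size=40)  # reader offset exercises MSC
        icc, lo, hi = icc_absolute(x, y)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(40), 2),
            "rater": np.tile(["a", "b"], 40),
            "score": np.column_stack([x, y]).ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert icc == pytest.approx(row["ICC"], abs=1e-10)
        # pingouin rounds the reported interval to two decimals
        assert lo == pytest.approx(row[ci_col][0], abs=0.01)
        assert hi == pytest.approx(row[ci_col][1], abs=0.01)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(9)
        subj = rng.normal(100, 40, size=60)
        x = subj + rng.normal(0, 5, size=60)
        y = subj + rng.normal(0, 5, size=60)
        icc, lo, hi = icc_absolute(x, y)
        assert lo < icc < hi
        assert 0 < icc < 1

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            icc_absolute([1.0, 2.0], [1.0, 2.0])


class TestBsaIndex:
    @pytest.mark.parametrize("v,bsa,expected", [(140.0, 2.0, 70.0), (0.0, 1.8, 0.0)])
    def test_values(self, v, bsa, expected):
        assert bsa_index(v, bsa) == pytest.approx(expected)

    def test_rounded_example(self):
        assert round(bsa_index(133.0, 1.9)) == 70

    def test_invalid_bsa(self):
        with pytest.raises(ValueError):
            bsa_index(100.0, 0.0)


class TestEvaluatePairs:
    def test_report_fields_consistent(self, rng):
        v_ref = rng.uniform(60, 220, size=30)
        v_pred = v_ref + rng.normal(-3, 8, size=30)
        rep = evaluate_pairs(v_pred, v_ref)
        assert rep.n == 30
        assert rep.loa_low_cm3 <= rep.bias_cm3 <= rep.loa_high_cm3
        assert 0 <= rep.mean_rel_vol_err_pct < 30
        assert -1 <= rep.pearson_r <= 1
        d = rep.to_dict()
        assert d["icc_ci"][0] <= d["icc"] <= d["icc_ci"][1]
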
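import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsesurf.mask_io import LabelMask
from sparsesurf.metrics import (
    band_dice,
    band_icc,
    band_overlap,
    bland_altman,
    cigen,
    classify_agreement,
    compute_agreement,
    dice,
    icc_absolute,
    jaccard,
    pool_hemispheres,
)
from conftest import random_mask_pair


def mask_from_voxels(voxels, shape=(8, 8, 8)):
    data = np.zeros(shape, np.uint8)
    for v in voxels:
        data[v] = 1
    return LabelMask(data)


class TestJaccardDice:
    def test_counted_example(self):
        a = mask_from_voxels([(0, 0, 0), (1, 0, 0)])
        b = mask_from_voxels([(1, 0, 0), (2, 0, 0)])
        assert jaccard(a, b) == pytest.approx(1 / 3)
        assert dice(a, b) == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        a = mask_from_voxels([(0, 0, 0), (1, 1, 1)])
        b = mask_from_voxels([(3, 3, 3)])
        assert jaccard(a, a) == 1.0 and dice(a, a) == 1.0
        assert jaccard(a, b) == 0.0 and dice(a, b) == 0.0

    def test_symmetry_and_dice_jaccard_identity(self, rng):
        for _ in range(25):
            a, b = random_mask_pair(rng)
            ji, ds = jaccard(a, b), dice(a, b)
            assert ji == jaccard(b, a)
            assert ds == pytest.approx(2 * ji / (1 + ji), abs=1e-12)
            assert 0 <= ji <= ds <= 1

    voxel_sets = st.sets(
        st.tuples(*[st.integers(0, 4)] * 3), min_size=0, max_size=30
    )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(va=voxel_sets, vb=voxel_sets)
    def test_set_identities_hold_for_arbitrary_voxel_sets(self, va, vb):
        if not va and not vb:
            return
        a, b = mask_from_voxels(va, (5, 5, 5)), mask_from_voxels(vb, (5, 5, 5))
        ji = jaccard(a, b)
        inter, union = len(va & vb), len(va | vb)
        assert ji == pytest.approx(inter / union)
        assert dice(a, b) == pytest.approx(2 * ji / (1 + ji), abs=1e-12)
        assert cigen([a, b]) == pytest.approx(ji, abs=1e-15)

    def test_both_empty_is_error(self):
        e = LabelMask(np.zeros((4, 4, 4), np.uint8))
        with pytest.raises(ValueError, match="empty"):
            jaccard(e, e)

    def test_grid_mismatch_rejected(self):
        a = mask_from_voxels([(0, 0, 0)])
        b = LabelMask(np.ones((4, 4, 4), np.uint8), spacing=(2, 1, 1))
        with pytest.raises(ValueError, match="grid"):
            jaccard(a, b)


class TestCigen:
    def test_two_raters_reduces_to_jaccard(self, rng):
        for _ in range(10):
            a, b = random_mask_pair(rng)
            assert cigen([a, b]) == pytest.approx(jaccard(a, b), abs=1e-15)

    def test_three_identical_masks(self):
        a = mask_from_voxels([(0, 0, 0), (1, 1, 1)])
        assert cigen([a, a.copy(), a.copy()]) == 1.0

    def test_enumerated_line_example(self):
        """A={1,2,3}, B={2,3,4}, C={3,4,5} -> (2+1+2)/(4+5+4) = 5/13."""
        a = mask_from_voxels([(1, 0, 0), (2, 0, 0), (3, 0, 0)])
        b = mask_from_voxels([(2, 0, 0), (3, 0, 0), (4, 0, 0)])
        c = mask_from_voxels([(3, 0, 0), (4, 0, 0), (5, 0, 0)])
        assert cigen([a, b, c]) == pytest.approx(5 / 13)

    def test_permutation_invariant_and_bounded_by_best_pair(self, rng):
        a, b = random_mask_pair(rng)
        c, _ = random_mask_pair(rng)
        masks = [a, b, c]
        ref = cigen(masks)
        assert cigen([c, a, b]) == ref
        assert cigen([b, c, a]) == ref
        best = max(jaccard(x, y) for i, x in enumerate(masks)
                   for y in masks[i + 1:])
        assert ref <= best + 1e-15


def icc_anova_oracle(x):
    """Brute-force two-way ANOVA ICC(A,1) from explicit cell deviations."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestIccAbsolute:
    def test_perfect_agreement(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert icc_absolute(x) == pytest.approx(1.0)

    def test_rater_offset_lowers_icc(self):
        base = np.array([[10.0, 10.0], [12.0, 12.0], [14.0, 14.0], [16.0, 16.0]])
        shifted = base.copy()
        shifted[:, 1] += 2.0
        assert icc_absolute(shifted) < icc_absolute(base)

    def test_4x2_example_matches_oracle(self):
        x = np.array([[10, 11], [12, 12], [14, 13], [16, 17]], float)
        assert icc_absolute(x) == pytest.approx(icc_anova_oracle(x), abs=1e-12)

    def test_fifty_random_matrices_match_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 8))
            k = int(rng.integers(2, 5))
            x = rng.normal(10, 3, (n, k))
            assert icc_absolute(x) == pytest.approx(icc_anova_oracle(x), abs=1e-10)

    def test_matches_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(3):
            x = rng.normal(5, 2, (6, 3))
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(6), 3),
                    "rater": np.tile(np.arange(3), 6),
                    "y": x.ravel(),
                }
            )
            res = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                           ratings="y")
            icc2 = res.loc[res["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
            assert icc_absolute(x) == pytest.approx(icc2, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="variance"):
            icc_absolute(np.full((3, 3), 2.0))


class TestBlandAltman:
    def test_hand_computed_example(self):
        b = np.array([1.0, 2.0, 3.0])
        a = b + np.array([1.0, 0.0, -1.0])
        ba = bland_altman(a, b)
        assert ba.mu_diff == pytest.approx(0.0)
        assert ba.sd == pytest.approx(1.0)
        assert ba.se == pytest.approx(0.577, abs=1e-3)
        assert ba.p_value == pytest.approx(1.0)
        assert ba.loa_lower == pytest.approx(-1.96)
        assert ba.loa_upper == pytest.approx(1.96)

    def test_identical_series_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(a, a)
        assert ba.mu_diff == 0.0 and ba.sd == 0.0
        assert ba.degenerate and np.isnan(ba.p_value)

    def test_constant_offset(self):
        b = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(b + 0.2, b)
        assert ba.mu_diff == pytest.approx(0.2)
        assert ba.sd == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestBands:
    @pytest.mark.parametrize("value,band", [(0.71, "excellent"), (0.70, "not excellent")])
    def test_overlap_threshold_is_strict(self, value, band):
        assert band_overlap(value) == band

    def test_dice_080_not_excellent(self):
        assert band_dice(0.80) == "not excellent"
        assert band_dice(0.81) == "excellent"

    @pytest.mark.parametrize(
        "value,band",
        [(0.39, "poor"), (0.40, "fair to good"), (0.74, "fair to good"),
         (0.75, "excellent")],
    )
    def test_icc_bands(self, value, band):
        assert band_icc(value) == band

    def test_classify_attaches_bands(self, rng):
        a, b = random_mask_pair(rng)
        report = classify_agreement(compute_agreement([a, b]))
        assert set(report.bands) >= {"ji", "dsc", "cigen"}


class TestPoolHemispheres:
    def test_overlap_averaged_volumes_summed(self):
        df = pd.DataFrame(
            {
                "structure": ["caudate", "caudate"],
                "hemisphere": ["left", "right"],
                "ji": [0.8, 0.9],
                "volume_ml": [2.0, 2.2],
            }
        )
        out = pool_hemispheres(df)
        both = out[out.hemisphere == "both"].iloc[0]
        assert both.ji == pytest.approx(0.85)
        assert both.volume_ml == pytest.approx(4.2)
        assert len(out) == 3  # per-hemisphere rows kept
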
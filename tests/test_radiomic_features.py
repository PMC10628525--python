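import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltarad import ImageVolume, extract_features, feature_local_names
from deltarad.core import RoiMask
from deltarad.firstorder import FO_NAMES, first_order_features
from deltarad.glcm import (
    DIRECTIONS,
    GLCM_SCALAR_NAMES,
    GlcmMatrix,
    glcm_matrix,
    glcm_scalar_features,
    quantize_roi,
    rotation_invariant_aggregate,
)

from .oracles import brute_first_order, brute_glcm, brute_glcm_scalars


class TestQuantize:
    def test_one_value_per_bin(self):
        got = quantize_roi(np.array([0.0, 1.0, 2.0, 3.0]), 4)
        assert sorted(got.tolist()) == [1, 2, 3, 4]

    def test_constant_roi_maps_to_level_one(self):
        assert np.all(quantize_roi(np.full(10, 7.0), 8) == 1)

    def test_histogram_oracle(self, rng):
        x = rng.random(2000)
        levels = quantize_roi(x, 8)
        occupancy = np.bincount(levels, minlength=9)[1:]
        hist, _ = np.histogram(x, bins=8, range=(x.min(), x.max()))
        assert occupancy.tolist() == hist.tolist()

    def test_errors(self):
        with pytest.raises(ValueError):
            quantize_roi(np.array([]), 8)
        with pytest.raises(ValueError):
            quantize_roi(np.array([1.0]), 1)


class TestFirstOrder:
    def test_symmetric_sample(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["Minimum"] == 1 and f["Maximum"] == 4
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_sample(self):
        f = first_order_features(np.full(20, 3.5))
        for name in ("Minimum", "Maximum", "Mean", "Percentile.1", "Percentile.99"):
            assert f[name] == 3.5
        assert f["Standard.Deviation"] == 0.0

    def test_direct_formula_oracle(self, rng):
        x = rng.standard_normal(1000)
        got = first_order_features(x)
        want = brute_first_order(x)
        for name in FO_NAMES:
            assert got[name] == pytest.approx(want[name], rel=1e-10), name

    def test_degenerate_inputs(self):
        empty = first_order_features(np.array([]))
        assert all(math.isnan(v) for v in empty.values())
        single = first_order_features(np.array([2.0]))
        assert single["Mean"] == 2.0
        assert math.isnan(single["Standard.Deviation"])
        assert math.isnan(single["Skewness"])


class TestGlcmMatrix:
    def test_constant_levels_single_entry(self):
        lv = np.ones((4, 4, 4), dtype=np.int64)
        mask = RoiMask(np.ones((4, 4, 4), dtype=bool))
        P = glcm_matrix(lv, mask, (1, 0, 0), 8)
        assert P.P[0, 0] == pytest.approx(1.0)
        assert P.P.sum() == pytest.approx(1.0)

    def test_toy_slice_enumeration_oracle(self):
        slab = np.array([[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]])
        lv = slab[:, :, None].astype(np.int64)
        mask = RoiMask(np.ones_like(lv, dtype=bool))
        offset = (0, 1, 0)
        got = glcm_matrix(lv, mask, offset, 4)
        want, total = brute_glcm(lv, mask.data, offset, 4)
        assert total > 0
        np.testing.assert_allclose(got.P, want, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), d=st.integers(0, 12))
    def test_symmetry_and_normalization_property(self, seed, d):
        r = np.random.default_rng(seed)
        lv = r.integers(1, 5, size=(5, 5, 5))
        mask = RoiMask(r.random((5, 5, 5)) < 0.6)
        P = glcm_matrix(lv, mask, DIRECTIONS[d], 4)
        if not P.empty:
            np.testing.assert_allclose(P.P, P.P.T, atol=0)
            assert P.P.sum() == pytest.approx(1.0)

    def test_no_valid_pairs_flagged_empty(self):
        lv = np.ones((3, 3, 3), dtype=np.int64)
        m = np.zeros((3, 3, 3), dtype=bool)
        m[0, 0, 0] = True  # isolated voxel: no in-mask pair at any offset
        P = glcm_matrix(lv, RoiMask(m), (1, 0, 0), 4)
        assert P.empty
        assert all(math.isnan(v) for v in glcm_scalar_features(P).values())

    def test_non_canonical_offset_rejected(self):
        lv = np.ones((3, 3, 3), dtype=np.int64)
        with pytest.raises(ValueError):
            glcm_matrix(lv, RoiMask(np.ones((3, 3, 3), dtype=bool)), (2, 0, 0), 4)


class TestGlcmScalars:
    def test_degenerate_single_entry(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        f = glcm_scalar_features(GlcmMatrix(P, 4, (1, 0, 0)))
        assert f["Energy"] == pytest.approx(1.0)
        assert f["Entropy"] == pytest.approx(0.0)
        assert f["Contrast"] == pytest.approx(0.0)
        assert f["MaximumProbability"] == pytest.approx(1.0)
        assert f["Dissimilarity"] == pytest.approx(0.0)
        assert math.isnan(f["Correlation"])  # zero marginal SD

    def test_uniform_two_by_two_hand_values(self):
        P = np.full((2, 2), 0.25)
        f = glcm_scalar_features(GlcmMatrix(P, 2, (1, 0, 0)))
        assert f["Energy"] == pytest.approx(0.25)
        assert f["Entropy"] == pytest.approx(2.0)  # log2(4)
        assert f["Contrast"] == pytest.approx(0.5)

    def test_direct_sum_oracle_random(self, rng):
        for _ in range(5):
            raw = rng.random((6, 6))
            P = raw + raw.T
            P /= P.sum()
            f = glcm_scalar_features(GlcmMatrix(P, 6, (1, 0, 0)))
            assert f["Energy"] == pytest.approx(float((P**2).sum()), rel=1e-12)
            i = np.arange(1, 7)
            contrast = sum(
                (a - b) ** 2 * P[a - 1, b - 1] for a in i for b in i
            )
            assert f["Contrast"] == pytest.approx(contrast, rel=1e-12)

    def test_full_brute_force_oracle(self, rng):
        raw = rng.random((5, 5))
        P = raw + raw.T
        P /= P.sum()
        got = glcm_scalar_features(GlcmMatrix(P, 5, (1, 0, 0)))
        want = brute_glcm_scalars(P)
        for name in GLCM_SCALAR_NAMES:
            assert got[name] == pytest.approx(want[name], rel=1e-10), name

    def test_invariant_ranges(self, rng):
        raw = rng.random((8, 8))
        P = raw + raw.T
        P /= P.sum()
        f = glcm_scalar_features(GlcmMatrix(P, 8, (1, 0, 0)))
        assert 0 < f["Energy"] <= 1
        assert f["Entropy"] >= 0
        assert 0 < f["MaximumProbability"] <= 1
        assert -1 <= f["Correlation"] <= 1


class TestAggregation:
    def test_identical_directions(self):
        assert rotation_invariant_aggregate([3.0] * 13) == (3.0, 0.0, 0.0)

    def test_split_values(self):
        mean, rng_, _ = rotation_invariant_aggregate([0.0] * 12 + [1.0])
        assert mean == pytest.approx(1 / 13)
        assert rng_ == 1.0

    def test_direct_formula_oracle(self, rng):
        v = rng.standard_normal(13)
        mean, rng_, var = rotation_invariant_aggregate(v)
        assert mean == pytest.approx(v.mean())
        assert rng_ == pytest.approx(v.max() - v.min())
        assert var == pytest.approx(v.var(ddof=0))

    def test_missing_directions_excluded(self):
        v = [math.nan] * 10 + [1.0, 2.0, 3.0]
        mean, rng_, var = rotation_invariant_aggregate(v)
        assert mean == pytest.approx(2.0)
        assert rng_ == pytest.approx(2.0)
        assert var == pytest.approx(2.0 / 3.0)
        assert all(math.isnan(x) for x in rotation_invariant_aggregate([math.nan] * 13))


def _random_volume_and_mask(rng, n=12):
    from scipy import ndimage

    data = ndimage.gaussian_filter(rng.standard_normal((n, n, n)), 1.0)
    z, y, x = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    mask = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= (n / 3) ** 2
    return ImageVolume(data, (1, 1, 1)), RoiMask(mask)


class TestExtractFeatures:
    def test_feature_counts(self, rng):
        vol, mask = _random_volume_and_mask(rng)
        fv = extract_features(vol, mask)
        names = list(fv.values)
        assert len(names) == 310
        assert sum(n.startswith("FO_") for n in names) == 10
        assert sum(n.startswith("GLCM_") for n in names) == 300
        assert sum("_N32_" in n for n in names) == 60

    def test_rotation_invariance(self, rng):
        vol, mask = _random_volume_and_mask(rng)
        fv = extract_features(vol, mask)
        rot_vol = ImageVolume(np.rot90(vol.data, axes=(0, 1)).copy(), (1, 1, 1))
        rot_mask = RoiMask(np.rot90(mask.data, axes=(0, 1)).copy())
        fv_rot = extract_features(rot_vol, rot_mask)
        for name in feature_local_names():
            if name.startswith("GLCM_"):
                assert fv_rot.values[name] == pytest.approx(
                    fv.values[name], rel=1e-10
                ), name

    def test_intensity_shift_effect(self, rng):
        vol, mask = _random_volume_and_mask(rng)
        shifted = ImageVolume(vol.data + 17.5, (1, 1, 1))
        fv = extract_features(vol, mask)
        fv_s = extract_features(shifted, mask)
        for name in feature_local_names():
            if name.startswith("GLCM_"):
                assert fv_s.values[name] == pytest.approx(fv.values[name], rel=1e-9)
        assert fv_s.values["FO_Mean"] - fv.values["FO_Mean"] == pytest.approx(17.5)

    def test_empty_mask_all_missing(self, rng):
        vol, _ = _random_volume_and_mask(rng)
        fv = extract_features(vol, RoiMask(np.zeros(vol.shape, dtype=bool)))
        assert len(fv.values) == 310
        assert all(math.isnan(v) for v in fv.values.values())

    def test_mask_grid_mismatch_rejected(self, rng):
        vol, _ = _random_volume_and_mask(rng)
        with pytest.raises(ValueError):
            extract_features(vol, RoiMask(np.ones((8, 8, 8), dtype=bool)))
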
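"""Unit and property tests for the 82-feature 3D texture extractor."""

import numpy as np
import pytest

from deltarad import (
    FEATURE_CATALOG,
    FEATURE_CLASS_COUNTS,
    ImageVolume,
    TumorMask,
    discretize_fixed_bin_width,
    extract_feature_vector,
    first_order_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    normalize_intensity,
)
from deltarad.radiomics import glcm_matrices, gldm_matrix, glszm_matrix

from conftest import random_roi, roi_from_levels
import oracles


class TestNormalization:
    def test_constant_volume_maps_to_100(self):
        vol = ImageVolume(np.full((3, 3, 3), 7.0))
        out = normalize_intensity(vol)
        assert np.allclose(out.intensities, 100.0)

    def test_mean_100_is_fixed_point(self):
        vol = ImageVolume(np.array([50.0, 150.0]).reshape(2, 1, 1))
        out = normalize_intensity(vol)
        assert np.allclose(out.intensities.ravel(), [50.0, 150.0])

    def test_elementwise_formula(self, rng):
        vol = ImageVolume(rng.uniform(10, 90, (8, 8, 4)))
        out = normalize_intensity(vol)
        expected = vol.intensities * 100.0 / vol.intensities.mean()
        assert np.allclose(out.intensities, expected)
        assert abs(out.intensities.mean() - 100.0) < 1e-9

    def test_zero_mean_raises_naming_scan(self):
        vol = ImageVolume(np.array([-1.0, 1.0]).reshape(2, 1, 1), scan_id="P7_pre")
        with pytest.raises(ValueError, match="P7_pre"):
            normalize_intensity(vol)


class TestDiscretization:
    def test_single_bin(self):
        vol = ImageVolume(np.array([0.0, 5.0, 9.99]).reshape(3, 1, 1))
        roi = discretize_fixed_bin_width(vol, TumorMask(np.ones((3, 1, 1), bool)), 10)
        assert roi.n_levels == 1
        assert set(roi.levels[roi.mask]) == {1}

    def test_floor_rule(self):
        vol = ImageVolume(np.array([0.0, 10.0, 25.0]).reshape(3, 1, 1))
        roi = discretize_fixed_bin_width(vol, TumorMask(np.ones((3, 1, 1), bool)), 10)
        assert list(roi.levels.ravel()) == [1, 2, 3]
        assert roi.n_levels == 3

    def test_matches_brute_force_binning(self, rng):
        vals = rng.uniform(0, 100, 500)
        vol = ImageVolume(vals.reshape(25, 20, 1))
        roi = discretize_fixed_bin_width(vol, TumorMask(np.ones((25, 20, 1), bool)), 10)
        expected = np.floor((vals - vals.min()) / 10).astype(int) + 1
        assert np.array_equal(roi.levels.ravel(), expected)

    def test_empty_mask_raises(self):
        vol = ImageVolume(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="empty mask"):
            discretize_fixed_bin_width(vol, TumorMask(np.zeros((2, 2, 2), bool)), 10)


class TestTextureExamples:
    def test_glcm_constant_roi(self):
        roi = roi_from_levels(np.ones((2, 2, 2), dtype=int))
        f = glcm_features(roi)
        assert f["Autocorrelation"] == pytest.approx(1.0)
        assert f["Inverse Variance"] == 0.0

    def test_glcm_two_voxel_pair(self):
        f = glcm_features(roi_from_levels(np.array([1, 2]).reshape(1, 1, 2)))
        # single contributing offset; symmetric matrix [[0,.5],[.5,0]]
        assert f["Autocorrelation"] == pytest.approx(2.0)

    def test_gldm_single_voxel(self):
        roi = roi_from_levels(np.array([[[1]]]))
        P = gldm_matrix(roi)
        assert P[0, 0] == 1 and P.sum() == 1  # (level 1, dependence 0)
        f = gldm_features(roi)
        assert f["Dependence Non-Uniformity Normalized"] == pytest.approx(1.0)
        assert f["Dependence Variance"] == pytest.approx(0.0)

    def test_gldm_constant_cube_neighbour_counts(self):
        roi = roi_from_levels(np.ones((3, 3, 3), dtype=int))
        P = gldm_matrix(roi)
        # 8 corners with 7 dependents, 12 edges 11, 6 faces 17, 1 center 26
        assert P[0, 7] == 8 and P[0, 11] == 12 and P[0, 17] == 6 and P[0, 26] == 1

    def test_glrlm_single_voxel(self):
        f = glrlm_features(roi_from_levels(np.array([[[1]]])))
        assert f["Long Run Emphasis"] == pytest.approx(1.0)

    def test_glrlm_line_of_four(self):
        f = glrlm_features(roi_from_levels(np.ones((1, 1, 4), dtype=int)))
        # one direction sees a single run of length 4 (LRE 16), the other 12
        # see four runs of length 1 (LRE 1): average (16 + 12) / 13
        assert f["Long Run Emphasis"] == pytest.approx(28.0 / 13.0)

    def test_glszm_single_voxel(self):
        f = glszm_features(roi_from_levels(np.array([[[1]]])))
        assert f["Small Area Emphasis"] == pytest.approx(1.0)
        assert f["Size Zone Non-Uniformity Normalized"] == pytest.approx(1.0)
        assert f["Zone Percentage"] == pytest.approx(1.0)
        assert f["Small Area High Gray Level Emphasis"] == pytest.approx(1.0)

    def test_glszm_single_zone_of_four(self):
        f = glszm_features(roi_from_levels(np.ones((2, 2, 1), dtype=int)))
        assert f["Zone Percentage"] == pytest.approx(0.25)
        assert f["Small Area Emphasis"] == pytest.approx(1.0 / 16.0)
        assert f["Size Zone Non-Uniformity Normalized"] == pytest.approx(1.0)

    def test_ngtdm_constant_roi(self):
        f = ngtdm_features(roi_from_levels(np.ones((3, 3, 1), dtype=int)))
        assert f["Contrast"] == 0.0
        assert f["Coarseness"] == pytest.approx(1.0e6)

    def test_ngtdm_two_levels_hand_computed(self):
        f = ngtdm_features(roi_from_levels(np.array([1, 2]).reshape(1, 1, 2)))
        # n = (1,1), s = (1,1), p = (.5,.5): all five features by hand
        assert f["Coarseness"] == pytest.approx(1.0)
        assert f["Contrast"] == pytest.approx(0.25)
        assert f["Busyness"] == pytest.approx(1.0)
        assert f["Complexity"] == pytest.approx(1.0)
        assert f["Strength"] == pytest.approx(1.0)

    def test_first_order_constant(self):
        vol = ImageVolume(np.full((2, 2, 2), 5.0))
        mask = TumorMask(np.ones((2, 2, 2), bool))
        norm = normalize_intensity(vol)
        roi = discretize_fixed_bin_width(norm, mask, 10)
        f = first_order_features(norm, mask, roi)
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Variance"] == 0.0

    def test_first_order_two_equal_bins(self):
        vol = ImageVolume(np.array([50.0, 150.0]).reshape(1, 1, 2))
        mask = TumorMask(np.ones((1, 1, 2), bool))
        norm = normalize_intensity(vol)
        roi = discretize_fixed_bin_width(norm, mask, 60)
        f = first_order_features(norm, mask, roi)
        assert f["Entropy"] == pytest.approx(1.0)
        assert f["Uniformity"] == pytest.approx(0.5)


CLASS_ORACLES = [
    (glcm_features, oracles.oracle_glcm),
    (gldm_features, oracles.oracle_gldm),
    (glrlm_features, oracles.oracle_glrlm),
    (glszm_features, oracles.oracle_glszm),
    (ngtdm_features, oracles.oracle_ngtdm),
]


@pytest.mark.parametrize("seed", range(8))
def test_texture_features_match_enumeration_oracles(seed):
    """Vectorized extractors agree with explicit pair/run/zone/neighbourhood
    enumeration on random ROIs (the exhaustive sweep lives in the acceptance
    suite)."""
    _, _, roi = random_roi(seed)
    for impl, oracle in CLASS_ORACLES:
        got = impl(roi)
        want = oracle(roi.levels)
        for name, v in want.items():
            assert got[name] == pytest.approx(v, rel=1e-9, abs=1e-12), name


def test_first_order_matches_histogram_oracle():
    norm, mask, roi = random_roi(99)
    got = first_order_features(norm, mask, roi)
    want = oracles.oracle_first_order(norm.intensities, roi.levels)
    for name, v in want.items():
        assert got[name] == pytest.approx(v, rel=1e-9, abs=1e-12), name


class TestFullVector:
    def test_catalog_and_class_counts(self):
        assert len(FEATURE_CATALOG) == 82
        assert len(set(FEATURE_CATALOG)) == 82
        for cls, n in FEATURE_CLASS_COUNTS.items():
            assert sum(1 for f in FEATURE_CATALOG if f.startswith(cls + " ")) == n

    def test_extraction_returns_all_82_finite(self, rng):
        vol = ImageVolume(rng.uniform(20, 200, (7, 6, 5)))
        mask = TumorMask(rng.random((7, 6, 5)) < 0.7)
        fv = extract_feature_vector(vol, mask)
        assert list(fv) == FEATURE_CATALOG
        assert all(np.isfinite(v) for v in fv.as_dict().values())

    def test_determinism(self, rng):
        vol = ImageVolume(rng.uniform(20, 200, (6, 6, 4)))
        mask = TumorMask(rng.random((6, 6, 4)) < 0.8)
        a = extract_feature_vector(vol, mask).as_dict()
        b = extract_feature_vector(vol, mask).as_dict()
        assert a == b

    def test_global_intensity_scale_invariance(self, rng):
        vol = ImageVolume(rng.uniform(20, 200, (6, 6, 4)))
        mask = TumorMask(rng.random((6, 6, 4)) < 0.8)
        a = extract_feature_vector(vol, mask).as_dict()
        for c in (3.0, 0.017):
            scaled = ImageVolume(vol.intensities * c)
            b = extract_feature_vector(scaled, mask).as_dict()
            for name in a:
                assert b[name] == pytest.approx(a[name], rel=1e-9, abs=1e-12), name

    def test_axis_permutation_invariance(self, rng):
        """Consistently transposing volume and mask permutes the direction set
        onto itself, so every feature is unchanged."""
        vol = ImageVolume(rng.uniform(20, 200, (6, 5, 4)))
        mask = TumorMask(rng.random((6, 5, 4)) < 0.8)
        a = extract_feature_vector(vol, mask).as_dict()
        perm = (2, 0, 1)
        b = extract_feature_vector(
            ImageVolume(vol.intensities.transpose(perm)),
            TumorMask(mask.voxels.transpose(perm)),
        ).as_dict()
        for name in a:
            assert b[name] == pytest.approx(a[name], rel=1e-9, abs=1e-12), name

    def test_shape_mismatch_raises(self, rng):
        vol = ImageVolume(rng.uniform(0, 1, (4, 4, 4)) + 1)
        with pytest.raises(ValueError, match="mask shape"):
            extract_feature_vector(vol, TumorMask(np.ones((3, 4, 4), bool)))


class TestMatrixInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_glszm_mass_conservation(self, seed):
        _, _, roi = random_roi(seed + 1000)
        P = glszm_matrix(roi)
        sizes = np.arange(1, P.shape[1] + 1)
        assert (P * sizes[None, :]).sum() == pytest.approx(roi.n_voxels)

    @pytest.mark.parametrize("seed", range(6))
    def test_glcm_symmetry(self, seed):
        _, _, roi = random_roi(seed + 2000)
        for P in glcm_matrices(roi):
            assert np.array_equal(P, P.T)


from hypothesis import given, settings, strategies as st_h


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st_h.integers(0, 10_000), st_h.floats(0.5, 30.0))
def test_discretization_floor_rule_property(seed, width):
    """Every voxel's level obeys floor((x - min)/W) + 1 and the minimum maps
    to level 1, for arbitrary bin widths."""
    r = np.random.default_rng(seed)
    vol = ImageVolume(r.uniform(0, 200, (3, 3, 2)))
    mask = TumorMask(r.random((3, 3, 2)) < 0.7)
    if mask.n_voxels == 0:
        return
    roi = discretize_fixed_bin_width(vol, mask, width)
    x = vol.intensities[mask.voxels]
    expected = np.floor((x - x.min()) / width).astype(int) + 1
    assert np.array_equal(roi.levels[mask.voxels], expected)
    assert roi.levels[mask.voxels].min() == 1
    assert roi.n_levels == expected.max()
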
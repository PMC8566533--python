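"""Radiomic feature panel: morphology, first-order statistics, texture
matrices against a brute-force oracle, and the per-lesion extraction layout."""

import math

import numpy as np
import pytest

from bmradiomics.features import (
    FIRST_ORDER_FEATURES,
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    SHAPE_FEATURES,
    FeatureConfig,
    TextureMatrix,
    extract_lesion_features,
    feature_ids_for_config,
    first_order_features,
    shape_features,
    texture_features,
    texture_matrix,
)
from bmradiomics.preprocess import preprocess_lesion

from conftest import make_image, make_mask, qroi_from_levels
from oracle_textures import bf_glcm, bf_gldm, bf_glszm, bf_ngtdm


def ball_mask(radius_vox: int, spacing=1.0):
    n = 2 * radius_vox + 3
    idx = np.indices((n, n, n))
    c = n // 2
    values = ((idx - c) ** 2).sum(axis=0) <= radius_vox**2
    return make_mask(values, spacing=(spacing,) * 3)


class TestShape:
    def test_collinear_line_elongation_zero(self):
        vals = np.zeros((1, 1, 20), dtype=bool)
        vals[0, 0, :] = True
        feats = shape_features(make_mask(vals))
        assert feats["Elongation"] == pytest.approx(0.0, abs=1e-12)
        assert feats["Flatness"] == pytest.approx(0.0, abs=1e-12)

    def test_digitized_sphere_elongation_one(self):
        feats = shape_features(ball_mask(10))
        assert feats["Elongation"] == pytest.approx(1.0, abs=0.02)

    def test_ellipsoid_axis_ratio(self):
        # semi-axes 20:10:10 voxels -> elongation = minor/major = 0.5
        n = 45
        idx = np.indices((n, n, n)).astype(float)
        c = n // 2
        q = ((idx[0] - c) / 20) ** 2 + ((idx[1] - c) / 10) ** 2 + ((idx[2] - c) / 10) ** 2
        feats = shape_features(make_mask(q <= 1.0))
        assert feats["Elongation"] == pytest.approx(0.5, abs=0.03)

    def test_sphere_mesh_volume_and_sphericity(self):
        r = 10
        feats = shape_features(ball_mask(r))
        assert feats["MeshVolume"] == pytest.approx(4 / 3 * math.pi * r**3, rel=0.05)
        # the staircase surface of a binary ball inflates the mesh area ~10%
        assert feats["Sphericity"] == pytest.approx(0.91, abs=0.05)
        assert feats["SurfaceVolumeRatio"] == pytest.approx(3 / r * 1.1, rel=0.1)
        assert feats["Maximum3DDiameter"] == pytest.approx(2 * r, rel=0.1)

    def test_single_voxel_fallback(self):
        vals = np.zeros((3, 3, 3), dtype=bool)
        vals[1, 1, 1] = True
        feats = shape_features(make_mask(vals))
        assert feats["Elongation"] == 1.0
        assert feats["VoxelVolume"] == 1.0

    def test_elongation_in_unit_interval_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            vals = rng.random((6, 6, 6)) > 0.5
            if not vals.any():
                continue
            feats = shape_features(make_mask(vals))
            assert 0.0 <= feats["Elongation"] <= 1.0 + 1e-12

    def test_intensity_independent(self):
        mask = ball_mask(4)
        assert set(shape_features(mask)) == set(SHAPE_FEATURES)


class TestFirstOrder:
    def _roi(self, intensities):
        vals = np.zeros((len(intensities), 1, 1))
        vals[:, 0, 0] = intensities
        return make_image(vals), make_mask(np.ones_like(vals))

    def test_constant_roi(self):
        img, mask = self._roi([5.0] * 8)
        f = first_order_features(img, mask)
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Variance"] == 0.0

    def test_small_roi_arithmetic(self):
        img, mask = self._roi([1.0, 2.0, 3.0, 4.0])
        f = first_order_features(img, mask)
        assert f["Energy"] == pytest.approx(30.0)
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Range"] == pytest.approx(3.0)
        assert f["RootMeanSquared"] == pytest.approx(math.sqrt(30.0 / 4))

    def test_uniformity_two_bins(self):
        img, mask = self._roi([1.0, 1.0, 2.0, 2.0])
        f = first_order_features(img, mask, bin_width=1.0)
        assert f["Uniformity"] == pytest.approx(0.5)
        assert f["Entropy"] == pytest.approx(1.0)  # bits

    def test_all_18_present_and_finite(self):
        rng = np.random.default_rng(9)
        img, mask = self._roi(rng.normal(size=30))
        f = first_order_features(img, mask)
        assert set(f) == set(FIRST_ORDER_FEATURES)
        assert all(np.isfinite(v) for v in f.values())


class TestTextureMatrices:
    @pytest.mark.parametrize("seed", range(12))
    def test_matrices_equal_brute_force_random_rois(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, 5, size=(4, 4, 4))  # 0 = outside mask
        if not (levels > 0).any():
            levels[0, 0, 0] = 1
        ng = int(levels.max())
        q = qroi_from_levels(levels)
        assert q.n_levels == ng
        np.testing.assert_array_equal(texture_matrix(q, "GLCM").counts, bf_glcm(levels, ng))
        np.testing.assert_array_equal(texture_matrix(q, "GLDM").counts, bf_gldm(levels, ng))
        np.testing.assert_array_equal(texture_matrix(q, "GLSZM").counts, bf_glszm(levels, ng))
        np.testing.assert_allclose(texture_matrix(q, "NGTDM").counts, bf_ngtdm(levels, ng), atol=1e-12)

    def test_constant_cube_gldm_interior(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        q = qroi_from_levels(levels)
        m = texture_matrix(q, "GLDM")
        # all 27 voxels are level 1; dependence = number of in-mask neighbours
        assert m.counts.sum() == 27
        assert m.counts[0].sum() == 27
        assert m.counts[0, 26] == 1  # the interior voxel sees all 26 neighbours
        assert m.counts[0, 7] == 8  # corners

    def test_constant_2x2x2_single_zone(self):
        q = qroi_from_levels(np.ones((2, 2, 2), dtype=np.int64))
        m = texture_matrix(q, "GLSZM")
        assert m.counts.shape == (1, 8)
        assert m.counts[0, 7] == 1
        assert m.normalizer == 1.0

    def test_glcm_symmetric(self):
        rng = np.random.default_rng(3)
        q = qroi_from_levels(rng.integers(1, 4, size=(5, 5, 5)))
        m = texture_matrix(q, "GLCM")
        np.testing.assert_array_equal(m.counts, m.counts.T)


class TestTextureFeatures:
    def test_constant_roi_gldm_gln_equals_n(self):
        for shape in [(2, 2, 2), (3, 3, 3), (4, 3, 2)]:
            n = int(np.prod(shape))
            q = qroi_from_levels(np.ones(shape, dtype=np.int64))
            f = texture_features(texture_matrix(q, "GLDM"))
            assert f["GrayLevelNonUniformity"] == pytest.approx(n)
            assert f["HighGrayLevelEmphasis"] == pytest.approx(1.0)

    def test_single_zone_lahgle_closed_form(self):
        # one zone of size s at level g: LAHGLE = g^2 * s^2
        for g, s in [(1, 8), (3, 8), (5, 27)]:
            counts = np.zeros((g, s), dtype=np.int64)
            counts[g - 1, s - 1] = 1
            m = TextureMatrix("GLSZM", counts, g, 1.0)
            f = texture_features(m, n_voxels=s)
            assert f["LargeAreaHighGrayLevelEmphasis"] == pytest.approx(g**2 * s**2)

    def test_hgle_invariant_to_roi_duplication(self):
        rng = np.random.default_rng(8)
        levels = rng.integers(1, 4, size=(3, 3, 3))
        q1 = qroi_from_levels(levels)
        f1 = texture_features(texture_matrix(q1, "GLDM"))
        # duplicate the ROI far away on a bigger grid: same layout twice
        big = np.zeros((3, 3, 9), dtype=np.int64)
        big[:, :, :3] = levels
        big[:, :, 6:] = levels
        q2 = qroi_from_levels(big)
        f2 = texture_features(texture_matrix(q2, "GLDM"))
        assert f2["HighGrayLevelEmphasis"] == pytest.approx(f1["HighGrayLevelEmphasis"])

    def test_family_feature_counts(self):
        assert len(GLCM_FEATURES) == 24
        assert len(GLDM_FEATURES) == 14
        assert len(GLSZM_FEATURES) == 16
        assert len(NGTDM_FEATURES) == 5
        assert len(FIRST_ORDER_FEATURES) == 18
        assert len(SHAPE_FEATURES) == 14

    def test_all_features_finite_on_random_rois(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            levels = rng.integers(0, 6, size=(5, 5, 5))
            levels[2, 2, 2] = max(1, levels[2, 2, 2])
            q = qroi_from_levels(levels)
            nvox = int((levels > 0).sum())
            for fam in ("GLCM", "GLDM", "GLSZM", "NGTDM"):
                f = texture_features(texture_matrix(q, fam), n_voxels=nvox)
                assert all(np.isfinite(v) for v in f.values()), fam


class TestExtraction:
    def test_default_config_yields_672_features(self):
        ids = feature_ids_for_config(FeatureConfig())
        assert len(ids) == 672
        assert len(set(ids)) == 672
        # 4 regions x 2 images x (18 + 24 + 14 + 16 + 5) + 4 x 14 morphology
        assert 4 * 2 * (18 + 24 + 14 + 16 + 5) + 4 * 14 == 672

    def test_feature_id_layout(self):
        ids = feature_ids_for_config()
        assert "T1|edema|GLDM|GrayLevelNonUniformity" in ids
        assert "T2|tumour|GLDM|HighGrayLevelEmphasis" in ids
        assert "T1|edema|GLSZM|LargeAreaHighGrayLevelEmphasis" in ids
        assert "T1|tumour|shape|Elongation" in ids

    def test_extraction_deterministic_and_complete(self, tiny_cohort):
        lesions, _ = tiny_cohort
        prep = preprocess_lesion(lesions[0])
        f1, iss1 = extract_lesion_features(prep)
        f2, _ = extract_lesion_features(prep)
        assert list(f1) == feature_ids_for_config()
        assert f1 == f2
        assert not iss1
        assert all(np.isfinite(v) for v in f1.values())

    def test_translation_invariance(self):
        rng = np.random.default_rng(21)
        core = rng.normal(100, 20, size=(4, 4, 4))
        base = np.zeros((12, 12, 12))
        maskv = np.zeros((12, 12, 12), dtype=bool)
        feats = []
        for off in (1, 5):
            vals = base.copy()
            vals[off : off + 4, off : off + 4, off : off + 4] = core
            mv = maskv.copy()
            mv[off : off + 4, off : off + 4, off : off + 4] = True
            img = make_image(vals)
            mask = make_mask(mv)
            f = first_order_features(img, mask)
            from bmradiomics.preprocess import quantize_roi

            q = quantize_roi(img, mask, 25.0)
            for fam in ("GLCM", "GLDM", "GLSZM", "NGTDM"):
                f.update(texture_features(texture_matrix(q, fam), n_voxels=mask.n_voxels))
            f.update(shape_features(mask))
            feats.append(f)
        for key in feats[0]:
            assert feats[0][key] == pytest.approx(feats[1][key], rel=1e-12), key
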
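"""Preprocessing: resampling geometry, brain-window normalization, margin
shells and fixed-bin-width quantization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bmradiomics.preprocess import (
    build_margin_masks,
    normalize_within_brain,
    quantize_roi,
    resample_to_isotropic,
)

from conftest import make_image, make_mask


class TestResample:
    def test_identity_when_already_isotropic(self):
        rng = np.random.default_rng(0)
        img = make_image(rng.normal(size=(8, 7, 6)), spacing=(0.5, 0.5, 0.5))
        out, _ = resample_to_isotropic(img, [], target=0.5)
        assert out.shape == img.shape
        np.testing.assert_array_equal(out.values, img.values)

    def test_grid_arithmetic_thick_slices(self):
        img = make_image(np.zeros((10, 10, 4)), spacing=(0.5, 0.5, 5.0))
        out, _ = resample_to_isotropic(img, [], target=0.5)
        assert out.shape == (10, 10, 40)
        assert out.spacing == (0.5, 0.5, 0.5)

    def test_constant_preserved(self):
        img = make_image(np.full((6, 6, 3), 7.25), spacing=(1.0, 1.0, 2.0))
        out, _ = resample_to_isotropic(img, [], target=0.5)
        np.testing.assert_allclose(out.values, 7.25)

    def test_masks_stay_binary_and_aligned(self):
        rng = np.random.default_rng(1)
        img = make_image(rng.normal(size=(10, 10, 5)), spacing=(1.0, 1.0, 3.0))
        mask = make_mask(rng.random((10, 10, 5)) > 0.6, spacing=(1.0, 1.0, 3.0))
        out_img, (out_mask,) = resample_to_isotropic(img, [mask], target=1.0)
        assert out_img.shape == out_mask.shape
        assert out_mask.values.dtype == bool

    @given(st.integers(2, 6), st.integers(2, 6), st.integers(2, 4))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_resampling_idempotent_on_grid(self, nx, ny, nz):
        rng = np.random.default_rng(nx * 100 + ny * 10 + nz)
        img = make_image(rng.normal(size=(nx, ny, nz)), spacing=(0.7, 1.1, 2.3))
        once, _ = resample_to_isotropic(img, [], target=1.0)
        twice, _ = resample_to_isotropic(once, [], target=1.0)
        assert once.shape == twice.shape
        np.testing.assert_array_equal(once.values, twice.values)


class TestNormalize:
    def test_three_voxel_example(self):
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [1.0, 2.0, 3.0]
        img = make_image(vals)
        brain = make_mask(np.ones((3, 1, 1)), kind="brain")
        out = normalize_within_brain(img, brain, intensity_scale=1.0)
        expected = np.array([-1.0, 0.0, 1.0]) / math.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(out.values[:, 0, 0], expected, atol=1e-12)

    def test_zero_mean_unit_variance_within_brain(self):
        rng = np.random.default_rng(3)
        img = make_image(rng.normal(50, 12, size=(12, 12, 6)))
        brain = make_mask(rng.random((12, 12, 6)) > 0.3, kind="brain")
        out = normalize_within_brain(img, brain, intensity_scale=1.0)
        vox = out.values[brain.values]
        assert abs(vox.mean()) < 1e-10
        assert abs(vox.std() - 1.0) < 1e-10

    def test_scale_factor_applied(self):
        rng = np.random.default_rng(4)
        img = make_image(rng.normal(size=(5, 5, 5)))
        brain = make_mask(np.ones((5, 5, 5)), kind="brain")
        out = normalize_within_brain(img, brain, intensity_scale=100.0)
        assert abs(out.values[brain.values].std() - 100.0) < 1e-8

    def test_constant_brain_raises(self):
        img = make_image(np.full((4, 4, 4), 3.0))
        brain = make_mask(np.ones((4, 4, 4)), kind="brain")
        with pytest.raises(ValueError):
            normalize_within_brain(img, brain)


class TestMargins:
    def test_single_voxel_ball_matches_brute_force(self):
        shape = (25, 25, 25)
        sp = 0.5
        region = np.zeros(shape, dtype=bool)
        region[12, 12, 12] = True
        brain = np.ones(shape, dtype=bool)
        margin = build_margin_masks(
            make_mask(region, "tumour", (sp,) * 3),
            make_mask(brain, "brain", (sp,) * 3),
            distance=5.0,
        )
        # brute-force: all voxels within 5 mm of the centre voxel, minus it
        idx = np.indices(shape)
        dist = np.sqrt(((idx - 12) ** 2).sum(axis=0)) * sp
        expected = (dist <= 5.0) & ~region
        np.testing.assert_array_equal(margin.values, expected)
        assert margin.kind == "tumour-margin"

    def test_margin_clipped_at_brain_boundary(self):
        shape = (20, 20, 20)
        brain = np.zeros(shape, dtype=bool)
        brain[5:15, 5:15, 5:15] = True
        region = np.zeros(shape, dtype=bool)
        region[5:8, 8:12, 8:12] = True  # touches the brain face at x=5
        margin = build_margin_masks(
            make_mask(region, "tumour", (1.0,) * 3),
            make_mask(brain, "brain", (1.0,) * 3),
            distance=3.0,
        )
        assert not (margin.values & ~brain).any()
        assert not (margin.values & region).any()

    def test_subvoxel_distance_gives_empty_margin(self):
        region = np.zeros((9, 9, 9), dtype=bool)
        region[4, 4, 4] = True
        brain = np.ones((9, 9, 9), dtype=bool)
        margin = build_margin_masks(
            make_mask(region, "tumour", (1.0,) * 3),
            make_mask(brain, "brain", (1.0,) * 3),
            distance=0.4,
        )
        assert margin.is_empty()

    def test_anisotropic_grid_rejected(self):
        region = make_mask(np.ones((4, 4, 4)), "tumour", (0.5, 0.5, 5.0))
        brain = make_mask(np.ones((4, 4, 4)), "brain", (0.5, 0.5, 5.0))
        with pytest.raises(ValueError):
            build_margin_masks(region, brain, distance=5.0)


class TestQuantize:
    def _roi(self, intensities, width):
        vals = np.zeros((len(intensities), 1, 1))
        vals[:, 0, 0] = intensities
        img = make_image(vals)
        mask = make_mask(np.ones_like(vals), kind="tumour")
        return quantize_roi(img, mask, width)

    def test_zero_anchored_edges(self):
        q = self._roi([0.0, 24.9, 25.0, 60.0], 25.0)
        assert list(q.levels[:, 0, 0]) == [1, 1, 2, 3]
        assert q.n_levels == 3

    def test_constant_roi_single_level(self):
        q = self._roi([13.0, 13.0, 13.0], 25.0)
        assert q.n_levels == 1
        assert set(q.levels[:, 0, 0]) == {1}

    def test_negative_intensities(self):
        q = self._roi([-30.0, -1.0, 1.0], 25.0)
        assert list(q.levels[:, 0, 0]) == [1, 2, 3]

    @given(st.integers(-4, 4))
    @settings(max_examples=9, deadline=None, derandomize=True)
    def test_invariant_to_bin_width_multiples(self, shift_bins):
        rng = np.random.default_rng(12)
        base = rng.uniform(-80, 80, size=(4, 4, 4))
        width = 25.0
        img_a = make_image(base)
        img_b = make_image(base + shift_bins * width)
        mask = make_mask(np.ones((4, 4, 4)), kind="tumour")
        qa = quantize_roi(img_a, mask, width)
        qb = quantize_roi(img_b, mask, width)
        np.testing.assert_array_equal(qa.levels, qb.levels)

    def test_empty_mask_raises(self):
        img = make_image(np.zeros((3, 3, 3)))
        mask = make_mask(np.zeros((3, 3, 3)), kind="tumour")
        with pytest.raises(ValueError):
            quantize_roi(img, mask, 25.0)
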
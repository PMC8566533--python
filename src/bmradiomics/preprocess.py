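"""Image preprocessing: isotropic resampling, brain-window normalization,
margin-mask construction and fixed-bin-width gray-level quantization.

The processing order mirrors the analysis pipeline: resample both modalities
to a common isotropic grid (default 0.5 mm), z-normalize intensities within
the brain, derive the 5 mm margin shells, then quantize each ROI for texture
analysis with a fixed bin width (default 25) whose bin edges sit at integer
multiples of the width.
"""

from __future__ import annotations

import math
import numpy as np
from scipy import ndimage

from .core import QuantizedROI, RegionMask, VolumetricImage

__all__ = [
    "resample_to_isotropic",
    "normalize_within_brain",
    "build_margin_masks",
    "quantize_roi",
    "preprocess_lesion",
]

DEFAULT_TARGET_MM = 0.5
DEFAULT_MARGIN_MM = 5.0
DEFAULT_BIN_WIDTH = 25.0
#: Multiplier applied after unit-variance normalization so that a bin width
#: of 25 yields a useful number of gray levels (z-scores alone would collapse
#: nearly the whole brain into one bin).
DEFAULT_INTENSITY_SCALE = 100.0


def _output_shape(shape: tuple[int, ...], spacing: tuple[float, ...], target: float) -> tuple[int, ...]:
    # ceil keeps the full physical extent: never crops tissue at the far edge
    return tuple(int(math.ceil(n * s / target)) for n, s in zip(shape, spacing))


def resample_to_isotropic(
    image: VolumetricImage,
    masks: list[RegionMask] | None = None,
    target: float = DEFAULT_TARGET_MM,
) -> tuple[VolumetricImage, list[RegionMask]]:
    """Resample an image (trilinear) and its masks (nearest) to an isotropic grid.

    The output grid is anchored at the input origin with per-axis size
    ``ceil(n_in * spacing_in / target)``.  Masks stay strictly binary.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if image.values.size == 0:
        raise ValueError("cannot resample an empty image")
    masks = masks or []
    for m in masks:
        if m.shape != image.shape:
            raise ValueError("mask grid does not match image grid")

    out_shape = _output_shape(image.shape, image.spacing, target)
    if tuple(image.spacing) == (target, target, target):
        # identity: same grid, values untouched
        out_img = VolumetricImage(image.values.copy(), (target,) * 3, image.origin, image.modality)
        out_masks = [RegionMask(m.values.copy(), m.kind, (target,) * 3, m.origin) for m in masks]
        return out_img, out_masks

    # output voxel centre i maps to input index i * target / spacing;
    # single-precision interpolation (intensities are O(100), so float32
    # rounding is far below the quantization bin width)
    coords = np.empty((3, *out_shape), dtype=np.float32)
    for ax in range(3):
        axis_idx = (np.arange(out_shape[ax]) * target / image.spacing[ax]).astype(np.float32)
        shape = [1, 1, 1]
        shape[ax] = out_shape[ax]
        coords[ax] = axis_idx.reshape(shape)
    vals = ndimage.map_coordinates(image.values.astype(np.float32), coords, order=1, mode="nearest").astype(np.float64)
    out_img = VolumetricImage(vals, (target,) * 3, image.origin, image.modality)
    # nearest-neighbour mask resampling via direct index lookup
    nn_idx = [
        np.clip(np.rint(np.arange(n) * target / s).astype(np.intp), 0, n_in - 1)
        for n, s, n_in in zip(out_shape, image.spacing, image.shape)
    ]
    out_masks = [
        RegionMask(m.values[np.ix_(*nn_idx)], m.kind, (target,) * 3, m.origin) for m in masks
    ]
    return out_img, out_masks


def normalize_within_brain(
    image: VolumetricImage,
    brain: RegionMask,
    intensity_scale: float = DEFAULT_INTENSITY_SCALE,
) -> VolumetricImage:
    """Normalize intensities to zero mean / unit variance over brain voxels.

    The same affine transform is applied outside the brain; the result is
    then multiplied by ``intensity_scale``.  Uses the population standard
    deviation.  Raises on a (degenerate) constant brain region.
    """
    if brain.shape != image.shape:
        raise ValueError("brain mask grid does not match image grid")
    vox = image.values[brain.values]
    if vox.size < 2:
        raise ValueError("brain mask must contain at least 2 voxels")
    mu = float(vox.mean())
    sd = float(vox.std())  # population sd
    if sd == 0:
        raise ValueError("zero intensity variance within the brain (degenerate image)")
    vals = (image.values - mu) / sd * intensity_scale
    return VolumetricImage(vals, image.spacing, image.origin, image.modality)


def build_margin_masks(
    region: RegionMask,
    brain: RegionMask,
    distance: float = DEFAULT_MARGIN_MM,
    kind: str | None = None,
) -> RegionMask:
    """Build the margin shell around a region, clipped to the brain.

    The margin is the set of voxels outside ``region`` whose centre lies
    within ``distance`` mm (Euclidean, to the nearest region-voxel centre),
    intersected with the brain mask.  ``kind`` defaults to ``tumour-margin``
    for a tumour source and ``lesion-margin`` otherwise.  The grid must be
    isotropic (resample first).
    """
    if distance <= 0:
        raise ValueError("margin distance must be positive")
    sp = region.spacing
    if not (abs(sp[0] - sp[1]) < 1e-9 and abs(sp[1] - sp[2]) < 1e-9):
        raise ValueError("margin construction requires an isotropic grid; resample first")
    if region.shape != brain.shape:
        raise ValueError("region and brain masks must share a grid")
    if region.is_empty():
        raise ValueError("cannot build a margin around an empty region")
    if np.any(region.values & ~brain.values):
        raise ValueError("region extends outside the brain")
    if kind is None:
        kind = "tumour-margin" if region.kind == "tumour" else "lesion-margin"
    # EDT only on the padded bounding box: the margin cannot extend further
    pad = int(math.ceil(distance / sp[0])) + 1
    bbox = ndimage.find_objects(region.values.astype(np.int8))[0]
    sl = tuple(
        slice(max(0, s.start - pad), min(n, s.stop + pad))
        for s, n in zip(bbox, region.shape)
    )
    margin = np.zeros(region.shape, dtype=bool)
    sub = region.values[sl]
    dist = ndimage.distance_transform_edt(~sub, sampling=sp)
    margin[sl] = (dist <= distance) & ~sub & brain.values[sl]
    return RegionMask(margin, kind, sp, region.origin)


def quantize_roi(
    image: VolumetricImage,
    mask: RegionMask,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> QuantizedROI:
    """Quantize in-mask intensities into fixed-width bins anchored at zero.

    ``level(v) = floor(x_v / w) - floor(min_ROI / w) + 1`` so bin edges fall
    on integer multiples of the width and the ROI minimum maps to level 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if mask.is_empty():
        raise ValueError("cannot quantize an empty mask")
    if mask.shape != image.shape:
        raise ValueError("mask grid does not match image grid")
    inm = mask.values
    # quantize only within the mask bounding box; levels stay 0 elsewhere
    sl = ndimage.find_objects(inm.astype(np.int8))[0]
    sub_in = inm[sl]
    x = image.values[sl][sub_in]
    base = math.floor(x.min() / bin_width)
    lv = np.floor(image.values[sl] / bin_width).astype(np.int64) - base + 1
    levels = np.zeros(image.shape, dtype=np.int64)
    levels[sl] = np.where(sub_in, lv, 0)
    ng = int(lv[sub_in].max())
    return QuantizedROI(levels, ng, float(bin_width), mask, image.spacing)


def preprocess_lesion(
    lesion,
    target: float = DEFAULT_TARGET_MM,
    margin: float = DEFAULT_MARGIN_MM,
    intensity_scale: float = DEFAULT_INTENSITY_SCALE,
):
    """Run the per-lesion preprocessing chain on both modalities.

    Returns a dict with normalized isotropic images and, per modality, the
    tumour / edema / brain masks plus the derived tumour-margin (around the
    tumour) and lesion-margin (around tumour + edema) shells.
    """
    out = {}
    for mod, img, masks in (
        ("t1", lesion.image_t1, (lesion.tumour_mask, lesion.edema_mask, lesion.brain_mask)),
        (
            "flair",
            lesion.image_flair,
            (
                lesion.tumour_mask_flair or lesion.tumour_mask,
                lesion.edema_mask_flair or lesion.edema_mask,
                lesion.brain_mask_flair or lesion.brain_mask,
            ),
        ),
    ):
        rimg, (tum, ede, brain) = resample_to_isotropic(img, list(masks), target)
        nimg = normalize_within_brain(rimg, brain, intensity_scale)
        lesion_region = RegionMask(tum.values | ede.values, "edema", tum.spacing, tum.origin)
        tmarg = build_margin_masks(tum, brain, margin, kind="tumour-margin")
        lmarg = build_margin_masks(lesion_region, brain, margin, kind="lesion-margin")
        out[mod] = {
            "image": nimg,
            "tumour": tum,
            "edema": ede,
            "brain": brain,
            "tumour-margin": tmarg,
            "lesion-margin": lmarg,
        }
    return out
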
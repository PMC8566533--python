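"""Radiomic feature panel: morphology, first-order statistics and the four
gray-level texture families (GLCM, GLDM, GLSZM, NGTDM).

All formulas follow the community-standard (IBSI-consistent) definitions.
Texture matrices are computed in 3D with 26-connectivity and, for the GLCM,
distance-1 offsets over the 13 unique directions aggregated (summed) before
normalization.  Gray levels come from fixed-bin-width quantization
(:func:`bmradiomics.preprocess.quantize_roi`).

Feature ids follow ``"<image>|<region>|<family>|<name>"``, e.g.
``"T1|edema|GLDM|GrayLevelNonUniformity"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .core import QuantizedROI, RegionMask, VolumetricImage
from .preprocess import DEFAULT_BIN_WIDTH, quantize_roi

__all__ = [
    "shape_features",
    "first_order_features",
    "texture_matrix",
    "texture_features",
    "extract_lesion_features",
    "FeatureConfig",
    "TextureMatrix",
    "feature_ids_for_config",
    "GLCM_FEATURES",
    "GLDM_FEATURES",
    "GLSZM_FEATURES",
    "NGTDM_FEATURES",
    "FIRST_ORDER_FEATURES",
    "SHAPE_FEATURES",
]

_EPS = np.spacing(1.0)

# ---------------------------------------------------------------------------
# texture matrix container
# ---------------------------------------------------------------------------


@dataclass
class TextureMatrix:
    """A gray-level texture matrix plus the normalizer its features divide by.

    ``counts`` layout by family:

    * GLCM  — ``(Ng, Ng)`` symmetric pair counts summed over 13 directions
    * GLDM  — ``(Ng, 27)`` voxel counts by (level, dependence d in [0, 26])
    * GLSZM — ``(Ng, S_max)`` zone counts by (level, zone size)
    * NGTDM — ``(Ng, 3)`` columns ``(n_i, p_i, s_i)``
    """

    family: str
    counts: np.ndarray
    ng: int
    normalizer: float


# 13 unique direction offsets for distance-1 3D GLCM (positive half of the
# 26-neighbourhood).
_GLCM_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _crop_levels(qroi: QuantizedROI) -> np.ndarray:
    """Levels array cropped to the mask bounding box (0 outside the mask)."""
    inm = qroi.mask.values
    sl = ndimage.find_objects(inm.astype(np.int8))[0]
    lv = np.where(inm, qroi.levels, 0)
    return lv[sl]


def _glcm(levels: np.ndarray, ng: int) -> np.ndarray:
    counts = np.zeros((ng, ng), dtype=np.int64)
    for off in _GLCM_OFFSETS:
        sl_a = tuple(slice(max(0, -o), levels.shape[ax] - max(0, o)) for ax, o in enumerate(off))
        sl_b = tuple(slice(max(0, o), levels.shape[ax] + min(0, o)) for ax, o in enumerate(off))
        a = levels[sl_a].ravel()
        b = levels[sl_b].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1)
    return counts + counts.T  # symmetric aggregation


def _neighbour_stack(levels: np.ndarray):
    """Yield, for each of the 26 neighbour offsets, the shifted level array
    (0-padded) aligned with ``levels``."""
    padded = np.pad(levels, 1, mode="constant")
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                yield padded[
                    1 + dx : 1 + dx + levels.shape[0],
                    1 + dy : 1 + dy + levels.shape[1],
                    1 + dz : 1 + dz + levels.shape[2],
                ]


def _gldm(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    inm = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for nb in _neighbour_stack(levels):
        dep += ((nb > 0) & (np.abs(nb - levels) <= alpha)).astype(np.int64)
    counts = np.zeros((ng, 27), dtype=np.int64)
    np.add.at(counts, (levels[inm] - 1, dep[inm]), 1)
    return counts


def _glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    zones: list[tuple[int, int]] = []
    for g in range(1, ng + 1):
        lab, nlab = ndimage.label(levels == g, structure=_STRUCT_26)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    smax = max(s for _, s in zones)
    counts = np.zeros((ng, smax), dtype=np.int64)
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return counts


def _ngtdm(levels: np.ndarray, ng: int) -> np.ndarray:
    inm = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for nb in _neighbour_stack(levels):
        valid = nb > 0
        nb_sum += np.where(valid, nb, 0)
        nb_cnt += valid.astype(np.int64)
    has_nb = inm & (nb_cnt > 0)
    table = np.zeros((ng, 3), dtype=np.float64)
    lv = levels[has_nb]
    diffs = np.abs(lv - nb_sum[has_nb] / nb_cnt[has_nb])
    np.add.at(table[:, 0], lv - 1, 1)
    np.add.at(table[:, 2], lv - 1, diffs)
    nv = table[:, 0].sum()
    if nv > 0:
        table[:, 1] = table[:, 0] / nv
    return table


def texture_matrix(qroi: QuantizedROI, family: str, _levels: np.ndarray | None = None) -> TextureMatrix:
    """Compute the texture matrix of one family for a quantized ROI.

    ``_levels`` lets batch callers pass the bbox-cropped level grid once
    instead of recomputing it per family.
    """
    if qroi.n_levels < 1:
        raise ValueError("quantized ROI has no gray levels")
    levels = _crop_levels(qroi) if _levels is None else _levels
    ng = qroi.n_levels
    if family == "GLCM":
        counts = _glcm(levels, ng)
        norm = float(counts.sum())
    elif family == "GLDM":
        counts = _gldm(levels, ng)
        norm = float(counts.sum())  # = number of in-mask voxels
    elif family == "GLSZM":
        counts = _glszm(levels, ng)
        norm = float(counts.sum())  # = number of zones
    elif family == "NGTDM":
        counts = _ngtdm(levels, ng)
        norm = float(counts[:, 0].sum())
    else:
        raise ValueError(f"unknown texture family {family!r}")
    return TextureMatrix(family, counts, ng, norm)


# ---------------------------------------------------------------------------
# texture features
# ---------------------------------------------------------------------------

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLDM_FEATURES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

NGTDM_FEATURES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _glcm_features(m: TextureMatrix) -> dict[str, float]:
    if m.normalizer == 0:
        # single-voxel ROI: no pairs at all; define neutral values
        return {name: 0.0 for name in GLCM_FEATURES} | {"Correlation": 1.0, "MCC": 1.0}
    P = m.counts / m.normalizer
    ng = m.ng
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float((px * i).sum())
    uy = float((py * i).sum())
    sx = math.sqrt(float((px * (i - ux) ** 2).sum()))
    sy = math.sqrt(float((py * (i - uy) ** 2).sum()))

    # diagonal (difference) and cross-diagonal (sum) probabilities
    k_diff = np.arange(ng)
    pxmy = np.array([P[np.abs(I - J) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    pxpy = np.array([P[(I + J) == k].sum() for k in k_sum])

    da = float((pxmy * k_diff).sum())
    hxy = _entropy2(P.ravel())
    hx = _entropy2(px)
    hy = _entropy2(py)
    pxy_prod = np.outer(px, py)
    nz = pxy_prod > 0
    hxy1 = float(-(P[nz] * np.log2(pxy_prod[nz])).sum())
    hxy2 = _entropy2(pxy_prod.ravel())

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((P * I * J).sum())
    out["JointAverage"] = ux
    cdev = I + J - ux - uy
    out["ClusterProminence"] = float((P * cdev**4).sum())
    out["ClusterShade"] = float((P * cdev**3).sum())
    out["ClusterTendency"] = float((P * cdev**2).sum())
    out["Contrast"] = float((P * (I - J) ** 2).sum())
    out["Correlation"] = 1.0 if sx * sy == 0 else float(((P * (I - ux) * (J - uy)).sum()) / (sx * sy))
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = _entropy2(pxmy)
    out["DifferenceVariance"] = float((pxmy * (k_diff - da) ** 2).sum())
    out["Id"] = float((pxmy / (1 + k_diff)).sum())
    out["Idm"] = float((pxmy / (1 + k_diff**2)).sum())
    out["Idmn"] = float((pxmy / (1 + (k_diff / ng) ** 2)).sum())
    out["Idn"] = float((pxmy / (1 + k_diff / ng)).sum())
    denom = max(hx, hy)
    out["Imc1"] = 0.0 if denom == 0 else float((hxy - hxy1) / denom)
    out["Imc2"] = float(math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))))
    out["InverseVariance"] = float((pxmy[1:] / (k_diff[1:] ** 2)).sum()) if ng > 1 else 0.0
    out["JointEnergy"] = float((P**2).sum())
    out["JointEntropy"] = hxy
    if ng == 1:
        out["MCC"] = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            Q = (P / np.where(px[:, None] > 0, px[:, None], 1)) @ (P / np.where(py[:, None] > 0, py[:, None], 1)).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        out["MCC"] = float(math.sqrt(max(0.0, ev[-2]))) if ev.size >= 2 else 1.0
    out["MaximumProbability"] = float(P.max())
    out["SumAverage"] = float((pxpy * k_sum).sum())
    out["SumEntropy"] = _entropy2(pxpy)
    out["SumSquares"] = float((P * (I - ux) ** 2).sum())
    return out


def _gldm_features(m: TextureMatrix) -> dict[str, float]:
    nz = m.normalizer
    if nz == 0:
        raise ValueError("empty GLDM")
    P = m.counts.astype(np.float64)
    ng = m.ng
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, P.shape[1] + 1)[None, :]  # dependence size d + 1
    p = P / nz
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_i = float((pg * i.ravel()).sum())
    mu_j = float((pd * j.ravel()).sum())
    out: dict[str, float] = {}
    out["SmallDependenceEmphasis"] = float((P / j**2).sum() / nz)
    out["LargeDependenceEmphasis"] = float((P * j**2).sum() / nz)
    out["GrayLevelNonUniformity"] = float((P.sum(axis=1) ** 2).sum() / nz)
    out["DependenceNonUniformity"] = float((P.sum(axis=0) ** 2).sum() / nz)
    out["DependenceNonUniformityNormalized"] = out["DependenceNonUniformity"] / nz
    out["GrayLevelVariance"] = float((pg * (i.ravel() - mu_i) ** 2).sum())
    out["DependenceVariance"] = float((pd * (j.ravel() - mu_j) ** 2).sum())
    out["DependenceEntropy"] = _entropy2(p.ravel())
    out["LowGrayLevelEmphasis"] = float((P / i**2).sum() / nz)
    out["HighGrayLevelEmphasis"] = float((P * i**2).sum() / nz)
    out["SmallDependenceLowGrayLevelEmphasis"] = float((P / (i**2 * j**2)).sum() / nz)
    out["SmallDependenceHighGrayLevelEmphasis"] = float((P * i**2 / j**2).sum() / nz)
    out["LargeDependenceLowGrayLevelEmphasis"] = float((P * j**2 / i**2).sum() / nz)
    out["LargeDependenceHighGrayLevelEmphasis"] = float((P * i**2 * j**2).sum() / nz)
    return out


def _glszm_features(m: TextureMatrix, n_voxels: int) -> dict[str, float]:
    nz = m.normalizer
    if nz == 0:
        raise ValueError("empty GLSZM")
    P = m.counts.astype(np.float64)
    ng = m.ng
    i = np.arange(1, ng + 1)[:, None]
    s = np.arange(1, P.shape[1] + 1)[None, :]
    p = P / nz
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float((pg * i.ravel()).sum())
    mu_s = float((ps * s.ravel()).sum())
    out: dict[str, float] = {}
    out["SmallAreaEmphasis"] = float((P / s**2).sum() / nz)
    out["LargeAreaEmphasis"] = float((P * s**2).sum() / nz)
    out["GrayLevelNonUniformity"] = float((P.sum(axis=1) ** 2).sum() / nz)
    out["GrayLevelNonUniformityNormalized"] = out["GrayLevelNonUniformity"] / nz
    out["SizeZoneNonUniformity"] = float((P.sum(axis=0) ** 2).sum() / nz)
    out["SizeZoneNonUniformityNormalized"] = out["SizeZoneNonUniformity"] / nz
    out["ZonePercentage"] = float(nz / n_voxels)
    out["GrayLevelVariance"] = float((pg * (i.ravel() - mu_i) ** 2).sum())
    out["ZoneVariance"] = float((ps * (s.ravel() - mu_s) ** 2).sum())
    out["ZoneEntropy"] = _entropy2(p.ravel())
    out["LowGrayLevelZoneEmphasis"] = float((P / i**2).sum() / nz)
    out["HighGrayLevelZoneEmphasis"] = float((P * i**2).sum() / nz)
    out["SmallAreaLowGrayLevelEmphasis"] = float((P / (i**2 * s**2)).sum() / nz)
    out["SmallAreaHighGrayLevelEmphasis"] = float((P * i**2 / s**2).sum() / nz)
    out["LargeAreaLowGrayLevelEmphasis"] = float((P * s**2 / i**2).sum() / nz)
    out["LargeAreaHighGrayLevelEmphasis"] = float((P * i**2 * s**2).sum() / nz)
    return out


def _ngtdm_features(m: TextureMatrix) -> dict[str, float]:
    t = m.counts
    nv = m.normalizer
    if nv == 0:
        raise ValueError("empty NGTDM")
    n_i, p_i, s_i = t[:, 0], t[:, 1], t[:, 2]
    i = np.arange(1, m.ng + 1, dtype=np.float64)
    act = p_i > 0
    ngp = int(act.sum())
    out: dict[str, float] = {}
    ps = float((p_i * s_i).sum())
    out["Coarseness"] = 1e6 if ps == 0 else float(1.0 / ps)
    if ngp <= 1:
        out["Contrast"] = 0.0
    else:
        pij = np.outer(p_i[act], p_i[act])
        dij = (i[act][:, None] - i[act][None, :]) ** 2
        out["Contrast"] = float((pij * dij).sum() / (ngp * (ngp - 1)) * s_i.sum() / nv)
    num = float((p_i * s_i).sum())
    den = float(np.abs(i[act][:, None] * p_i[act][:, None] - i[act][None, :] * p_i[act][None, :]).sum())
    out["Busyness"] = 0.0 if den == 0 else num / den
    if ngp <= 1:
        out["Complexity"] = 0.0
        out["Strength"] = 0.0
    else:
        ia, pa, sa = i[act], p_i[act], s_i[act]
        absdiff = np.abs(ia[:, None] - ia[None, :])
        out["Complexity"] = float(
            (absdiff * (pa[:, None] * sa[:, None] + pa[None, :] * sa[None, :]) / (pa[:, None] + pa[None, :])).sum() / nv
        )
        ssum = float(s_i.sum())
        out["Strength"] = (
            0.0 if ssum == 0 else float(((pa[:, None] + pa[None, :]) * (ia[:, None] - ia[None, :]) ** 2).sum() / ssum)
        )
    return out


def texture_features(matrix: TextureMatrix, n_voxels: int | None = None) -> dict[str, float]:
    """Named features of one texture family from its matrix.

    ``n_voxels`` (in-mask voxel count) is required for the GLSZM zone
    percentage; for other families it is ignored.
    """
    if matrix.family == "GLCM":
        return _glcm_features(matrix)
    if matrix.family == "GLDM":
        return _gldm_features(matrix)
    if matrix.family == "GLSZM":
        if n_voxels is None:
            raise ValueError("GLSZM features need the in-mask voxel count")
        return _glszm_features(matrix, n_voxels)
    if matrix.family == "NGTDM":
        return _ngtdm_features(matrix)
    raise ValueError(f"unknown texture family {matrix.family!r}")


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

SHAPE_FEATURES = (
    "Elongation",
    "Flatness",
    "LeastAxisLength",
    "MajorAxisLength",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice",
    "Maximum3DDiameter",
    "MeshVolume",
    "MinorAxisLength",
    "Sphericity",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "VoxelVolume",
)


def _mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 50:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    return float(pdist(points).max())


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~eroded)


def shape_features(mask: RegionMask, spacing: tuple[float, float, float] | None = None) -> dict[str, float]:
    """The 14 morphology features of a binary region.

    Axis lengths derive from the PCA eigenvalues of physical voxel-centre
    coordinates (length = 4*sqrt(lambda)); elongation = sqrt(l2/l1) and
    flatness = sqrt(l3/l1), both in [0, 1] with 0 for a line and 1 for a
    ball.  Volume and surface area come from a marching-cubes mesh.  A
    single-voxel region falls back to elongation = flatness = 1.
    """
    if mask.is_empty():
        raise ValueError("cannot compute shape features of an empty mask")
    sp = np.asarray(spacing if spacing is not None else mask.spacing, dtype=float)
    mv = mask.values
    coords = np.argwhere(mv) * sp
    n = len(coords)

    out: dict[str, float] = {}
    if n < 2:
        lam = np.zeros(3)
        out["Elongation"] = 1.0
        out["Flatness"] = 1.0
    else:
        cov = np.cov(coords.T, bias=False)
        lam = np.clip(np.sort(np.linalg.eigvalsh(cov))[::-1], 0.0, None)
        out["Elongation"] = float(math.sqrt(lam[1] / lam[0])) if lam[0] > 0 else 1.0
        out["Flatness"] = float(math.sqrt(lam[2] / lam[0])) if lam[0] > 0 else 1.0
    out["MajorAxisLength"] = float(4 * math.sqrt(lam[0]))
    out["MinorAxisLength"] = float(4 * math.sqrt(lam[1]))
    out["LeastAxisLength"] = float(4 * math.sqrt(lam[2]))

    verts, faces = _mesh(mv, sp)
    vol = _mesh_volume(verts, faces)
    area = float(measure.mesh_surface_area(verts, faces))
    out["MeshVolume"] = vol
    out["SurfaceArea"] = area
    out["Sphericity"] = float((36 * math.pi * vol**2) ** (1 / 3) / area) if area > 0 and vol > 0 else 0.0
    out["SurfaceVolumeRatio"] = float(area / vol) if vol > 0 else float("inf")
    out["VoxelVolume"] = float(n * np.prod(sp))

    svox = _boundary_voxels(mv)
    out["Maximum3DDiameter"] = _max_pairwise(svox * sp)
    # 2D diameters: max in-plane extent over slabs perpendicular to one axis
    for name, drop_axis in (
        ("Maximum2DDiameterSlice", 2),
        ("Maximum2DDiameterColumn", 1),
        ("Maximum2DDiameterRow", 0),
    ):
        keep = [ax for ax in range(3) if ax != drop_axis]
        best = 0.0
        for idx in np.unique(svox[:, drop_axis]):
            pts = svox[svox[:, drop_axis] == idx][:, keep] * sp[keep]
            best = max(best, _max_pairwise(pts))
        out[name] = best
    return out


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

FIRST_ORDER_FEATURES = (
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
)


def first_order_features(
    image: VolumetricImage,
    mask: RegionMask,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict[str, float]:
    """The 18 first-order statistics of in-mask intensities.

    Entropy (bits) and uniformity are computed on the fixed-bin-width
    histogram with the same zero-anchored bin rule used for quantization.
    """
    if mask.is_empty():
        raise ValueError("cannot compute first-order features of an empty mask")
    x = image.values[mask.values].astype(np.float64)
    n = x.size
    vv = float(np.prod(image.spacing))
    mu = float(x.mean())
    sd = float(x.std())

    bins = np.floor(x / bin_width).astype(np.int64)
    p = np.bincount(bins - bins.min()).astype(np.float64) / n

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    out: dict[str, float] = {}
    out["Energy"] = float((x**2).sum())
    out["TotalEnergy"] = out["Energy"] * vv
    out["Entropy"] = _entropy2(p)
    out["Uniformity"] = float((p**2).sum())
    out["Minimum"] = float(x.min())
    out["Maximum"] = float(x.max())
    out["Range"] = out["Maximum"] - out["Minimum"]
    out["Mean"] = mu
    out["Median"] = float(np.median(x))
    out["10Percentile"] = float(p10)
    out["90Percentile"] = float(p90)
    out["InterquartileRange"] = float(p75 - p25)
    out["MeanAbsoluteDeviation"] = float(np.abs(x - mu).mean())
    out["RobustMeanAbsoluteDeviation"] = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    out["RootMeanSquared"] = float(math.sqrt((x**2).mean()))
    out["Variance"] = sd**2
    out["Skewness"] = 0.0 if sd == 0 else float(((x - mu) ** 3).mean() / sd**3)
    out["Kurtosis"] = 0.0 if sd == 0 else float(((x - mu) ** 4).mean() / sd**4)
    return out


# ---------------------------------------------------------------------------
# per-lesion extraction
# ---------------------------------------------------------------------------

TEXTURE_FAMILIES = ("GLCM", "GLDM", "GLSZM", "NGTDM")
_FAMILY_NAMES = {
    "GLCM": GLCM_FEATURES,
    "GLDM": GLDM_FEATURES,
    "GLSZM": GLSZM_FEATURES,
    "NGTDM": NGTDM_FEATURES,
}

INTENSITY_REGIONS = ("tumour", "edema", "tumour-margin", "lesion-margin")
# morphology source grids: tumour-side masks from the CE-T1w grid, edema-side
# masks from the T2-FLAIR grid
SHAPE_SOURCES = (
    ("T1", "tumour"),
    ("T1", "tumour-margin"),
    ("T2", "edema"),
    ("T2", "lesion-margin"),
)
_IMAGE_TAGS = {"t1": "T1", "flair": "T2"}


@dataclass
class FeatureConfig:
    """What to extract and with which quantization."""

    bin_width: float = DEFAULT_BIN_WIDTH
    families: tuple[str, ...] = TEXTURE_FAMILIES
    regions: tuple[str, ...] = INTENSITY_REGIONS
    include_shape: bool = True
    include_first_order: bool = True


def feature_ids_for_config(config: FeatureConfig | None = None) -> list[str]:
    """The full ordered id list produced by :func:`extract_lesion_features`."""
    config = config or FeatureConfig()
    ids: list[str] = []
    if config.include_shape:
        for img, region in SHAPE_SOURCES:
            if region in config.regions or region in ("tumour", "edema"):
                ids.extend(f"{img}|{region}|shape|{n}" for n in SHAPE_FEATURES)
    for img in ("T1", "T2"):
        for region in config.regions:
            if config.include_first_order:
                ids.extend(f"{img}|{region}|firstorder|{n}" for n in FIRST_ORDER_FEATURES)
            for fam in config.families:
                ids.extend(f"{img}|{region}|{fam}|{n}" for n in _FAMILY_NAMES[fam])
    return ids


def extract_lesion_features(
    preprocessed: dict,
    config: FeatureConfig | None = None,
) -> tuple[dict[str, float], list[str]]:
    """Extract the configured feature panel from a preprocessed lesion.

    ``preprocessed`` is the output of
    :func:`bmradiomics.preprocess.preprocess_lesion`.  Returns the feature
    map and a list of issue strings (empty regions are flagged and their
    features set to NaN rather than silently dropped).
    """
    config = config or FeatureConfig()
    out: dict[str, float] = {}
    issues: list[str] = []

    if config.include_shape:
        for img_tag, region in SHAPE_SOURCES:
            mod = "t1" if img_tag == "T1" else "flair"
            mask = preprocessed[mod][region]
            if mask.is_empty():
                issues.append(f"empty region for shape: {img_tag}|{region}")
                for n in SHAPE_FEATURES:
                    out[f"{img_tag}|{region}|shape|{n}"] = float("nan")
            else:
                for n, v in shape_features(mask).items():
                    out[f"{img_tag}|{region}|shape|{n}"] = v

    for mod in ("t1", "flair"):
        img_tag = _IMAGE_TAGS[mod]
        image = preprocessed[mod]["image"]
        for region in config.regions:
            mask = preprocessed[mod][region]
            prefix_issue = f"empty region: {img_tag}|{region}"
            if mask.is_empty():
                issues.append(prefix_issue)
                if config.include_first_order:
                    for n in FIRST_ORDER_FEATURES:
                        out[f"{img_tag}|{region}|firstorder|{n}"] = float("nan")
                for fam in config.families:
                    for n in _FAMILY_NAMES[fam]:
                        out[f"{img_tag}|{region}|{fam}|{n}"] = float("nan")
                continue
            if config.include_first_order:
                for n, v in first_order_features(image, mask, config.bin_width).items():
                    out[f"{img_tag}|{region}|firstorder|{n}"] = v
            qroi = quantize_roi(image, mask, config.bin_width)
            nvox = mask.n_voxels
            cropped = _crop_levels(qroi)
            for fam in config.families:
                mat = texture_matrix(qroi, fam, _levels=cropped)
                for n, v in texture_features(mat, n_voxels=nvox).items():
                    out[f"{img_tag}|{region}|{fam}|{n}"] = v

    ordered = {fid: out[fid] for fid in feature_ids_for_config(config)}
    return ordered, issues
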
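"""Core data containers for the brain-metastasis radiomics pipeline.

Volumes are stored as plain ``numpy`` arrays with explicit per-axis voxel
spacing (mm) and a physical origin; NIfTI round-tripping goes through
``nibabel`` with a diagonal affine.  Masks carry a semantic ``kind`` so that
downstream feature ids can name the region they came from.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumetricImage",
    "RegionMask",
    "QuantizedROI",
    "ClinicalRecord",
    "LesionSample",
    "FeatureTable",
    "MASK_KINDS",
    "HISTOLOGIES",
    "DOSE_LEVELS_GY",
]

MASK_KINDS = ("tumour", "edema", "tumour-margin", "lesion-margin", "brain")

#: Histology categories used for one-hot clinical encoding.
HISTOLOGIES = ("lung", "breast", "melanoma", "colorectal", "rcc", "other")

#: Total-dose support (Gy over five fractions) for hypo-fractionated SRT.
DOSE_LEVELS_GY = (22.5, 25.0, 27.5, 30.0, 32.5, 35.0)


@dataclass
class VolumetricImage:
    """A 3D scalar grid with per-axis spacing (mm), origin (mm) and modality.

    ``modality`` is ``"CE-T1w"`` or ``"T2-FLAIR"``; the grid is index-ordered
    (i, j, k) with physical position ``origin + index * spacing``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CE-T1w"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("image values must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine())
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path, modality: str = "CE-T1w") -> "VolumetricImage":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, origin, modality)


@dataclass
class RegionMask:
    """A binary grid aligned with an image grid.

    ``kind`` is one of :data:`MASK_KINDS`.  Margin masks may legitimately be
    empty (a region touching the brain boundary can have its margin clipped
    away); all other kinds are expected non-empty.
    """

    values: np.ndarray
    kind: str
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask values must be a 3D array")
        if self.kind not in MASK_KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not bool(self.values.any())

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.uint8), self.affine())
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path, kind: str) -> "RegionMask":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(np.asarray(img.dataobj) > 0, kind, spacing, origin)


@dataclass
class QuantizedROI:
    """Gray levels of a masked region after fixed-bin-width quantization.

    ``levels`` holds integer levels in ``[1, n_levels]`` at in-mask voxels and
    0 elsewhere; bins have width ``bin_width`` with edges anchored at integer
    multiples of the width (so the bin grid is the same for every ROI).
    """

    levels: np.ndarray
    n_levels: int
    bin_width: float
    mask: RegionMask
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        inm = self.mask.values
        if self.levels.shape != inm.shape:
            raise ValueError("levels grid must match the mask grid")
        lv = self.levels[inm]
        if lv.size and (lv.min() < 1 or lv.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in [1, n_levels]")


@dataclass
class ClinicalRecord:
    """Per-lesion clinical covariates recorded at treatment planning."""

    histology: str
    total_dose: float
    n_brain_mets: int
    location: str  # "supratentorium" | "infratentorium"
    max_diameter: float  # cm
    prev_wbrt: bool
    prev_srs_srt: bool
    targeted_systemic: bool

    def __post_init__(self) -> None:
        if self.max_diameter <= 0:
            raise ValueError("max_diameter must be positive")
        if self.n_brain_mets < 1:
            raise ValueError("n_brain_mets must be >= 1")

    def as_dict(self) -> dict:
        return {
            "histology": self.histology,
            "total_dose": self.total_dose,
            "n_brain_mets": self.n_brain_mets,
            "location": self.location,
            "max_diameter": self.max_diameter,
            "prev_wbrt": self.prev_wbrt,
            "prev_srs_srt": self.prev_srs_srt,
            "targeted_systemic": self.targeted_systemic,
        }


CLINICAL_FIELDS = (
    "histology",
    "total_dose",
    "n_brain_mets",
    "location",
    "max_diameter",
    "prev_wbrt",
    "prev_srs_srt",
    "targeted_systemic",
)


@dataclass
class LesionSample:
    """One lesion: co-registered image pair, masks, outcome and survival."""

    patient_id: str
    lesion_id: str
    image_t1: VolumetricImage
    image_flair: VolumetricImage
    tumour_mask: RegionMask
    edema_mask: RegionMask
    brain_mask: RegionMask
    outcome: str  # "LC" | "LF"
    clinical: ClinicalRecord
    survival_time: float  # months, patient-level
    survival_event: bool
    # FLAIR-grid copies of the masks (the two modalities live on different
    # native grids until resampling).
    tumour_mask_flair: RegionMask | None = None
    edema_mask_flair: RegionMask | None = None
    brain_mask_flair: RegionMask | None = None

    def __post_init__(self) -> None:
        if self.outcome not in ("LC", "LF"):
            raise ValueError("outcome must be 'LC' or 'LF'")
        for m, name in ((self.tumour_mask, "tumour"), (self.edema_mask, "edema"), (self.brain_mask, "brain")):
            if m.is_empty():
                raise ValueError(f"{name} mask is empty")
        if np.any(self.tumour_mask.values & ~self.brain_mask.values):
            raise ValueError("tumour mask extends outside the brain")
        if np.any(self.edema_mask.values & ~self.brain_mask.values):
            raise ValueError("edema mask extends outside the brain")


class FeatureTable:
    """Lesions x named features, with patient ids and LC/LF labels.

    A thin wrapper over a :class:`pandas.DataFrame` whose index is
    ``(patient_id, lesion_id)`` and whose columns are feature ids.
    """

    def __init__(self, values: pd.DataFrame, outcome: pd.Series):
        if not values.index.equals(outcome.index):
            raise ValueError("feature rows and outcome labels must share an index")
        bad = set(outcome.unique()) - {"LC", "LF"}
        if bad:
            raise ValueError(f"unknown outcome labels: {bad}")
        self.values = values
        self.outcome = outcome

    @classmethod
    def from_records(
        cls,
        feature_maps: Sequence[Mapping[str, float]],
        patient_ids: Sequence[str],
        lesion_ids: Sequence[str],
        outcomes: Sequence[str],
    ) -> "FeatureTable":
        idx = pd.MultiIndex.from_arrays([list(patient_ids), list(lesion_ids)], names=["patient_id", "lesion_id"])
        df = pd.DataFrame(list(feature_maps), index=idx)
        return cls(df, pd.Series(list(outcomes), index=idx, name="outcome"))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.values.index.get_level_values("patient_id").to_numpy()

    @property
    def lesion_ids(self) -> np.ndarray:
        return self.values.index.get_level_values("lesion_id").to_numpy()

    @property
    def labels(self) -> np.ndarray:
        """Binary labels with LF (local failure) as the positive class."""
        return (self.outcome.to_numpy() == "LF").astype(np.int64)

    def __len__(self) -> int:
        return len(self.values)

    def subset_rows(self, indices: Iterable[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(self.values.iloc[idx], self.outcome.iloc[idx])

    def subset_columns(self, feature_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.values[list(feature_ids)], self.outcome)

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        df = self.values.copy()
        df.insert(0, "outcome", self.outcome)
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            df.to_csv(fh, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, comment="#", index_col=[0, 1])
        outcome = df.pop("outcome")
        return cls(df, outcome)
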
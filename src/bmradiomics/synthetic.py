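"""Synthetic brain-metastasis MRI cohort generator.

Emulates the structure of a hypo-fractionated SRT study cohort: per patient,
one or more lesions, each rendered as a pair of co-registered volumes
(CE-T1w-like at 0.5 x 0.5 x 1.5 mm, T2-FLAIR-like at 0.5 x 0.5 x 5 mm) with
analytic tumour / edema / brain masks, clinical covariates drawn from
realistic marginal frequencies, an LC/LF lesion outcome, and patient-level
survival calibrated to distinct LC / LF medians.

Each lesion's field of view is a cube centred on the lesion inside a fixed
ellipsoidal brain phantom (no skull is rendered).  Tumour and edema regions
are filled with stationary correlated Gaussian random fields whose
correlation length, variance and mean offset depend on the lesion's outcome
class, so that a planted texture difference exists for the downstream
pipeline to find.  Tumour elongation is likewise class-dependent.

Randomness is forked from one root seed per cohort by (patient, lesion)
index, so any lesion can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .core import (
    CLINICAL_FIELDS,
    DOSE_LEVELS_GY,
    HISTOLOGIES,
    ClinicalRecord,
    LesionSample,
    RegionMask,
    VolumetricImage,
)

__all__ = ["SyntheticParams", "TextureEffect", "generate_cohort", "synth_survival", "write_cohort", "load_cohort"]


@dataclass
class TextureEffect:
    """Class-conditional texture parameters of the lesion random fields.

    corr_mm: spatial correlation length (Gaussian kernel sd, mm);
    field_sd: standard deviation of the correlated field (intensity units);
    tumour_shift / edema_shift: mean intensity offsets over background.
    """

    corr_mm: float
    field_sd: float
    tumour_shift: float
    edema_shift: float


# Table-1-style marginal frequencies used for the clinical covariates.
_HISTOLOGY_P = (0.50, 0.24, 0.09, 0.05, 0.05, 0.07)
_NBM_P = (0.35, 0.34, 0.31)  # patients with 1 / 2 / >=3 brain metastases
_DOSE_P = (0.01, 0.17, 0.05, 0.60, 0.08, 0.09)
_P_SUPRA = 0.75
_P_WBRT = 0.36
_P_SRS = 0.01
_P_TARGETED = 0.32

#: Brain phantom semi-axes (mm): a fixed ~120 x 150 x 100 mm ellipsoid.
BRAIN_SEMI_AXES = (60.0, 75.0, 50.0)

#: Administrative follow-up horizon (months) for uniform censoring times.
FOLLOWUP_HORIZON_MONTHS = 72.0


@dataclass
class SyntheticParams:
    """Cohort-level generator settings (defaults are the study conditions)."""

    n_patients: int = 120
    #: probabilities of 1 / 2 / >=3 rendered target lesions per patient;
    #: the default reproduces a ~170-lesion cohort from 120 patients
    #: (two thirds of patients with a single target lesion).  The per-patient
    #: count of ALL brain metastases (the NBM clinical covariate) is drawn
    #: separately and can exceed the rendered target count.
    lesion_count_mixture: tuple[float, float, float] = (0.68, 0.18, 0.14)
    lf_prevalence: float = 0.37
    texture_effect: dict = field(
        default_factory=lambda: {
            "LC": TextureEffect(corr_mm=1.0, field_sd=10.0, tumour_shift=30.0, edema_shift=20.0),
            "LF": TextureEffect(corr_mm=2.0, field_sd=18.0, tumour_shift=45.0, edema_shift=32.0),
        }
    )
    elongation_effect: dict = field(
        default_factory=lambda: {"LC": (0.85, 0.07), "LF": (0.55, 0.10)}
    )
    noise_sd: float = 4.0
    spacing_t1: tuple[float, float, float] = (0.5, 0.5, 1.5)
    spacing_flair: tuple[float, float, float] = (0.5, 0.5, 5.0)
    survival_median_lc: float = 26.2
    survival_median_lf: float = 13.5
    censor_rate: float = 0.2
    seed: int = 0
    #: edge length (mm) of the cubic per-lesion field of view
    patch_mm: float = 64.0
    #: tumour diameter distribution (lognormal of the diameter in mm)
    diameter_log_mean: float = math.log(18.0)
    diameter_log_sd: float = 0.35
    diameter_range_mm: tuple[float, float] = (6.0, 30.0)
    #: optional log-odds bump linking previous WBRT to LF (keeps the
    #: marginal LF prevalence fixed by adjusting the intercept)
    wbrt_lf_log_odds: float = 1.0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        mix = tuple(float(p) for p in self.lesion_count_mixture)
        if any(p < 0 or p > 1 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("lesion_count_mixture must be probabilities summing to 1")
        self.lesion_count_mixture = mix
        if not (0.0 <= self.lf_prevalence <= 1.0):
            raise ValueError("lf_prevalence must be in [0, 1]")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must be in [0, 1]")
        for sp in (self.spacing_t1, self.spacing_flair):
            if any(s <= 0 for s in sp):
                raise ValueError("spacing triples must be strictly positive")
        if self.survival_median_lc <= 0 or self.survival_median_lf <= 0:
            raise ValueError("survival medians must be strictly positive")


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def synth_survival(outcome: str, params: SyntheticParams, rng: np.random.Generator) -> tuple[float, bool]:
    """Draw one (time, event) pair from the class-conditional survival model.

    Event times are exponential with the class median; with probability
    ``censor_rate`` an independent uniform censoring time on the follow-up
    horizon truncates the observation.
    """
    if outcome not in ("LC", "LF"):
        raise ValueError("outcome must be 'LC' or 'LF'")
    median = params.survival_median_lc if outcome == "LC" else params.survival_median_lf
    t = rng.exponential(median / math.log(2.0))
    if rng.random() < params.censor_rate:
        c = rng.uniform(0.0, FOLLOWUP_HORIZON_MONTHS)
        return (min(t, c), bool(t <= c))
    return (t, True)


# ---------------------------------------------------------------------------
# outcome model with optional clinical link
# ---------------------------------------------------------------------------


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _lf_intercept(params: SyntheticParams) -> float:
    """Intercept keeping the marginal LF prevalence at ``lf_prevalence``
    despite the WBRT log-odds bump."""
    bump = params.wbrt_lf_log_odds
    target = params.lf_prevalence
    if bump == 0.0 or target in (0.0, 1.0):
        return _logit(min(max(target, 1e-9), 1 - 1e-9)) if 0 < target < 1 else (math.inf if target == 1 else -math.inf)

    def marginal(b0: float) -> float:
        return (1 - _P_WBRT) * _sigmoid(b0) + _P_WBRT * _sigmoid(b0 + bump) - target

    return brentq(marginal, -20.0, 20.0)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------


def _correlated_field(shape, spacing, corr_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary correlated field: white noise smoothed with an isotropic
    (in mm) Gaussian kernel of sd ``corr_mm``, rescaled to unit variance."""
    w = rng.standard_normal(shape)
    sigma_vox = [corr_mm / s for s in spacing]
    f = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _ellipsoid_mask(grid_coords, centre, semi_axes, rotation) -> np.ndarray:
    """Voxel centres inside a rotated ellipsoid.  ``grid_coords`` is a
    (3, nx, ny, nz) array of physical coordinates."""
    rel = grid_coords - np.asarray(centre)[:, None, None, None]
    local = np.einsum("ab,bxyz->axyz", rotation.T, rel)
    q = sum((local[a] / semi_axes[a]) ** 2 for a in range(3))
    return q <= 1.0


def _render_modality(
    spacing,
    patch_origin,
    patch_mm,
    brain_centre,
    tumour_centre,
    tumour_axes,
    edema_axes,
    rotation,
    eff: TextureEffect,
    modality: str,
    noise_sd: float,
    rng: np.random.Generator,
):
    shape = tuple(int(math.ceil(patch_mm / s)) for s in spacing)
    axes_coords = [patch_origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    grid = np.stack(np.meshgrid(*axes_coords, indexing="ij"))

    rel = grid - np.asarray(brain_centre)[:, None, None, None]
    brain = sum((rel[a] / BRAIN_SEMI_AXES[a]) ** 2 for a in range(3)) <= 1.0
    outer = _ellipsoid_mask(grid, tumour_centre, edema_axes, rotation)
    tumour = _ellipsoid_mask(grid, tumour_centre, tumour_axes, rotation)
    edema = outer & ~tumour
    brain = brain | outer  # geometric safety: lesion always inside the brain

    # modality-dependent visibility of the mean offsets: contrast enhancement
    # dominates on CE-T1w in the tumour, edema is conspicuous on T2-FLAIR
    if modality == "CE-T1w":
        t_shift, e_shift = eff.tumour_shift, 0.3 * eff.edema_shift
    else:
        t_shift, e_shift = 0.6 * eff.tumour_shift, eff.edema_shift

    # background heterogeneity dominates the brain-window statistics so that
    # per-lesion normalization is not driven by the lesion's own field (the
    # rendered patch emulates a whole-brain normalization window)
    background = 100.0 + 12.0 * _correlated_field(shape, spacing, 15.0, rng)
    lesion_field = _correlated_field(shape, spacing, eff.corr_mm, rng) * eff.field_sd
    vals = np.where(brain, background, 0.0)
    vals = vals + tumour * (t_shift + lesion_field * 1.0) + edema * (e_shift + lesion_field * 0.7)
    vals = vals + noise_sd * rng.standard_normal(shape)

    img = VolumetricImage(vals, spacing, tuple(patch_origin), modality)
    return (
        img,
        RegionMask(tumour, "tumour", spacing, tuple(patch_origin)),
        RegionMask(edema, "edema", spacing, tuple(patch_origin)),
        RegionMask(brain, "brain", spacing, tuple(patch_origin)),
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _draw_clinical(rng: np.random.Generator, n_lesions: int, diameter_cm: float) -> ClinicalRecord:
    return ClinicalRecord(
        histology=HISTOLOGIES[rng.choice(len(HISTOLOGIES), p=_HISTOLOGY_P)],
        total_dose=float(DOSE_LEVELS_GY[rng.choice(len(DOSE_LEVELS_GY), p=_DOSE_P)]),
        n_brain_mets=n_lesions,
        location="supratentorium" if rng.random() < _P_SUPRA else "infratentorium",
        max_diameter=diameter_cm,
        prev_wbrt=bool(rng.random() < _P_WBRT),
        prev_srs_srt=bool(rng.random() < _P_SRS),
        targeted_systemic=bool(rng.random() < _P_TARGETED),
    )


def generate_cohort(params: SyntheticParams) -> tuple[list[LesionSample], pd.DataFrame]:
    """Generate a fully labelled synthetic cohort.

    Returns the lesion samples and a manifest with one row per lesion
    (ids, outcome, patient survival and the eight clinical fields).
    Deterministic given ``params.seed``.
    """
    lesions: list[LesionSample] = []
    rows: list[dict] = []
    intercept = _lf_intercept(params)
    counts = np.array([1, 2, 3])

    for pi in range(params.n_patients):
        prng = np.random.default_rng(np.random.SeedSequence((params.seed, 1, pi)))
        n_lesions = int(counts[prng.choice(3, p=params.lesion_count_mixture)])
        # NBM (all brain metastases) is at least the rendered target count
        n_brain_mets = max(int(counts[prng.choice(3, p=_NBM_P)]), n_lesions)
        prev_wbrt = bool(prng.random() < _P_WBRT)
        p_lf = _sigmoid(intercept + params.wbrt_lf_log_odds * prev_wbrt) if params.wbrt_lf_log_odds else params.lf_prevalence

        lesion_info = []
        for li in range(n_lesions):
            lrng = np.random.default_rng(np.random.SeedSequence((params.seed, 2, pi, li)))
            outcome = "LF" if lrng.random() < p_lf else "LC"
            lesion_info.append((li, outcome, lrng))

        # patient cohort (any-LF lesion) governs the survival draw
        patient_class = "LF" if any(o == "LF" for _, o, _ in lesion_info) else "LC"
        surv_time, surv_event = synth_survival(patient_class, params, prng)

        for li, outcome, lrng in lesion_info:
            diam_mm = float(
                np.clip(
                    math.exp(lrng.normal(params.diameter_log_mean, params.diameter_log_sd)),
                    *params.diameter_range_mm,
                )
            )
            mean_ratio, ratio_sd = params.elongation_effect[outcome]
            r1 = float(np.clip(lrng.normal(mean_ratio, ratio_sd), 0.2, 1.0))
            r2 = float(np.clip(lrng.normal(mean_ratio, ratio_sd), 0.2, r1))
            a = diam_mm / 2.0
            # floor of 2.8 mm per semi-axis keeps the tumour visible on the
            # coarse (5 mm slice) FLAIR grid
            tumour_axes = (a, max(a * r1, 2.8), max(a * r2, 2.8))
            edema_pad = float(lrng.uniform(3.0, 8.0))
            edema_axes = tuple(ax + edema_pad for ax in tumour_axes)
            rotation = _random_rotation(lrng)

            # lesion centre well inside the brain phantom
            while True:
                u = lrng.uniform(-1.0, 1.0, size=3)
                if (u**2).sum() <= 1.0:
                    break
            brain_centre = np.array(BRAIN_SEMI_AXES)
            centre = brain_centre + 0.5 * u * np.array(BRAIN_SEMI_AXES)
            patch_origin = centre - params.patch_mm / 2.0

            eff = params.texture_effect[outcome]
            img_t1, tum_t1, ede_t1, brain_t1 = _render_modality(
                params.spacing_t1, patch_origin, params.patch_mm, brain_centre,
                centre, tumour_axes, edema_axes, rotation, eff, "CE-T1w", params.noise_sd, lrng,
            )
            img_fl, tum_fl, ede_fl, brain_fl = _render_modality(
                params.spacing_flair, patch_origin, params.patch_mm, brain_centre,
                centre, tumour_axes, edema_axes, rotation, eff, "T2-FLAIR", params.noise_sd, lrng,
            )
            clinical = _draw_clinical(lrng, n_brain_mets, diam_mm / 10.0)
            clinical.prev_wbrt = prev_wbrt  # patient-level covariate

            pid = f"P{pi:04d}"
            lid = f"P{pi:04d}_L{li}"
            lesions.append(
                LesionSample(
                    patient_id=pid,
                    lesion_id=lid,
                    image_t1=img_t1,
                    image_flair=img_fl,
                    tumour_mask=tum_t1,
                    edema_mask=ede_t1,
                    brain_mask=brain_t1,
                    outcome=outcome,
                    clinical=clinical,
                    survival_time=surv_time,
                    survival_event=surv_event,
                    tumour_mask_flair=tum_fl,
                    edema_mask_flair=ede_fl,
                    brain_mask_flair=brain_fl,
                )
            )
            rows.append(
                {
                    "patient_id": pid,
                    "lesion_id": lid,
                    "outcome": outcome,
                    "survival_time": surv_time,
                    "survival_event": surv_event,
                    **clinical.as_dict(),
                }
            )

    cols = ["patient_id", "lesion_id", "outcome", "survival_time", "survival_event", *CLINICAL_FIELDS]
    manifest = pd.DataFrame(rows, columns=cols)
    return lesions, manifest


# ---------------------------------------------------------------------------
# cohort IO
# ---------------------------------------------------------------------------


def write_cohort(lesions: list[LesionSample], manifest: pd.DataFrame, out_dir) -> pd.DataFrame:
    """Write per-lesion NIfTI volumes/masks and ``manifest.csv``; returns the
    manifest augmented with file paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    path_cols = {c: [] for c in ("t1", "flair", "tumour_t1", "edema_t1", "brain_t1", "tumour_flair", "edema_flair", "brain_flair")}
    for les in lesions:
        stem = les.lesion_id
        files = {
            "t1": (les.image_t1, f"{stem}_t1.nii.gz"),
            "flair": (les.image_flair, f"{stem}_flair.nii.gz"),
            "tumour_t1": (les.tumour_mask, f"{stem}_tumour_t1.nii.gz"),
            "edema_t1": (les.edema_mask, f"{stem}_edema_t1.nii.gz"),
            "brain_t1": (les.brain_mask, f"{stem}_brain_t1.nii.gz"),
            "tumour_flair": (les.tumour_mask_flair, f"{stem}_tumour_flair.nii.gz"),
            "edema_flair": (les.edema_mask_flair, f"{stem}_edema_flair.nii.gz"),
            "brain_flair": (les.brain_mask_flair, f"{stem}_brain_flair.nii.gz"),
        }
        for col, (obj, name) in files.items():
            obj.save(out / name)
            path_cols[col].append(name)
    for col, paths in path_cols.items():
        manifest[f"path_{col}"] = paths
    manifest.to_csv(out / "manifest.csv", index=False, lineterminator="\n")
    return manifest


def load_cohort(cohort_dir) -> tuple[list[LesionSample], pd.DataFrame]:
    """Load a cohort previously written by :func:`write_cohort`."""
    from pathlib import Path

    d = Path(cohort_dir)
    manifest = pd.read_csv(d / "manifest.csv")
    lesions = []
    for _, row in manifest.iterrows():
        clinical = ClinicalRecord(
            histology=row["histology"],
            total_dose=float(row["total_dose"]),
            n_brain_mets=int(row["n_brain_mets"]),
            location=row["location"],
            max_diameter=float(row["max_diameter"]),
            prev_wbrt=bool(row["prev_wbrt"]),
            prev_srs_srt=bool(row["prev_srs_srt"]),
            targeted_systemic=bool(row["targeted_systemic"]),
        )
        lesions.append(
            LesionSample(
                patient_id=row["patient_id"],
                lesion_id=row["lesion_id"],
                image_t1=VolumetricImage.load(d / row["path_t1"], "CE-T1w"),
                image_flair=VolumetricImage.load(d / row["path_flair"], "T2-FLAIR"),
                tumour_mask=RegionMask.load(d / row["path_tumour_t1"], "tumour"),
                edema_mask=RegionMask.load(d / row["path_edema_t1"], "edema"),
                brain_mask=RegionMask.load(d / row["path_brain_t1"], "brain"),
                outcome=row["outcome"],
                clinical=clinical,
                survival_time=float(row["survival_time"]),
                survival_event=bool(row["survival_event"]),
                tumour_mask_flair=RegionMask.load(d / row["path_tumour_flair"], "tumour"),
                edema_mask_flair=RegionMask.load(d / row["path_edema_flair"], "edema"),
                brain_mask_flair=RegionMask.load(d / row["path_brain_flair"], "brain"),
            )
        )
    return lesions, manifest
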
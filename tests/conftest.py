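"""Shared fixtures: small synthetic cohorts and helper constructors."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bmradiomics.core import FeatureTable, RegionMask, VolumetricImage
from bmradiomics.preprocess import quantize_roi
from bmradiomics.synthetic import SyntheticParams, generate_cohort


def small_params(**overrides) -> SyntheticParams:
    """Desk-scale generator settings: small field of view and lesions so a
    cohort renders in seconds; everything else at study defaults."""
    defaults = dict(
        patch_mm=36.0,
        diameter_log_mean=np.log(11.0),
        diameter_range_mm=(6.0, 16.0),
    )
    defaults.update(overrides)
    return SyntheticParams(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Nine-ish lesions with images, used by preprocessing/extraction tests."""
    params = small_params(n_patients=4, seed=11)
    lesions, manifest = generate_cohort(params)
    return lesions, manifest


def make_image(values, spacing=(1.0, 1.0, 1.0), modality="CE-T1w"):
    return VolumetricImage(np.asarray(values, dtype=float), spacing, (0.0, 0.0, 0.0), modality)


def make_mask(values, kind="tumour", spacing=(1.0, 1.0, 1.0)):
    return RegionMask(np.asarray(values, dtype=bool), kind, spacing, (0.0, 0.0, 0.0))


def qroi_from_levels(levels: np.ndarray, bin_width: float = 1.0):
    """Build a QuantizedROI whose levels equal the given integer grid
    (0 = outside the mask), via an image with intensity = level * width."""
    levels = np.asarray(levels, dtype=np.int64)
    mask = make_mask(levels > 0)
    img = make_image(levels.astype(float) * bin_width)
    q = quantize_roi(img, mask, bin_width)
    assert np.array_equal(q.levels[mask.values], levels[levels > 0])
    return q


def make_feature_table(x: np.ndarray, labels, patient_ids=None, columns=None) -> FeatureTable:
    n = len(labels)
    if patient_ids is None:
        patient_ids = [f"P{i:03d}" for i in range(n)]
    lesion_ids = [f"{p}_L{i}" for i, p in enumerate(patient_ids)]
    if columns is None:
        columns = [f"f{j:02d}" for j in range(x.shape[1])]
    idx = pd.MultiIndex.from_arrays([patient_ids, lesion_ids], names=["patient_id", "lesion_id"])
    df = pd.DataFrame(np.asarray(x, dtype=float), index=idx, columns=columns)
    return FeatureTable(df, pd.Series(list(labels), index=idx, name="outcome"))


def planted_table(n_patients, seed, n_noise=60, sep=1.5, lf_prev=0.35, planted=2) -> FeatureTable:
    """Feature table with class-shifted planted features among N(0,1) noise;
    patients carry 1-2 lesions so patient-level CV is exercised."""
    rng = np.random.default_rng(seed)
    pids, lids, ys = [], [], []
    for p in range(n_patients):
        n_les = int(rng.choice([1, 2], p=[0.6, 0.4]))
        for li in range(n_les):
            pids.append(f"P{p:03d}")
            lids.append(f"P{p:03d}_L{li}")
            ys.append("LF" if rng.random() < lf_prev else "LC")
    n = len(ys)
    y = (np.array(ys) == "LF").astype(int)
    x = rng.standard_normal((n, n_noise + planted))
    for j in range(planted):
        x[:, j] += sep * y
    cols = [f"planted_{chr(97 + j)}" for j in range(planted)] + [f"noise_{i:02d}" for i in range(n_noise)]
    idx = pd.MultiIndex.from_arrays([pids, lids], names=["patient_id", "lesion_id"])
    df = pd.DataFrame(x, index=idx, columns=cols)
    return FeatureTable(df, pd.Series(ys, index=idx, name="outcome"))
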
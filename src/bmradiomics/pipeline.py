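"""End-to-end workflow: manifest handling, clinical encoding, the stratified
patient-level train/test split, stage orchestration and artifact output.

All randomness flows from one root seed through named sub-streams (split /
subsets / synthetic) so a full run is reproducible; every artifact file is
hashed into ``hashes.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CLINICAL_FIELDS, HISTOLOGIES, ClinicalRecord, FeatureTable
from .features import FeatureConfig, extract_lesion_features, feature_ids_for_config
from .model import classification_metrics, fit_knn_ensemble, predict
from .preprocess import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_INTENSITY_SCALE,
    DEFAULT_MARGIN_MM,
    DEFAULT_TARGET_MM,
    preprocess_lesion,
)
from .selection import (
    SelectionConfig,
    make_balanced_subsets,
    select_features,
)
from .survival import SurvivalRecord, assign_patient_cohorts, compare_cohorts

logger = logging.getLogger("bmradiomics")

__all__ = [
    "PipelineConfig",
    "split_train_test",
    "encode_clinical",
    "build_feature_table",
    "run_pipeline",
]

FEATURE_SET_MODES = (
    "radiomic",
    "clinical",
    "radiomic+clinical-subsets",
    "clinical+radiomic-subsets",
)


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run."""

    target_spacing: float = DEFAULT_TARGET_MM
    margin_distance: float = DEFAULT_MARGIN_MM
    bin_width: float = DEFAULT_BIN_WIDTH
    intensity_scale: float = DEFAULT_INTENSITY_SCALE
    k_neighbors: int = 5
    train_fraction: float = 100.0 / 120.0
    feature_set_mode: str = "radiomic"
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set_mode not in FEATURE_SET_MODES:
            raise ValueError(f"feature_set_mode must be one of {FEATURE_SET_MODES}")
        if isinstance(self.selection, dict):
            self.selection = SelectionConfig(**self.selection)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------


def _lesion_count_bucket(n: int) -> int:
    return min(int(n), 3)


def split_train_test(
    manifest: pd.DataFrame, train_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level stratified random split of the cohort manifest.

    Strata are (patient-level any-LF outcome) x (lesion-count bucket 1/2/3+);
    within each stratum the train share matches ``train_fraction`` up to
    rounding.  A single-patient stratum goes to training with a warning.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 301)))
    per_patient = manifest.groupby("patient_id").agg(
        any_lf=("outcome", lambda s: int((s == "LF").any())),
        n_lesions=("lesion_id", "count"),
    )
    per_patient["bucket"] = per_patient["n_lesions"].map(_lesion_count_bucket)

    strata: list[np.ndarray] = []
    singletons: list[str] = []
    for (_, _), grp in sorted(per_patient.groupby(["any_lf", "bucket"]), key=lambda kv: kv[0]):
        patients = np.array(sorted(grp.index))
        if len(patients) == 1:
            warnings.warn(f"stratum with a single patient ({patients[0]}): assigned to training", stacklevel=2)
            singletons.append(patients[0])
        else:
            strata.append(patients)

    # largest-remainder allocation: per-stratum shares match train_fraction
    # within rounding while the global train count is hit exactly
    n_total = sum(len(s) for s in strata)
    target_train = int(round(n_total * train_fraction))
    quotas = [len(s) * train_fraction for s in strata]
    n_train_per = [min(max(int(np.floor(q)), 1), len(s) - 1) for q, s in zip(quotas, strata)]
    remainders = sorted(
        range(len(strata)), key=lambda i: (quotas[i] - np.floor(quotas[i])), reverse=True
    )
    while sum(n_train_per) < target_train:
        bumped = False
        for i in remainders:
            if sum(n_train_per) >= target_train:
                break
            if n_train_per[i] < len(strata[i]) - 1:
                n_train_per[i] += 1
                bumped = True
        if not bumped:  # every stratum at its cap
            break

    train_patients: list[str] = list(singletons)
    test_patients: list[str] = []
    for patients, n_train in zip(strata, n_train_per):
        perm = rng.permutation(len(patients))
        train_patients.extend(patients[perm[:n_train]])
        test_patients.extend(patients[perm[n_train:]])
    train = manifest[manifest["patient_id"].isin(train_patients)].reset_index(drop=True)
    test = manifest[manifest["patient_id"].isin(test_patients)].reset_index(drop=True)
    assert not set(train["patient_id"]) & set(test["patient_id"])
    return train, test


# ---------------------------------------------------------------------------
# clinical encoding
# ---------------------------------------------------------------------------


def encode_clinical(record: ClinicalRecord | dict, audit: list | None = None) -> dict[str, float]:
    """Numeric encoding of the eight clinical variables (ids prefixed clin|).

    Binaries map to {0, 1}; location to 1 for supratentorium; histology is
    one-hot over the standard categories with unknown values mapped to
    "other" (audited).
    """
    rec = record.as_dict() if isinstance(record, ClinicalRecord) else dict(record)
    hist = str(rec["histology"]).lower()
    if hist not in HISTOLOGIES:
        if audit is not None:
            audit.append(f"unknown histology {hist!r} mapped to 'other'")
        hist = "other"
    out: dict[str, float] = {
        "clin|TD": float(rec["total_dose"]),
        "clin|NBM": float(rec["n_brain_mets"]),
        "clin|max_diam": float(rec["max_diameter"]),
        "clin|location": 1.0 if rec["location"] == "supratentorium" else 0.0,
        "clin|prev_wbrt": 1.0 if rec["prev_wbrt"] else 0.0,
        "clin|prev_srs_srt": 1.0 if rec["prev_srs_srt"] else 0.0,
        "clin|targeted_systemic": 1.0 if rec["targeted_systemic"] else 0.0,
    }
    for h in HISTOLOGIES:
        out[f"clin|histology_{h}"] = 1.0 if hist == h else 0.0
    return out


def clinical_feature_table(manifest: pd.DataFrame) -> FeatureTable:
    """Encode the manifest's clinical columns into a FeatureTable."""
    audit: list = []
    maps = [encode_clinical({k: row[k] for k in CLINICAL_FIELDS}, audit) for _, row in manifest.iterrows()]
    return FeatureTable.from_records(
        maps, manifest["patient_id"], manifest["lesion_id"], manifest["outcome"]
    )


# ---------------------------------------------------------------------------
# feature extraction over a cohort
# ---------------------------------------------------------------------------


def build_feature_table(
    lesions,
    config: PipelineConfig | None = None,
    include_clinical: bool = False,
) -> tuple[FeatureTable, list[str]]:
    """Preprocess and extract the radiomic panel for every lesion."""
    config = config or PipelineConfig()
    fconf = FeatureConfig(bin_width=config.bin_width)
    maps, pids, lids, outcomes = [], [], [], []
    issues_all: list[str] = []
    for les in lesions:
        prep = preprocess_lesion(
            les,
            target=config.target_spacing,
            margin=config.margin_distance,
            intensity_scale=config.intensity_scale,
        )
        fmap, issues = extract_lesion_features(prep, fconf)
        if issues:
            issues_all.extend(f"{les.lesion_id}: {msg}" for msg in issues)
        if include_clinical:
            fmap = {**fmap, **encode_clinical(les.clinical)}
        maps.append(fmap)
        pids.append(les.patient_id)
        lids.append(les.lesion_id)
        outcomes.append(les.outcome)
        logger.debug("extracted %d features for %s", len(fmap), les.lesion_id)
    table = FeatureTable.from_records(maps, pids, lids, outcomes)
    return table, issues_all


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_json(path: Path, data) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(data), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def serialize_ensemble(ensemble, path: Path) -> None:
    bundle = {
        "format_version": 1,
        "k": ensemble.k,
        "feature_ids": ensemble.feature_ids,
        "models": [
            {"x": m["x"].tolist(), "y": m["y"].tolist(), "mu": m["mu"].tolist(), "sd": m["sd"].tolist()}
            for m in ensemble.models
        ],
    }
    _write_json(path, bundle)


def load_ensemble(path: Path):
    from .model import KnnEnsemble

    with open(path) as fh:
        bundle = json.load(fh)
    ens = KnnEnsemble(feature_ids=bundle["feature_ids"], k=bundle["k"])
    for m in bundle["models"]:
        ens.models.append(
            {
                "x": np.asarray(m["x"], dtype=np.float64),
                "y": np.asarray(m["y"], dtype=np.int64),
                "mu": np.asarray(m["mu"], dtype=np.float64),
                "sd": np.asarray(m["sd"], dtype=np.float64),
            }
        )
    return ens


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def _survival_records(manifest: pd.DataFrame, cohorts: dict[str, str]) -> list[SurvivalRecord]:
    per_patient = manifest.drop_duplicates("patient_id").set_index("patient_id")
    recs = []
    for pid, cohort in sorted(cohorts.items()):
        row = per_patient.loc[pid]
        recs.append(
            SurvivalRecord(
                patient_id=pid,
                time=float(row["survival_time"]),
                event=bool(row["survival_event"]),
                cohort=cohort,
            )
        )
    return recs


def _survival_summary(records: list[SurvivalRecord]) -> dict:
    cmp = compare_cohorts(records)
    out = {"n_lc": cmp["n_lc"], "n_lf": cmp["n_lf"]}
    for arm in ("lc", "lf"):
        km = cmp[f"km_{arm}"]
        out[f"median_{arm}"] = None if km is None else km.median
    if "logrank" in cmp:
        out["logrank_chi_square"] = cmp["logrank"].chi_square
        out["logrank_p"] = cmp["logrank"].p_value
    return out


def run_pipeline(config: PipelineConfig, lesions, manifest: pd.DataFrame, out_dir) -> dict:
    """Execute the full analysis and write artifacts to ``out_dir``.

    Stages: preprocess + feature extraction, patient-level stratified split,
    reduction/ranking/forward selection on the training set, balanced-subset
    k-NN ensemble fit, test-set prediction and metrics, and the patient-level
    survival comparison of predicted vs label-based cohorts.  Returns a
    summary dict; artifacts and their SHA-256 hashes land in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = config.feature_set_mode
    logger.info("pipeline start: mode=%s seed=%d n_lesions=%d", mode, config.seed, len(manifest))

    sel_config = dataclasses.replace(config.selection, seed=config.seed, k_neighbors=config.k_neighbors)

    # --- features ---------------------------------------------------------
    need_radiomic = mode != "clinical"
    if need_radiomic:
        table, issues = build_feature_table(lesions, config, include_clinical=True)
    else:
        table, issues = clinical_feature_table(manifest), []
    fconf = FeatureConfig(bin_width=config.bin_width)
    n_radiomic = len(feature_ids_for_config(fconf)) if need_radiomic else 0
    header = f"config_seed={config.seed} mode={mode} n_features={len(table.feature_ids)} n_radiomic={n_radiomic}"
    table.to_csv(out / "features.csv", header_comment=header)

    # --- split ------------------------------------------------------------
    train_manifest, test_manifest = split_train_test(manifest, config.train_fraction, config.seed)
    train_ids = set(train_manifest["lesion_id"])
    test_ids = set(test_manifest["lesion_id"])
    all_lids = table.lesion_ids
    tr_rows = [i for i, lid in enumerate(all_lids) if lid in train_ids]
    te_rows = [i for i, lid in enumerate(all_lids) if lid in test_ids]
    train_tab = table.subset_rows(tr_rows)
    test_tab = table.subset_rows(te_rows)
    assert not set(train_tab.patient_ids) & set(test_tab.patient_ids), "patient leakage"

    radiomic_ids = [f for f in table.feature_ids if not f.startswith("clin|")]
    clinical_ids = [f for f in table.feature_ids if f.startswith("clin|")]

    # --- selection --------------------------------------------------------
    def run_selection(tab: FeatureTable):
        return select_features(tab, sel_config)

    results: dict = {"mode": mode, "issues": issues}
    if mode == "radiomic":
        sel = run_selection(train_tab.subset_columns(radiomic_ids))
        base_sets = [("radiomic", sel.selected)]
    elif mode == "clinical":
        sel = run_selection(train_tab.subset_columns(clinical_ids))
        base_sets = [("clinical", sel.selected)]
    elif mode == "clinical+radiomic-subsets":
        # best clinical set, then selected radiomic features added one at a time
        sel_clin = run_selection(train_tab.subset_columns(clinical_ids))
        sel_rad = run_selection(train_tab.subset_columns(radiomic_ids))
        sel = sel_clin
        base_sets = [("clinical", sel_clin.selected)]
        for step in range(1, len(sel_rad.selected) + 1):
            base_sets.append((f"clinical+{step}rad", sel_clin.selected + sel_rad.selected[:step]))
    else:  # radiomic+clinical-subsets
        sel_rad = run_selection(train_tab.subset_columns(radiomic_ids))
        sel_clin = run_selection(train_tab.subset_columns(clinical_ids))
        sel = sel_rad
        base_sets = [("radiomic", sel_rad.selected)]
        for step in range(1, len(sel_clin.selected) + 1):
            base_sets.append((f"radiomic+{step}clin", sel_rad.selected + sel_clin.selected[:step]))
    _write_json(out / "selection.json", {"selected": sel.selected, "step_scores": sel.step_scores, "audit": sel.audit})

    # --- ensemble fit / prediction per feature set ------------------------
    subsets = make_balanced_subsets(train_tab, sel_config)
    metrics_by_set = {}
    primary_pred = None
    for name, feats in base_sets:
        ens = fit_knn_ensemble(train_tab, feats, subsets, k=config.k_neighbors)
        pred = predict(ens, test_tab)
        try:
            rep = classification_metrics(pred.labels, test_tab.outcome.to_numpy(), scores=pred.vote_fraction)
            metrics_by_set[name] = rep.as_dict()
        except ValueError as exc:  # degenerate (single-class) test set
            metrics_by_set[name] = {"error": str(exc)}
        if primary_pred is None:
            primary_pred = pred
            serialize_ensemble(ens, out / "model.json")
    results["metrics"] = metrics_by_set
    _write_json(out / "metrics.json", metrics_by_set)

    pred_df = pd.DataFrame(
        {
            "patient_id": test_tab.patient_ids,
            "lesion_id": test_tab.lesion_ids,
            "outcome": test_tab.outcome.to_numpy(),
            "vote_fraction": primary_pred.vote_fraction,
            "predicted": primary_pred.labels,
        }
    )
    pred_df.to_csv(out / "predictions.csv", index=False, lineterminator="\n")

    # --- survival ---------------------------------------------------------
    pred_pairs = list(zip(pred_df["patient_id"], pred_df["predicted"]))
    true_pairs = list(zip(pred_df["patient_id"], pred_df["outcome"]))
    surv = {}
    for label, pairs in (("predicted", pred_pairs), ("observed", true_pairs)):
        cohorts = assign_patient_cohorts(pairs)
        recs = _survival_records(test_manifest, cohorts)
        try:
            surv[label] = _survival_summary(recs)
        except ValueError as exc:  # e.g. single-cohort test set
            surv[label] = {"error": str(exc)}
    results["survival"] = surv
    _write_json(out / "survival.json", surv)

    # --- hashes -----------------------------------------------------------
    artifact_files = sorted(p.name for p in out.iterdir() if p.name != "hashes.json")
    hashes = {name: _sha256(out / name) for name in artifact_files}
    _write_json(out / "hashes.json", hashes)
    results["hashes"] = hashes
    results["selected"] = sel.selected
    results["n_train_lesions"] = len(train_tab)
    results["n_test_lesions"] = len(test_tab)
    logger.info("pipeline done: selected=%s", sel.selected)
    return results
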
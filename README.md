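# bmradiomics

A-priori prediction of local failure in brain metastases treated with
hypo-fractionated stereotactic radiotherapy (SRT), from treatment-planning
MRI radiomics.

About one in five brain metastases progresses locally after stereotactic
radiotherapy. Knowing *before treatment* which lesions are likely to fail
would let clinicians adapt dose or plan salvage early. This package
implements a complete, tested pipeline for that prediction task — aimed at
researchers in quantitative imaging / radiation oncology who want a
reproducible reference implementation they can run end to end without
patient data:

1. **Preprocessing** — CE-T1w and T2-FLAIR volumes (NIfTI) are resampled to
   an isotropic 0.5 mm grid, intensity-normalized to zero mean / unit
   variance within the brain, and 5 mm margin shells are built around the
   tumour and around tumour + edema.
2. **Radiomics** — 672 features per lesion: 14 morphology features (e.g.
   elongation = sqrt(λ₂/λ₁) of the ROI's PCA eigenvalues), 18 first-order
   statistics, and the GLCM / GLDM / GLSZM / NGTDM texture families with
   IBSI-consistent formulas on fixed-bin-width (25) quantized gray levels,
   for 4 regions × 2 images.
3. **Feature selection under class imbalance** — Pearson-R² redundancy
   pruning (R² > 0.8), mRMR ranking to a top-100 pool, then sequential
   forward selection scored by the mean AUC of a k-NN vote under
   patient-level stratified 5-fold cross-validation over 501 class-balanced
   undersampled subsets of the training lesions.
4. **Outcome model** — an ensemble of 501 k-NN classifiers (k = 5, one per
   balanced subset, per-model z-scoring); the final LC/LF label is the
   majority over the 501 models, and the LF vote fraction is the continuous
   score for ROC analysis.
5. **Survival** — patients with at least one locally failing lesion form
   the LF cohort; Kaplan–Meier curves and a log-rank test compare the
   cohorts defined by the *predicted* (pre-treatment) labels against those
   defined by the observed outcomes.

Because no patient data ship with the package, a first-class synthetic
cohort generator renders per-lesion MRI phantoms (anisotropic native grids,
correlated random-field textures with class-dependent heterogeneity,
class-dependent tumour elongation, realistic clinical covariates, and
exponential survival with medians 26.2 / 13.5 months for LC / LF) so every
stage of the pipeline is exercised and validated end to end. See
`docs/methods.md` for the model details and what the phantom does and does
not emulate.

## Worked example

Run the whole pipeline on a simulated cohort from the shell:

```bash
bmradiomics run-all --n-patients 16 --seed 5 --out run5
```

or from Python:

```python
from bmradiomics import SyntheticParams, generate_cohort, PipelineConfig, run_pipeline
from bmradiomics.selection import SelectionConfig

params = SyntheticParams(n_patients=16, seed=5, lf_prevalence=0.45, patch_mm=36.0)
lesions, manifest = generate_cohort(params)
cfg = PipelineConfig(selection=SelectionConfig(n_subsets=21, cv_folds=3, seed=5), seed=5)
results = run_pipeline(cfg, lesions, manifest, "run5")
print(results["selected"], results["metrics"]["radiomic"])
```

At the full study structure (120 patients, 167 lesions, 501 subsets;
`python scripts/acceptance.py --seed 1 --out results/acceptance.json`,
about 15 minutes on one CPU) the pipeline reports, among others:

```json
"n_selected_radiomic_features": {"n": 139, "value": 2},
"radiomic_test_auc":            {"n": 28,  "value": 1.0},
"radiomic_test_accuracy_pct":   {"n": 28,  "value": 100.0},
"clinical_test_auc":            {"n": 28,  "value": 0.4417},
"survival_median_lc_cohort":    {"n": 120, "value": 28.78},
"survival_median_lf_cohort":    {"n": 120, "value": 14.80},
"survival_logrank_p_cohort":    {"n": 120, "value": 6.75e-05},
"survival_logrank_p_predicted": {"n": 20,  "value": 0.00723}
```

with the selected features printed during the run
(`T1|tumour|shape|Flatness`, `T1|tumour-margin|GLCM|ClusterProminence`).

Reading these numbers: the selection stage found two features that track
the planted class differences (a tumour-shape feature and a peritumoural
texture feature); the ensemble separates the held-out lesions perfectly at
the generator's default effect sizes, while the clinical covariates alone
are near chance on the small test set. The Kaplan–Meier medians recover the
generator's calibrated 26.2 / 13.5-month LC/LF survival split, and the
pre-treatment predicted cohorts reproduce the significant survival
separation of the observed-outcome cohorts.

## Command-line interface

`simulate`, `preprocess`, `extract`, `select`, `train`, `predict`,
`evaluate`, `survival`, `run-all` — each stage reads and writes plain
CSV/JSON (NIfTI for volumes), so the pipeline can be driven stepwise or in
one shot. `--help` on any command shows its options.
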
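# Methods

## Problem and pipeline

`bmradiomics` implements an a-priori (pre-treatment) predictor of per-lesion
local failure (LF) versus local control (LC) for brain metastases treated
with hypo-fractionated stereotactic radiotherapy (SRT), built from
treatment-planning MRI. Per lesion the inputs are a contrast-enhanced
T1-weighted (CE-T1w) volume, a T2-FLAIR volume, and tumour / edema / brain
masks. The stages run in this order:

1. **Preprocessing.** Both volumes are resampled to an isotropic grid
   (default 0.5 mm; trilinear for images, nearest-neighbour for masks, the
   output extent uses `ceil` so tissue is never cropped). Intensities are
   normalized to zero mean / unit variance over brain voxels, then rescaled
   by a configurable factor (default 100). Margin shells are built by
   Euclidean distance (default 5 mm) around the tumour (tumour-margin) and
   around tumour + edema (lesion-margin), clipped to the brain and excluding
   the source region.
2. **Feature extraction.** Gray levels are quantized with a fixed bin width
   (default 25) and bin edges anchored at integer multiples of the width;
   the in-ROI minimum maps to level 1 (quantization is per ROI). The panel
   comprises 14 morphology features, 18 first-order statistics, and the
   GLCM (24), GLDM (14), GLSZM (16) and NGTDM (5) texture families with
   IBSI-consistent formulas: GLCM with distance-1 offsets over the 13 unique
   3D directions, symmetrized and summed before normalization; GLDM with
   dependence threshold alpha = 0 over the 26-neighbourhood; GLSZM zones and
   NGTDM neighbourhoods 26-connected. First-order + texture features are
   computed for 4 regions x 2 images; morphology once per region (tumour and
   tumour-margin on the CE-T1w grid, edema and lesion-margin on the T2-FLAIR
   grid), giving 4 x 2 x 77 + 4 x 14 = **672 features** per lesion under the
   default configuration. The extraction header reports the count, which is
   a deterministic function of the configuration.
3. **Feature selection.** (a) Pearson-R^2 redundancy pruning: features are
   nodes of a graph with edges where R^2 > 0.8; each connected component
   keeps the member with the highest direction-corrected univariate rank
   AUC. (b) mRMR ranking (MID criterion: relevance minus mean redundancy,
   mutual information on 4-quantile discretized features) down to a pool of
   100. (c) Sequential forward selection scored by the mean cross-validated
   AUC of a k-NN vote over 501 class-balanced undersampled subsets, with
   patient-level stratified 5-fold CV inside each subset (all lesions of a
   patient stay in one fold; folds stratified by the patient-level any-LF
   outcome).
4. **Outcome model.** One k-NN (k = 5, Euclidean, per-model z-scoring) per
   balanced subset; a test lesion's label is the majority over the 501
   models and its continuous score is the LF vote fraction. Odd counts at
   both levels make every vote decisive.
5. **Survival.** Patients with at least one LF lesion form the LF cohort;
   Kaplan-Meier curves and a two-sample log-rank test compare the LF and LC
   cohorts, once with predicted and once with observed outcomes. Estimation
   is delegated to `lifelines`; the median is reported only where the curve
   reaches 0.5, never extrapolated.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| target spacing | 0.5 mm | isotropic grid for 3D texture analysis |
| margin distance | 5 mm | expansion shell around tumour / lesion |
| bin width | 25 | fixed-width quantization (after normalization x100) |
| intensity scale | 100 | rescale after unit-variance normalization |
| R^2 threshold | 0.8 | redundancy pruning |
| mRMR pool | 100 | candidate list for forward selection |
| n subsets | 501 | balanced undersampled replicates (odd) |
| CV folds | 5 | patient-level stratified folds per subset |
| k neighbours | 5 | k-NN (odd) |
| max features / min improvement | 10 / 1e-4 | forward-selection stopping rule |

The intensity scale is needed because unit-variance intensities with a bin
width of 25 would collapse the brain into one gray level; scale 100 yields
roughly 20-40 levels in typical ROIs. The forward-selection stopping rule
(improvement threshold plus feature cap) is this package's own design, as is
the use of connected components (rather than cliques) for "sets of highly
correlated features" — chosen for determinism.

## Synthetic cohort generator

The generator emulates the structure of an SRT planning cohort so every
stage is testable without patient data:

* **Geometry.** A fixed ellipsoidal brain phantom (~120 x 150 x 100 mm,
  no skull). Each lesion is a randomly rotated ellipsoidal tumour (diameter
  lognormal, mean ≈ 18 mm, clipped to 6-30 mm, with a 2.8 mm per-semi-axis
  floor so lesions stay visible on the 5 mm FLAIR slices) inside an edema
  shell 3-8 mm thick. Axis ratios are class-dependent (LC ≈ 0.85, LF ≈ 0.55
  mean minor/major ratio), planting an elongation effect.
* **Rendering.** Per lesion a cubic field of view (default 64 mm) centred
  on the lesion is rendered on the native anisotropic grids (CE-T1w
  0.5 x 0.5 x 1.5 mm, T2-FLAIR 0.5 x 0.5 x 5 mm). Regions are filled with
  stationary correlated Gaussian fields (white noise smoothed with an
  isotropic-in-mm Gaussian kernel, rescaled to a target standard deviation):
  background sd 12 with 15 mm correlation length, lesion fields with
  class-dependent correlation length (LC 1 mm / LF 2 mm) and sd (LC 10 /
  LF 18), plus class- and modality-dependent mean offsets and additive
  Gaussian noise (sd 4). The background field deliberately dominates the
  brain-window statistics so per-lesion normalization behaves like a
  whole-brain normalization window; with a quiet background the lesion's
  own field inflates the normalization variance and can mask the planted
  texture difference.
* **Clinical covariates** are drawn independently from realistic marginal
  frequencies (histology mix, dose levels 22.5-35 Gy, location, previous
  WBRT 36%, targeted systemic treatment 32%); an optional log-odds bump
  (default +1.0) links previous WBRT to LF while an intercept correction
  keeps the marginal LF prevalence at its configured value (0.37), so
  clinical-model code paths have signal to find.
* **Survival** is a patient-level draw: the patient's class (any-LF)
  selects an exponential with median 26.2 (LC) or 13.5 (LF) months;
  censoring is independent uniform on a 72-month horizon with probability
  `censor_rate` (default 0.2).
* **Determinism.** One root seed; per-patient and per-lesion generators are
  forked by (seed, patient, lesion) index, so any lesion can be regenerated
  alone and cohorts are byte-identical across runs.

What the generator does **not** emulate: anatomy (no tissue classes, skull,
ventricles), scanner/site effects, bias fields, registration error,
correlated multi-lesion biology, or any quantitative LC/LF texture contrast
measured on real patients — the class effect sizes are free parameters of
the phantom. Passing tests therefore demonstrate that the pipeline recovers
*planted* effects of plausible magnitude, not that it would reach any
particular accuracy on clinical data.

## Numerical choices and edge cases

* Morphology: axis lengths from PCA eigenvalues of physical voxel centres
  (length = 4 sqrt(lambda)); elongation = sqrt(l2/l1) (0 = line, 1 = ball);
  a single-voxel region returns elongation = flatness = 1. Mesh volume and
  surface area come from a marching-cubes surface of the padded mask; on a
  digitized ball the staircase surface inflates the area ~10%, so
  sphericity of a voxelized sphere is ≈ 0.91, not 1. Maximum 2D diameters
  take the largest in-plane distance between boundary-voxel centres over
  slabs perpendicular to each axis.
* Quantization of a constant ROI yields a single level; GLCM features of a
  single-voxel ROI (no pairs) are defined as 0 (correlation and MCC as 1).
* Distance ties in the k-NN are broken by training-point index (stable
  sort); exact mid-rank handling in every AUC.
* Constant features form singleton components in redundancy pruning
  (undefined correlation), and are centred but not scaled by the z-scoring.
* Margins use the Euclidean distance transform with the grid spacing as
  sampling, evaluated on a padded bounding box (identical result to the
  full-grid transform).
* A CV fold whose validation split is single-class is skipped and audited;
  an entirely single-class plan raises.
* Single-patient strata in the train/test split go to training with a
  warning; the split uses largest-remainder allocation across strata so the
  global train count matches the requested fraction exactly (120 patients
  at fraction 100/120 give exactly 100/20).

## Problem sizes used by the shipped checks

The test suite exercises the pipeline on reduced phantoms (36 mm fields of
view, 6-16 mm tumours, 11-51 subsets) so the full suite runs in minutes;
the planted-feature recovery check uses feature-table cohorts of 100
training / 400 held-out patients over 20 seeds, a size at which the held-out
AUC estimate carries about ±0.01 sampling error. `scripts/acceptance.py`
runs the image pipeline end to end at the study structure (120 patients,
~170 lesions, 501 subsets) with the generator defaults above.

## Known limitations

* The per-lesion cropped field of view means "brain" statistics are local;
  with multiple lesions per patient each lesion is normalized in its own
  window.
* The 800-feature panel size sometimes quoted for comparable pipelines is
  not reconstructible from the stated families and regions; this package
  reports its own deterministic count (672 by default).
* Reported sensitivity/specificity follow the convention that sensitivity
  is the LF detection rate; sources that swap the two labels will appear
  transposed.
* mRMR uses 4-quantile discretization and the MID (difference) criterion;
  other mRMR variants (MIQ, different bin counts) would rank differently.
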
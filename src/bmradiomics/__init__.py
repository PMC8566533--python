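"""bmradiomics: a-priori prediction of local failure in brain metastases
after hypo-fractionated stereotactic radiotherapy from treatment-planning
MRI radiomics.

The package covers the full analysis chain: synthetic cohort generation,
preprocessing (isotropic resampling, brain-window normalization, margin
masks, gray-level quantization), the radiomic feature panel (morphology,
first-order, GLCM/GLDM/GLSZM/NGTDM), multi-phase feature selection under
class imbalance, a balanced-subset k-NN max-voting ensemble, and
patient-level Kaplan-Meier / log-rank survival comparison.
"""

from .core import (
    ClinicalRecord,
    FeatureTable,
    LesionSample,
    QuantizedROI,
    RegionMask,
    VolumetricImage,
)
from .features import (
    FeatureConfig,
    extract_lesion_features,
    feature_ids_for_config,
    first_order_features,
    shape_features,
    texture_features,
    texture_matrix,
)
from .model import (
    KnnEnsemble,
    MetricsReport,
    PredictionResult,
    classification_metrics,
    fit_knn_ensemble,
    predict,
    roc_auc,
)
from .pipeline import (
    PipelineConfig,
    build_feature_table,
    encode_clinical,
    run_pipeline,
    split_train_test,
)
from .preprocess import (
    build_margin_masks,
    normalize_within_brain,
    preprocess_lesion,
    quantize_roi,
    resample_to_isotropic,
)
from .selection import (
    BalancedSubset,
    SelectionConfig,
    SelectionResult,
    correlation_reduce,
    cv_feature_set_score,
    make_balanced_subsets,
    mrmr_rank,
    select_features,
    sequential_forward_select,
    univariate_auc,
)
from .survival import (
    KMCurve,
    LogRankResult,
    SurvivalRecord,
    assign_patient_cohorts,
    compare_cohorts,
    km_curve,
    logrank_test,
)
from .synthetic import (
    SyntheticParams,
    TextureEffect,
    generate_cohort,
    load_cohort,
    synth_survival,
    write_cohort,
)

__version__ = "0.1.0"
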
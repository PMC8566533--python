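"""LC/LF outcome prediction: a max-voting ensemble of k-NN models trained on
class-balanced undersampled subsets.

Each of the (odd) number of models is fitted on one balanced subset with its
own per-feature z-score standardization; a test lesion is labelled LF when
more than half the models vote LF.  With an odd model count and odd k no
vote is ever tied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

__all__ = [
    "KnnEnsemble",
    "PredictionResult",
    "MetricsReport",
    "fit_knn_ensemble",
    "predict",
    "roc_auc",
    "classification_metrics",
    "knn_vote_fractions",
    "aggregate_votes",
]


def knn_vote_fractions(train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray, k: int) -> np.ndarray:
    """Fraction of the k Euclidean nearest training points labelled positive.

    Distance ties are broken by training-point index (stable sort), making
    predictions reproducible across runs.
    """
    if k > len(train_x):
        raise ValueError(f"k={k} exceeds the number of training points ({len(train_x)})")
    d = cdist(test_x, train_x)
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    return train_y[nn].mean(axis=1)


def _standardize_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant feature: centred, not scaled
    return mu, sd


@dataclass
class KnnEnsemble:
    """Fitted balanced-subset k-NN ensemble (training data + per-model stats)."""

    feature_ids: list[str]
    k: int
    models: list[dict] = field(default_factory=list)  # {'x', 'y', 'mu', 'sd'}

    @property
    def n_models(self) -> int:
        return len(self.models)


@dataclass
class PredictionResult:
    """Per-lesion LF vote fraction and the max-voting label."""

    vote_fraction: np.ndarray
    labels: np.ndarray  # "LC"/"LF"


@dataclass
class MetricsReport:
    sensitivity: float  # percent, LF as positive class
    specificity: float
    accuracy: float
    auc: float | None
    tp: int
    tn: int
    fp: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "confusion": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
        }


def fit_knn_ensemble(table, feature_ids, subsets, k: int = 5) -> KnnEnsemble:
    """Fit one k-NN model per balanced subset.

    ``table`` is a :class:`~bmradiomics.core.FeatureTable`; ``subsets`` an
    iterable of row-index arrays (see
    :func:`bmradiomics.selection.make_balanced_subsets`).
    """
    missing = [f for f in feature_ids if f not in table.values.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    x_all = table.values[list(feature_ids)].to_numpy(dtype=np.float64)
    y_all = table.labels
    ens = KnnEnsemble(feature_ids=list(feature_ids), k=k)
    for sub in subsets:
        idx = np.asarray(getattr(sub, "indices", sub))
        x, y = x_all[idx], y_all[idx]
        if k > len(x):
            raise ValueError(f"k={k} exceeds subset size {len(x)}")
        mu, sd = _standardize_stats(x)
        ens.models.append({"x": (x - mu) / sd, "y": y, "mu": mu, "sd": sd})
    return ens


def aggregate_votes(votes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-model binary votes (n_samples x n_models) by max-voting."""
    frac = votes.mean(axis=1)
    labels = np.where(frac > 0.5, "LF", "LC")
    return frac, labels


def predict(ensemble: KnnEnsemble, vectors) -> PredictionResult:
    """Max-voting prediction for a feature table or array of lesions."""
    if hasattr(vectors, "values"):  # FeatureTable
        missing = [f for f in ensemble.feature_ids if f not in vectors.values.columns]
        if missing:
            raise KeyError(f"features missing from input: {missing}")
        x = vectors.values[ensemble.feature_ids].to_numpy(dtype=np.float64)
    else:
        x = np.asarray(vectors, dtype=np.float64)
    votes = np.empty((len(x), ensemble.n_models), dtype=np.int64)
    for mi, m in enumerate(ensemble.models):
        frac = knn_vote_fractions(m["x"], m["y"], (x - m["mu"]) / m["sd"], ensemble.k)
        votes[:, mi] = frac > 0.5  # odd k: never exactly 0.5
    frac, labels = aggregate_votes(votes)
    return PredictionResult(vote_fraction=frac, labels=labels)


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney, midrank ties) AUC with LF as positive."""
    y = np.asarray([1 if l in ("LF", 1, True) else 0 for l in labels])
    s = np.asarray(scores, dtype=np.float64)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for AUC")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def classification_metrics(predicted, truth, scores=None) -> MetricsReport:
    """Sensitivity / specificity / accuracy (percent) with LF positive."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if len(pred) != len(true):
        raise ValueError("prediction and truth lengths differ")
    p = pred == "LF"
    t = true == "LF"
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present in the truth labels")
    auc = roc_auc(scores, true) if scores is not None else None
    return MetricsReport(
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        accuracy=100.0 * (tp + tn) / len(true),
        auc=auc,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
    )
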
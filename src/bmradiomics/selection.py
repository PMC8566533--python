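"""Multi-phase feature reduction and selection under class imbalance.

The chain is: Pearson R^2 redundancy pruning (keep one representative per
connected component of the thresholded correlation graph), mRMR ranking to a
top-``pool`` candidate list, then sequential forward selection scored by the
mean patient-level stratified 5-fold cross-validated AUC of a k-NN vote over
many class-balanced undersampled subsets of the training lesions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .model import knn_vote_fractions
from .core import FeatureTable

__all__ = [
    "SelectionConfig",
    "BalancedSubset",
    "SelectionResult",
    "univariate_auc",
    "correlation_reduce",
    "mrmr_rank",
    "make_balanced_subsets",
    "make_cv_plan",
    "cv_feature_set_score",
    "sequential_forward_select",
    "select_features",
]


@dataclass
class SelectionConfig:
    r2_threshold: float = 0.8
    mrmr_pool: int = 100
    n_subsets: int = 501
    cv_folds: int = 5
    max_features: int = 10
    min_improvement: float = 1e-4
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold < 1.0):
            raise ValueError("r2_threshold must be in (0, 1)")
        if self.n_subsets % 2 == 0:
            raise ValueError("n_subsets must be odd (decisive max-voting)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class BalancedSubset:
    """Row indices of one balanced undersampled training subset."""

    indices: np.ndarray
    n_lc: int
    n_lf: int


@dataclass
class SelectionResult:
    selected: list[str]
    step_scores: list[float]
    audit: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# univariate screening
# ---------------------------------------------------------------------------


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float | None:
    """Mann-Whitney AUC with midrank tie handling (fast, allocation-light)."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return None
    _, inv, cnt = np.unique(scores, return_inverse=True, return_counts=True)
    csum = np.cumsum(cnt)
    midrank = csum - (cnt - 1) / 2.0
    r = midrank[inv]
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def univariate_auc(values, labels) -> float:
    """Direction-corrected rank AUC of a raw feature as an LF score.

    Threshold-free (Mann-Whitney with midrank ties); returns
    ``max(AUC, 1 - AUC)``, so the result lies in [0.5, 1].
    """
    y = np.asarray(labels)
    if y.dtype.kind in "US":
        y = (y == "LF").astype(np.int64)
    y = y.astype(np.int64)
    a = _rank_auc(np.asarray(values, dtype=np.float64), y)
    if a is None:
        raise ValueError("both classes must be present")
    return max(a, 1.0 - a)


# ---------------------------------------------------------------------------
# correlation-based redundancy pruning
# ---------------------------------------------------------------------------


def correlation_reduce(table: FeatureTable, config: SelectionConfig | None = None) -> tuple[FeatureTable, dict]:
    """Drop redundant features by thresholded R^2 connected components.

    Features are nodes; edges join pairs with Pearson R^2 above the
    threshold; each connected component keeps the member with the highest
    univariate AUC (ties: lexicographically smallest id).  Constant features
    have undefined correlation and form singleton components.
    """
    config = config or SelectionConfig()
    ids = table.feature_ids
    if len(ids) < 2:
        return table, {"components": [[i] for i in ids], "representatives": list(ids)}
    x = table.values.to_numpy(dtype=np.float64)
    y = table.labels

    sd = x.std(axis=0)
    variable = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r2 = np.nan_to_num(r, nan=0.0) ** 2
    adj = (r2 > config.r2_threshold) & np.outer(variable, variable)
    np.fill_diagonal(adj, False)

    # connected components by iterative flood fill
    n = len(ids)
    comp = -np.ones(n, dtype=np.int64)
    ncomp = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = ncomp
        while stack:
            v = stack.pop()
            for u in np.flatnonzero(adj[v]):
                if comp[u] < 0:
                    comp[u] = ncomp
                    stack.append(int(u))
        ncomp += 1

    components: list[list[str]] = [[] for _ in range(ncomp)]
    for fi, ci in enumerate(comp):
        components[ci].append(ids[fi])
    reps: list[str] = []
    for members in components:
        if len(members) == 1:
            reps.append(members[0])
            continue
        scored = sorted(
            members,
            key=lambda fid: (-univariate_auc(table.values[fid].to_numpy(), y), fid),
        )
        reps.append(scored[0])
    kept = [fid for fid in ids if fid in set(reps)]  # preserve column order
    audit = {"components": components, "representatives": reps, "n_in": n, "n_out": len(kept)}
    return table.subset_columns(kept), audit


# ---------------------------------------------------------------------------
# mRMR ranking (MID criterion)
# ---------------------------------------------------------------------------


def _discretize(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Equal-frequency binning; features with <= n_bins distinct values keep
    their own categories."""
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    r = rankdata(x, method="average")
    return np.minimum((n_bins * (r - 0.5) / len(x)).astype(np.int64), n_bins - 1)


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) of two discrete code vectors via the contingency table."""
    na = int(a.max()) + 1
    nb = int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(np.float64)
    n = joint.sum()
    pj = joint / n
    pa = pj.sum(axis=1, keepdims=True)
    pb = pj.sum(axis=0, keepdims=True)
    nz = pj > 0
    return float((pj[nz] * np.log(pj[nz] / (pa @ pb)[nz])).sum())


def mrmr_rank(table: FeatureTable, labels=None, pool: int | None = None, n_bins: int = 4) -> list[str]:
    """Greedy minimal-redundancy-maximal-relevance ranking (MID criterion).

    Relevance and redundancy are mutual informations of 4-quantile
    discretized features; each step adds the feature maximizing
    ``I(f; y) - mean_s I(f; s)`` over already-ranked features ``s``.
    Returns the first ``pool`` ids.
    """
    ids = table.feature_ids
    if not ids:
        raise ValueError("no features to rank")
    pool = pool if pool is not None else len(ids)
    if pool <= 0:
        raise ValueError("pool must be positive")
    y = table.labels if labels is None else np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    codes = {fid: _discretize(table.values[fid].to_numpy(dtype=np.float64), n_bins) for fid in ids}
    relevance = {fid: _mutual_information(codes[fid], y) for fid in ids}

    # ties broken by lexicographic id for determinism
    order = sorted(ids)
    selected: list[str] = []
    remaining = set(ids)
    red_sum = {fid: 0.0 for fid in ids}
    while remaining and len(selected) < min(pool, len(ids)):
        if not selected:
            best = max(order, key=lambda f: (relevance[f], ))
        else:
            k = len(selected)
            best = None
            best_score = -np.inf
            for f in order:
                if f not in remaining:
                    continue
                score = relevance[f] - red_sum[f] / k
                if score > best_score + 1e-15:
                    best, best_score = f, score
        selected.append(best)
        remaining.discard(best)
        for f in remaining:
            red_sum[f] += _mutual_information(codes[f], codes[best])
    return selected[:pool]


# ---------------------------------------------------------------------------
# balanced undersampling and the patient-level CV plan
# ---------------------------------------------------------------------------


def make_balanced_subsets(table: FeatureTable, config: SelectionConfig | None = None) -> list[BalancedSubset]:
    """Undersample the majority class into ``n_subsets`` balanced subsets.

    Each subset is the full minority class plus an equally sized draw
    without replacement from the majority class; draws differ across
    subsets via the seeded rng.
    """
    config = config or SelectionConfig()
    y = table.labels
    lf_idx = np.flatnonzero(y == 1)
    lc_idx = np.flatnonzero(y == 0)
    if len(lf_idx) == 0 or len(lc_idx) == 0:
        raise ValueError("both classes must be present")
    minority, majority = lf_idx, lc_idx
    if len(minority) > len(majority):
        warnings.warn("LF outnumbers LC; undersampling LF instead", stacklevel=2)
        minority, majority = majority, minority
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    subsets = []
    m = len(minority)
    for _ in range(config.n_subsets):
        draw = rng.choice(majority, size=m, replace=False)
        idx = np.sort(np.concatenate([minority, draw]))
        subsets.append(BalancedSubset(indices=idx, n_lc=int((y[idx] == 0).sum()), n_lf=int((y[idx] == 1).sum())))
    return subsets


def _patient_stratified_folds(
    pids: np.ndarray, y: np.ndarray, idx: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Assign the patients appearing in ``idx`` to folds, stratified by the
    patient-level (any-LF) outcome; all lesions of a patient share a fold."""
    sub_pids = pids[idx]
    sub_y = y[idx]
    patients = np.unique(sub_pids)
    p_label = np.array([int(sub_y[sub_pids == p].max()) for p in patients])
    fold_of: dict = {}
    counter = 0
    for cls in (0, 1):
        cls_pat = patients[p_label == cls]
        perm = rng.permutation(len(cls_pat))
        for j, pi in enumerate(perm):
            fold_of[cls_pat[pi]] = (counter + j) % n_folds
        counter += len(cls_pat)
    folds = []
    fold_ids = np.array([fold_of[p] for p in sub_pids])
    for f in range(n_folds):
        val = idx[fold_ids == f]
        train = idx[fold_ids != f]
        if len(val) and len(train):
            folds.append((train, val))
    return folds


@dataclass
class CVPlan:
    """Feature-independent cross-validation bookkeeping.

    Folds (and per-fold standardization statistics over every column) are
    computed once; scoring a candidate feature set then only slices columns.
    """

    col_pos: dict
    x: np.ndarray  # lesions x all features
    y: np.ndarray
    fold_train: list  # flat list over (subset, fold)
    fold_val: list
    fold_mu: list  # per-fold per-column mean over the training lesions
    fold_sd: list
    fold_subset: list  # subset index of each flat fold
    n_subsets: int


def make_cv_plan(table: FeatureTable, subsets: list[BalancedSubset], config: SelectionConfig) -> CVPlan:
    """Precompute per-subset patient-level stratified folds (feature-independent)."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 202)))
    pids = table.patient_ids
    y = table.labels
    x = np.ascontiguousarray(table.values.to_numpy(dtype=np.float64))
    plan = CVPlan(
        col_pos={fid: j for j, fid in enumerate(table.feature_ids)},
        x=x,
        y=y,
        fold_train=[],
        fold_val=[],
        fold_mu=[],
        fold_sd=[],
        fold_subset=[],
        n_subsets=len(subsets),
    )
    for si, s in enumerate(subsets):
        for train, val in _patient_stratified_folds(pids, y, s.indices, config.cv_folds, rng):
            xt = x[train]
            mu = xt.mean(axis=0)
            sd = xt.std(axis=0)
            sd[sd == 0] = 1.0
            plan.fold_train.append(train)
            plan.fold_val.append(val)
            plan.fold_mu.append(mu)
            plan.fold_sd.append(sd)
            plan.fold_subset.append(si)
    return plan


def cv_feature_set_score(
    table: FeatureTable,
    feature_ids,
    subsets: list[BalancedSubset],
    config: SelectionConfig,
    plan: list[list] | None = None,
    audit: dict | None = None,
) -> float:
    """Mean cross-validated AUC of a k-NN vote over the balanced subsets.

    Per subset: patient-level stratified k-fold; per fold the k-NN is fitted
    on the training folds (z-scored with training statistics) and validation
    lesions are scored by neighbour vote fraction; the fold AUCs are
    averaged, then averaged over subsets.  Single-class folds are skipped
    (and counted in ``audit``).
    """
    if not feature_ids:
        raise ValueError("feature set must be non-empty")
    plan = plan if plan is not None else make_cv_plan(table, subsets, config)
    cols = np.array([plan.col_pos[f] for f in feature_ids])
    xc = np.ascontiguousarray(plan.x[:, cols])  # one column slice per evaluation
    y = plan.y
    k = config.k_neighbors
    skipped = 0
    per_subset: list[list[float]] = [[] for _ in range(plan.n_subsets)]
    for train, val, mu, sd, si in zip(
        plan.fold_train, plan.fold_val, plan.fold_mu, plan.fold_sd, plan.fold_subset
    ):
        yv = y[val]
        if yv.min() == yv.max():
            skipped += 1
            continue
        mu_c = mu[cols]
        inv_sd = 1.0 / sd[cols]
        kk = min(k, len(train))
        frac = knn_vote_fractions(
            (xc[train] - mu_c) * inv_sd,
            y[train],
            (xc[val] - mu_c) * inv_sd,
            kk,
        )
        per_subset[si].append(_rank_auc(frac, yv))
    if audit is not None:
        audit["skipped_folds"] = skipped
    subset_scores = [float(np.mean(aucs)) for aucs in per_subset if aucs]
    if not subset_scores:
        raise ValueError("all CV folds were single-class; cannot score")
    return float(np.mean(subset_scores))


# ---------------------------------------------------------------------------
# sequential forward selection
# ---------------------------------------------------------------------------


def sequential_forward_select(
    table: FeatureTable,
    candidates,
    config: SelectionConfig | None = None,
    subsets: list[BalancedSubset] | None = None,
) -> SelectionResult:
    """Greedy forward selection scored by :func:`cv_feature_set_score`.

    Stops when the best improvement falls below ``min_improvement`` or
    ``max_features`` is reached.
    """
    config = config or SelectionConfig()
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    subsets = subsets if subsets is not None else make_balanced_subsets(table, config)
    plan = make_cv_plan(table, subsets, config)

    selected: list[str] = []
    step_scores: list[float] = []
    audit: dict = {"steps": []}
    current = -np.inf
    while len(selected) < config.max_features and len(selected) < len(candidates):
        best_f, best_score = None, -np.inf
        # candidate order (the mRMR ranking) breaks exact ties deterministically
        for f in candidates:
            if f in selected:
                continue
            score = cv_feature_set_score(table, selected + [f], subsets, config, plan=plan)
            if score > best_score:
                best_f, best_score = f, score
        improvement = best_score - (current if np.isfinite(current) else 0.0)
        audit["steps"].append({"feature": best_f, "score": best_score, "improvement": improvement})
        if selected and improvement < config.min_improvement:
            break
        selected.append(best_f)
        step_scores.append(best_score)
        current = best_score
    return SelectionResult(selected=selected, step_scores=step_scores, audit=audit)


def select_features(table: FeatureTable, config: SelectionConfig | None = None) -> SelectionResult:
    """Full chain: R^2 pruning, mRMR ranking to the candidate pool, SFS."""
    config = config or SelectionConfig()
    reduced, red_audit = correlation_reduce(table, config)
    ranked = mrmr_rank(reduced, pool=config.mrmr_pool)
    result = sequential_forward_select(reduced, ranked, config)
    result.audit["reduction"] = {
        "n_in": red_audit.get("n_in", len(table.feature_ids)),
        "n_out": red_audit.get("n_out", len(reduced.feature_ids)),
        "representatives": red_audit.get("representatives"),
    }
    result.audit["mrmr_ranking"] = ranked
    return result
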
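"""Feature reduction and selection: univariate screening, R^2 pruning, mRMR
ranking against an exhaustive oracle, balanced subsets, patient-level CV and
sequential forward selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

from bmradiomics.selection import (
    SelectionConfig,
    correlation_reduce,
    cv_feature_set_score,
    make_balanced_subsets,
    make_cv_plan,
    mrmr_rank,
    select_features,
    sequential_forward_select,
    univariate_auc,
)
from bmradiomics.selection import _discretize

from conftest import make_feature_table, planted_table


class TestUnivariateAuc:
    def test_perfectly_ordered(self):
        assert univariate_auc([1, 2, 3, 10, 11, 12], ["LC"] * 3 + ["LF"] * 3) == 1.0

    def test_anti_ordered_direction_corrected(self):
        assert univariate_auc([10, 11, 12, 1, 2, 3], ["LC"] * 3 + ["LF"] * 3) == 1.0

    def test_alternating_classes_exhaustive_count(self):
        # values 1..10, classes alternating LF/LC; exhaustive Mann-Whitney:
        # LF = {1,3,5,7,9}, LC = {2,4,6,8,10}; #(LF > LC) = 10 of 25 pairs
        values = list(range(1, 11))
        labels = ["LF", "LC"] * 5
        assert univariate_auc(values, labels) == pytest.approx(max(10 / 25, 15 / 25))

    def test_midrank_ties(self):
        assert univariate_auc([1.0, 1.0], ["LC", "LF"]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            univariate_auc([1, 2], ["LC", "LC"])


class TestCorrelationReduce:
    def test_identical_features_collapse(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=40)
        tab = make_feature_table(np.column_stack([f, f]), ["LC", "LF"] * 20, columns=["a", "b"])
        reduced, audit = correlation_reduce(tab)
        assert len(reduced.feature_ids) == 1
        assert audit["n_out"] == 1

    def test_affine_pair_plus_independent(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=60)
        g = rng.normal(size=60)
        tab = make_feature_table(
            np.column_stack([f, 2 * f + 1, g]), ["LC", "LF"] * 30, columns=["f", "f_affine", "g"]
        )
        reduced, audit = correlation_reduce(tab)
        assert len(reduced.feature_ids) == 2
        comps = {frozenset(c) for c in audit["components"]}
        assert frozenset({"f", "f_affine"}) in comps
        assert frozenset({"g"}) in comps

    def test_no_remaining_pair_above_threshold(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(80, 3))
        # build 9 features in 3 correlated triplets
        x = np.column_stack([base[:, j] + 0.01 * rng.normal(size=80) for j in range(3) for _ in range(3)])
        tab = make_feature_table(x, ["LC", "LF"] * 40)
        reduced, _ = correlation_reduce(tab)
        r2 = np.corrcoef(reduced.values.to_numpy(), rowvar=False) ** 2
        off = r2[~np.eye(len(reduced.feature_ids), dtype=bool)]
        assert (off <= 0.8).all()

    def test_constant_feature_is_singleton(self):
        rng = np.random.default_rng(3)
        x = np.column_stack([np.full(20, 5.0), rng.normal(size=20)])
        tab = make_feature_table(x, ["LC", "LF"] * 10, columns=["const", "var"])
        reduced, audit = correlation_reduce(tab)
        assert set(reduced.feature_ids) == {"const", "var"}


def _oracle_mid_rank(df: pd.DataFrame, y: np.ndarray, pool: int) -> list[str]:
    """Exhaustive MID greedy using sklearn's mutual_info_score (nats)."""
    codes = {c: _discretize(df[c].to_numpy()) for c in df.columns}
    rel = {c: mutual_info_score(codes[c], y) for c in df.columns}
    selected: list[str] = []
    remaining = sorted(df.columns)
    while remaining and len(selected) < pool:
        best, best_score = None, -np.inf
        for c in remaining:
            red = np.mean([mutual_info_score(codes[c], codes[s]) for s in selected]) if selected else 0.0
            score = rel[c] - red
            if score > best_score + 1e-15:
                best, best_score = c, score
        selected.append(best)
        remaining.remove(best)
    return selected


class TestMrmr:
    def test_single_feature(self):
        tab = make_feature_table(np.arange(10.0).reshape(-1, 1), ["LC", "LF"] * 5, columns=["only"])
        assert mrmr_rank(tab, pool=5) == ["only"]

    def test_label_copy_ranked_first(self):
        rng = np.random.default_rng(4)
        y = np.array([0, 1] * 20)
        x = np.column_stack([rng.normal(size=40), y.astype(float), rng.normal(size=40)])
        tab = make_feature_table(x, ["LF" if v else "LC" for v in y], columns=["n1", "label_copy", "n2"])
        assert mrmr_rank(tab)[0] == "label_copy"

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        x = rng.integers(0, 3, size=(n, 3)).astype(float)
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        labels = ["LF" if v else "LC" for v in y]
        tab = make_feature_table(x, labels, columns=["fa", "fb", "fc"])
        assert mrmr_rank(tab) == _oracle_mid_rank(tab.values, y, 3)

    def test_bad_pool_rejected(self):
        tab = make_feature_table(np.ones((4, 1)), ["LC", "LF"] * 2)
        with pytest.raises(ValueError):
            mrmr_rank(tab, pool=0)


class TestBalancedSubsets:
    def test_study_scale_counts(self):
        labels = ["LC"] * 91 + ["LF"] * 50
        rng = np.random.default_rng(0)
        tab = make_feature_table(rng.normal(size=(141, 2)), labels)
        subsets = make_balanced_subsets(tab, SelectionConfig(n_subsets=51, seed=1))
        for s in subsets:
            assert len(s.indices) == 100
            assert s.n_lc == 50 and s.n_lf == 50
            assert len(np.unique(s.indices)) == 100

    def test_equal_classes_single_subset_is_full_table(self):
        labels = ["LC"] * 10 + ["LF"] * 10
        tab = make_feature_table(np.zeros((20, 1)), labels)
        (s,) = make_balanced_subsets(tab, SelectionConfig(n_subsets=1, seed=0))
        assert sorted(s.indices) == list(range(20))

    def test_minority_larger_swaps_with_warning(self):
        labels = ["LF"] * 12 + ["LC"] * 5
        tab = make_feature_table(np.zeros((17, 1)), labels)
        with pytest.warns(UserWarning):
            subsets = make_balanced_subsets(tab, SelectionConfig(n_subsets=3, seed=0))
        assert all(s.n_lc == 5 and s.n_lf == 5 for s in subsets)

    def test_deterministic_given_seed(self):
        labels = ["LC"] * 30 + ["LF"] * 10
        tab = make_feature_table(np.zeros((40, 1)), labels)
        a = make_balanced_subsets(tab, SelectionConfig(n_subsets=5, seed=7))
        b = make_balanced_subsets(tab, SelectionConfig(n_subsets=5, seed=7))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.indices, sb.indices)


class TestCvScore:
    def test_label_feature_scores_one(self):
        tab = planted_table(40, seed=0, n_noise=0, sep=50.0)
        cfg = SelectionConfig(n_subsets=11, seed=0)
        subsets = make_balanced_subsets(tab, cfg)
        score = cv_feature_set_score(tab, ["planted_a", "planted_b"], subsets, cfg)
        assert score > 0.99

    def test_noise_feature_near_chance(self):
        tab = planted_table(130, seed=3, n_noise=1, sep=0.0)
        cfg = SelectionConfig(n_subsets=51, seed=3)
        subsets = make_balanced_subsets(tab, cfg)
        score = cv_feature_set_score(tab, ["noise_00"], subsets, cfg)
        assert 0.4 <= score <= 0.6

    def test_patients_never_split_across_folds(self):
        tab = planted_table(50, seed=5, n_noise=2)
        cfg = SelectionConfig(n_subsets=7, seed=5)
        subsets = make_balanced_subsets(tab, cfg)
        plan = make_cv_plan(tab, subsets, cfg)
        pids = tab.patient_ids
        for train, val in zip(plan.fold_train, plan.fold_val):
            assert not set(pids[train]) & set(pids[val])


class TestSfs:
    def test_planted_perfect_feature_selected_first(self):
        tab = planted_table(60, seed=8, n_noise=20, sep=6.0, planted=1)
        cfg = SelectionConfig(n_subsets=11, seed=8)
        res = sequential_forward_select(tab, tab.feature_ids, cfg)
        assert res.selected[0] == "planted_a"

    def test_all_noise_stops_within_cap(self):
        # ~180 lesions, ~65 LF: the null CV-AUC sd is ~0.045, so even the
        # max over 10 candidates stays well below 0.7
        tab = planted_table(130, seed=9, n_noise=10, sep=0.0, planted=0)
        cfg = SelectionConfig(n_subsets=11, seed=9, max_features=4)
        res = sequential_forward_select(tab, tab.feature_ids, cfg)
        assert len(res.selected) <= 4
        assert all(s < 0.7 for s in res.step_scores)

    def test_xor_pair_both_selected(self):
        # neither feature separates alone; the pair does (XOR layout)
        rng = np.random.default_rng(10)
        n_pat = 60
        rows, labels = [], []
        for p in range(n_pat):
            a, b = rng.integers(0, 2), rng.integers(0, 2)
            y = "LF" if (a ^ b) else "LC"
            rows.append([a + 0.05 * rng.normal(), b + 0.05 * rng.normal()])
            labels.append(y)
        tab = make_feature_table(np.array(rows), labels, columns=["xa", "xb"])
        cfg = SelectionConfig(n_subsets=11, seed=10)
        res = sequential_forward_select(tab, ["xa", "xb"], cfg)
        assert set(res.selected) == {"xa", "xb"}
        assert res.step_scores[-1] > 0.9

    def test_full_chain_deterministic(self):
        tab = planted_table(40, seed=12, n_noise=10)
        cfg = SelectionConfig(n_subsets=11, seed=12)
        r1 = select_features(tab, cfg)
        r2 = select_features(tab, cfg)
        assert r1.selected == r2.selected
        assert r1.step_scores == r2.step_scores
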
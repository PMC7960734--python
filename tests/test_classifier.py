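"""LASSO selection, SVM training, CV protocol, metrics, model comparison."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from remitpredict.classifier import (
    DEFAULT_C_GRID,
    EmptySelectionError,
    LassoFit,
    Metrics,
    ModelResult,
    compare_models,
    compute_metrics,
    fit_lasso_cv,
    holdout_evaluate,
    kkt_residual,
    lambda_max,
    rank_auc,
    rank_features,
    repeated_cv_evaluate,
    select_features,
    train_svm,
)
from util import brute_force_auc

FAST_LASSO = dict(n_folds=3, n_alphas=30, alpha_min_ratio=1e-2)
FAST_SVM = dict(C_grid=(0.01, 1.0, 100.0), inner_folds=3)


def _blobs(rng, n=60, d=6.0, p=4):
    """Two well-separated Gaussian classes."""
    y = np.array(["continued", "remitted"] * (n // 2))
    X = rng.standard_normal((n, p))
    X[:, 0] += np.where(y == "remitted", d / 2, -d / 2)
    return X, y


class TestLasso:
    def test_all_zero_at_lambda_max(self, rng):
        X = rng.standard_normal((80, 30))
        y = rng.integers(0, 2, 80)
        amax = lambda_max(X, 2.0 * y - 1.0)
        fit = fit_lasso_cv(X, y, alphas=[amax * 1.0001], n_folds=3)
        assert np.all(fit.coef == 0.0)

    def test_orthonormal_design_soft_threshold(self, rng):
        """With X^T X = n I the LASSO solution is soft(OLS, alpha) exactly."""
        n, p = 64, 5
        M = rng.standard_normal((n, p))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        X = np.sqrt(n) * Q[:, :p]
        y = rng.integers(0, 2, n)
        ypm = 2.0 * y - 1.0
        alpha = 0.05
        fit = fit_lasso_cv(X, y, alphas=[alpha], n_folds=3)
        ols = X.T @ (ypm - ypm.mean()) / n
        expected = np.sign(ols) * np.maximum(np.abs(ols) - alpha, 0.0)
        np.testing.assert_allclose(fit.coef, expected, atol=1e-6)

    def test_kkt_conditions_hold(self, rng):
        for _ in range(10):
            X = rng.standard_normal((100, 60))
            y = rng.integers(0, 2, 100)
            alpha = lambda_max(X, 2.0 * y - 1.0) * rng.uniform(0.05, 0.8)
            fit = fit_lasso_cv(X, y, alphas=[alpha], n_folds=3)
            assert kkt_residual(X, y, fit) < 1e-6

    def test_informative_features_selected(self, rng):
        """2 planted features (d=1) among 98 noise at n=200 are found."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = np.array([0, 1] * 100)
            X = r.standard_normal((200, 100))
            X[:, :2] += (2.0 * y - 1.0)[:, None] * 0.5
            fit = fit_lasso_cv(X, y, seed=seed, **FAST_LASSO)
            if {"f0", "f1"} <= set(fit.selected):
                hits += 1
        assert hits >= 9

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        with pytest.raises(ValueError, match="classes"):
            fit_lasso_cv(X, np.zeros(20, dtype=int))

    def test_non_finite_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit_lasso_cv(X, np.array([0, 1] * 10))


class TestSelect:
    def _fit(self, coef, names):
        return LassoFit(
            coef=np.asarray(coef, dtype=float), intercept=0.0, alpha=0.1,
            alphas=np.array([0.1]), cv_loss=np.array([1.0]), feature_names=names,
        )

    def test_nonzero_in_original_order(self):
        fit = self._fit([0, 0.3, 0, -0.1], ["a", "b", "c", "d"])
        assert select_features(fit) == ["b", "d"]

    def test_empty_selection_signaled(self):
        with pytest.raises(EmptySelectionError):
            select_features(self._fit([0, 0, 0], ["a", "b", "c"]))

    def test_selection_set_invariant_to_column_permutation(self, rng):
        X = rng.standard_normal((120, 20))
        y = np.array([0, 1] * 60)
        X[:, 3] += (2.0 * y - 1.0) * 0.8
        fit = fit_lasso_cv(pd.DataFrame(X, columns=[f"c{j}" for j in range(20)]), y,
                           **FAST_LASSO)
        perm = rng.permutation(20)
        fit_p = fit_lasso_cv(
            pd.DataFrame(X[:, perm], columns=[f"c{j}" for j in perm]), y, **FAST_LASSO
        )
        assert set(fit.selected) == set(fit_p.selected)


class TestSvm:
    def test_separable_blobs_fit_perfectly(self, rng):
        X, y = _blobs(rng)
        model = train_svm(X, y, **FAST_SVM)
        acc = np.mean((model.decision_scores(X) > 0) == (y == "remitted"))
        assert acc == 1.0

    def test_label_flip_flips_weights(self, rng):
        X, y = _blobs(rng)
        flipped = np.where(y == "remitted", "continued", "remitted")
        m1 = train_svm(X, y, C_grid=(1.0,), inner_folds=2)
        m2 = train_svm(X, flipped, C_grid=(1.0,), inner_folds=2)
        np.testing.assert_allclose(m1.w, -m2.w, atol=1e-3)
        # identical decision boundary: same predictions up to label swap
        s1, s2 = m1.decision_scores(X), m2.decision_scores(X)
        assert np.all((s1 > 0) == (s2 < 0))

    def test_solution_is_locally_optimal(self, rng):
        """Hinge+L2 objective at the solution beats 1000 nearby perturbations."""
        X, y = _blobs(rng, n=40, d=3.0)
        model = train_svm(X, y, C_grid=(1.0,), inner_folds=2)
        y_pm = np.where(y == "remitted", 1.0, -1.0)
        C = model.C

        def objective(w, b):
            margins = y_pm * (X @ w + b)
            # liblinear augments the intercept as a feature, so it is penalized
            return 0.5 * (w @ w + b * b) + C * np.maximum(0, 1 - margins).sum()

        base = objective(model.w, model.b)
        probe_rng = np.random.default_rng(1)
        for _ in range(1000):
            dw = probe_rng.standard_normal(len(model.w)) * 1e-2
            db = probe_rng.standard_normal() * 1e-2
            assert base <= objective(model.w + dw, model.b + db) + 1e-4

    def test_degenerate_identical_rows_rejected(self):
        X = np.ones((10, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="identical"):
            train_svm(X, y)


class TestMetrics:
    def test_confusion_arithmetic(self):
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 8 + [0] * 2 + [1] * 3 + [0] * 7
        m = compute_metrics(y_true, y_pred)
        assert (m.tp, m.tn, m.fp, m.fn) == (8, 7, 3, 2)
        assert m.accuracy == pytest.approx(0.75)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.7)

    def test_perfect_ranking_auc_one(self):
        m = compute_metrics([1, 1, 0, 0], [1, 1, 0, 0], scores=[4, 3, 2, 1])
        assert m.auc == 1.0

    def test_tied_scores_auc(self):
        assert rank_auc(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.8, 0.1])) == 0.875

    def test_absent_class_flags_missing_rate(self):
        m = compute_metrics([1, 1, 1], [1, 0, 1])
        assert m.specificity is None
        assert m.sensitivity == pytest.approx(2 / 3)

    def test_auc_matches_brute_force_and_sklearn(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 100))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            ours = rank_auc(y, scores)
            assert ours == pytest.approx(brute_force_auc(y, scores), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_subject_order_invariance(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        s = rng.standard_normal(50)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        perm = rng.permutation(50)
        a = compute_metrics(y, p, s)
        b = compute_metrics(y[perm], p[perm], s[perm])
        assert a == b


class TestRepeatedCv:
    def test_separable_cohort_scores_perfectly_both_modes(self, rng):
        X, y = _blobs(rng, n=60, d=8.0)
        for mode in ("paper_faithful", "nested"):
            res = repeated_cv_evaluate(
                (X, y), mode=mode, outer_folds=5, repeats=2, seed=0,
                lasso_kwargs=FAST_LASSO, svm_kwargs=FAST_SVM,
            )
            assert res.summary["accuracy"][0] > 0.97
            assert res.summary["auc"][0] > 0.97

    def test_metrics_invariant_to_feature_order(self, rng):
        X, y = _blobs(rng, n=60, d=2.0, p=10)
        cols = [f"c{j}" for j in range(10)]
        df = pd.DataFrame(X, columns=cols)
        res_a = repeated_cv_evaluate(
            (df, y), mode="nested", outer_folds=5, repeats=1, seed=3,
            lasso_kwargs=FAST_LASSO, svm_kwargs=FAST_SVM,
        )
        perm = list(rng.permutation(cols))
        res_b = repeated_cv_evaluate(
            (df[perm], y), mode="nested", outer_folds=5, repeats=1, seed=3,
            lasso_kwargs=FAST_LASSO, svm_kwargs=FAST_SVM,
        )
        assert set(res_a.selected_features) == set(res_b.selected_features)
        assert res_a.summary["accuracy"][0] == pytest.approx(
            res_b.summary["accuracy"][0], abs=1e-9
        )

    def test_null_features_score_near_chance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((80, 10))
        y = np.array(["continued", "remitted"] * 40)
        res = repeated_cv_evaluate(
            (X, y), mode="nested", outer_folds=5, repeats=3, seed=7,
            lasso_kwargs=FAST_LASSO, svm_kwargs=FAST_SVM,
        )
        assert 0.3 <= res.summary["accuracy"][0] <= 0.7

    def test_records_complete_fold_structure(self, rng):
        X, y = _blobs(rng, n=40)
        res = repeated_cv_evaluate(
            (X, y), outer_folds=4, repeats=3, seed=1,
            lasso_kwargs=FAST_LASSO, svm_kwargs=FAST_SVM,
        )
        assert len(res.fold_metrics) == 3
        assert all(len(rep) == 4 for rep in res.fold_metrics)
        assert all(len(v) == 3 for v in res.repeat_means.values())
        ranks = [r for _, _, r in res.feature_ranks]
        assert ranks == list(range(1, len(ranks) + 1))

    def test_too_few_subjects_per_class_rejected(self, rng):
        X, y = _blobs(rng, n=10)
        with pytest.raises(ValueError, match="per class"):
            repeated_cv_evaluate((X, y), outer_folds=10)


class TestHoldout:
    def test_separable_and_deterministic(self, rng):
        X, y = _blobs(rng, n=80, d=8.0)
        m1 = holdout_evaluate((X, y), seed=5, lasso_kwargs=FAST_LASSO, svm_kwargs=FAST_SVM)
        m2 = holdout_evaluate((X, y), seed=5, lasso_kwargs=FAST_LASSO, svm_kwargs=FAST_SVM)
        assert m1 == m2
        assert m1.accuracy > 0.95

    def test_null_cohort_averages_to_chance_over_seeds(self):
        """Holdout accuracy on featureless noise averages ~50% across splits."""
        rng = np.random.default_rng(11)
        X = rng.standard_normal((200, 20))
        y = np.array(["continued", "remitted"] * 100)
        accs = [
            holdout_evaluate((X, y), seed=s,
                             lasso_kwargs=FAST_LASSO, svm_kwargs=FAST_SVM).accuracy
            for s in range(10)
        ]
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_small_stratum_advises_cv(self, rng):
        X, y = _blobs(rng, n=12)
        with pytest.raises(ValueError, match="CV"):
            holdout_evaluate((X, y))


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 1), st.integers(-5, 5)), min_size=4, max_size=60
    ).filter(lambda v: len({y for y, _ in v}) == 2)
)
def test_auc_pairwise_property(pairs):
    """Midrank AUC equals exhaustive pairwise counting for any tied integer
    score pattern."""
    y = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs], dtype=float)
    assert rank_auc(y, s) == pytest.approx(brute_force_auc(y, s), abs=1e-12)


def _result_with_accuracies(accs):
    n = len(accs)
    return ModelResult(
        mode="paper_faithful", fold_metrics=[], repeat_means={"accuracy": list(accs)},
        summary={}, selected_features=[], selection_frequency={}, feature_weights={},
        feature_ranks=[], feature_group_diff={}, feature_tags={}, n_subjects=0,
        n_features=0, outer_folds=10, repeats=n, seed=0,
    )


class TestCompareModels:
    def test_identical_results_p_one(self):
        a = _result_with_accuracies([0.8, 0.82, 0.79])
        cmp = compare_models(a, _result_with_accuracies([0.8, 0.82, 0.79]))
        assert cmp.p_value == 1.0
        assert cmp.direction == "none"

    def test_constant_shift_detected(self, rng):
        base = 0.7 + 0.01 * rng.standard_normal(10)
        cmp = compare_models(
            _result_with_accuracies(base + 0.05), _result_with_accuracies(base)
        )
        assert cmp.p_value < 0.01
        assert cmp.direction == "A"
        assert "anti-conservative" in cmp.caveat

    def test_mismatched_repeats_rejected(self):
        with pytest.raises(ValueError, match="repeat"):
            compare_models(
                _result_with_accuracies([0.5] * 3), _result_with_accuracies([0.5] * 4)
            )


class TestRankFeatures:
    def _model(self, w, names):
        from remitpredict.classifier import SvmModel

        return SvmModel(w=np.asarray(w, float), b=0.0, C=1.0,
                        feature_names=names, estimator=None)

    def test_descending_absolute_weight(self):
        ranks = rank_features(self._model([0.1, -0.5, 0.3], ["a", "b", "c"]),
                              ["a", "b", "c"])
        assert [r[0] for r in ranks] == ["b", "c", "a"]
        assert [r[2] for r in ranks] == [1, 2, 3]

    def test_tie_breaks_by_name(self):
        ranks = rank_features(self._model([0.5, -0.5], ["zz", "aa"]), ["zz", "aa"])
        assert [r[0] for r in ranks] == ["aa", "zz"]
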
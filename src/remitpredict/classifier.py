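"""LASSO feature selection + linear SVM with repeated cross-validation.

The prediction protocol: Z-normalized features are reduced by an L1-penalized
(LASSO) regression of the binary outcome (squared-error loss on a ±1-coded
label, penalty chosen by 10-fold CV over a log-spaced grid); features with
nonzero coefficients feed a soft-margin linear SVM whose regularization C is
tuned by inner cross-validation; performance is measured by shuffled,
stratified 10-fold CV repeated 10 times (means ± SD across repeats) with an
optional 70:30 holdout check.

Two evaluation modes are provided and named explicitly:

* ``paper_faithful`` — normalization and LASSO selection happen once on the
  full stratum before CV, reproducing the published order of operations. The
  held-out folds have then already influenced feature selection, so scores are
  optimistically biased (selection leakage).
* ``nested`` — normalization statistics and the LASSO selection are refit
  inside every training fold; held-out rows never touch feature selection.
  This is the leakage-free estimate.

The positive class throughout is ``remitted`` (sensitivity = remitted recall,
specificity = continued recall).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.linear_model import Lasso, lasso_path
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.svm import LinearSVC

from .cohort_assembly import FeatureTable, znormalize

__all__ = [
    "LassoFit",
    "SvmModel",
    "Metrics",
    "ModelResult",
    "ComparisonResult",
    "EmptySelectionError",
    "POSITIVE_LABEL",
    "fit_lasso_cv",
    "select_features",
    "kkt_residual",
    "train_svm",
    "repeated_cv_evaluate",
    "holdout_evaluate",
    "compute_metrics",
    "rank_auc",
    "compare_models",
    "rank_features",
]

POSITIVE_LABEL = "remitted"
NEGATIVE_LABEL = "continued"

DEFAULT_C_GRID: tuple[float, ...] = tuple(np.logspace(-3, 3, 10))


class EmptySelectionError(RuntimeError):
    """LASSO shrank every coefficient to zero; no features were selected."""


@dataclasses.dataclass
class LassoFit:
    coef: np.ndarray
    intercept: float
    alpha: float
    alphas: np.ndarray
    cv_loss: np.ndarray  # mean validation MSE per alpha, aligned with alphas
    feature_names: list[str]

    @property
    def selected(self) -> list[str]:
        return [n for n, b in zip(self.feature_names, self.coef) if b != 0.0]


@dataclasses.dataclass
class SvmModel:
    w: np.ndarray
    b: float
    C: float
    feature_names: list[str]
    estimator: LinearSVC

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.b


@dataclasses.dataclass
class Metrics:
    """Confusion counts and derived rates; undefined rates are None, never 0."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float | None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ComparisonResult:
    p_value: float
    direction: str  # "A" | "B" | "none"
    mean_diff: float
    caveat: str = "repeat-level, anti-conservative"


@dataclasses.dataclass
class ModelResult:
    """Everything a repeated-CV run produced, sufficient for exact replay."""

    mode: str
    fold_metrics: list[list[Metrics]]  # [repeat][fold]
    repeat_means: dict[str, list[float]]  # metric -> per-repeat mean
    summary: dict[str, tuple[float, float]]  # metric -> (mean, sd across repeats)
    selected_features: list[str]
    selection_frequency: dict[str, float]
    feature_weights: dict[str, float]
    feature_ranks: list[tuple[str, float, int]]
    feature_group_diff: dict[str, float]
    feature_tags: dict[str, str]
    n_subjects: int
    n_features: int
    outer_folds: int
    repeats: int
    seed: int
    label: str = ""

    def to_jsonable(self) -> dict:
        return {
            "label": self.label,
            "mode": self.mode,
            "n_subjects": self.n_subjects,
            "n_features": self.n_features,
            "outer_folds": self.outer_folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "summary": {k: list(v) for k, v in self.summary.items()},
            "repeat_means": self.repeat_means,
            "fold_metrics": [[m.as_dict() for m in rep] for rep in self.fold_metrics],
            "selected_features": self.selected_features,
            "selection_frequency": self.selection_frequency,
            "feature_weights": self.feature_weights,
            "feature_ranks": [list(t) for t in self.feature_ranks],
            "feature_group_diff": self.feature_group_diff,
            "feature_tags": {f: self.feature_tags.get(f, "") for f in self.selected_features},
        }


def _encode_labels(y: Sequence) -> np.ndarray:
    """Map labels to {0, 1} with 1 = remitted (positive class)."""
    arr = np.asarray(y)
    if arr.dtype.kind in "OU":
        out = np.where(arr == POSITIVE_LABEL, 1, 0)
        valid = np.isin(arr, [POSITIVE_LABEL, NEGATIVE_LABEL])
        if not valid.all():
            raise ValueError(f"unknown labels: {sorted(set(arr[~valid]))}")
        return out
    uniq = np.unique(arr)
    if set(uniq) <= {-1, 1}:
        return (arr > 0).astype(int)
    if set(uniq) <= {0, 1}:
        return arr.astype(int)
    raise ValueError(f"labels must be binary, got values {uniq[:5]}")


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the LASSO solution is exactly zero.

    For the objective (1/2n)||y - b0 - X beta||^2 + alpha ||beta||_1 this is
    max_j |x_j^T (y - ybar)| / n (with X column-centered implicitly through
    the intercept).
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(Xc.T @ yc)) / n)


def fit_lasso_cv(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    n_folds: int = 10,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
    alphas: Sequence[float] | None = None,
    seed: int = 0,
    tol: float = 1e-8,
    cv_tol: float = 1e-4,
    max_iter: int = 100_000,
) -> LassoFit:
    """LASSO on the ±1-coded outcome with the penalty chosen by k-fold CV.

    The grid is log-spaced from lambda_max (all-zero solution) down to
    ``alpha_min_ratio * lambda_max``; the CV criterion is mean held-out squared
    error and ties prefer the larger (sparser) penalty. The penalty search uses
    the looser ``cv_tol`` (only the CV-loss ranking matters there); the final
    returned fit is solved to ``tol`` so its coefficients satisfy the LASSO
    KKT conditions tightly.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        feature_names = [f"f{j}" for j in range(Xa.shape[1])]
    if not np.isfinite(Xa).all():
        raise ValueError("X contains non-finite values")
    y01 = _encode_labels(y)
    if len(np.unique(y01)) < 2:
        raise ValueError("both outcome classes must be present")
    ypm = 2.0 * y01 - 1.0  # ±1 coding

    if alphas is None:
        amax = lambda_max(Xa, ypm)
        if amax == 0:
            raise ValueError("degenerate design: lambda_max is 0")
        grid = np.logspace(math.log10(amax), math.log10(amax * alpha_min_ratio), n_alphas)
    else:
        grid = np.sort(np.asarray(alphas, dtype=float))[::-1]

    n = len(ypm)
    folds = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    sq_err = np.zeros(len(grid))
    for tr, va in folds.split(Xa):
        Xt, yt = Xa[tr], ypm[tr]
        xm, ym = Xt.mean(axis=0), yt.mean()
        # lasso_path solves the no-intercept problem; center per fold instead
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(
                Xt - xm, yt - ym, alphas=grid, tol=cv_tol, max_iter=max_iter
            )
        pred = (Xa[va] - xm) @ coefs + ym  # (n_va, n_alphas)
        sq_err += ((pred - ypm[va, None]) ** 2).sum(axis=0)
    cv_loss = sq_err / n
    best = int(np.argmin(cv_loss))  # grid descends, so argmin prefers larger alpha on ties

    final = Lasso(alpha=grid[best], tol=tol, max_iter=max_iter)
    final.fit(Xa, ypm)
    return LassoFit(
        coef=final.coef_.copy(),
        intercept=float(final.intercept_),
        alpha=float(grid[best]),
        alphas=grid,
        cv_loss=cv_loss,
        feature_names=feature_names,
    )


def kkt_residual(X: np.ndarray, y: Sequence, fit: LassoFit) -> float:
    """Maximum violation of the LASSO stationarity conditions at ``fit``.

    Zero coefficients require |x_j^T r| / n <= alpha; nonzero ones require
    x_j^T r / n = alpha * sign(beta_j), with r the residual.
    """
    Xa = np.asarray(X, dtype=float)
    ypm = 2.0 * _encode_labels(y) - 1.0
    r = ypm - Xa @ fit.coef - fit.intercept
    g = Xa.T @ r / len(ypm)
    active = fit.coef != 0
    viol_zero = np.maximum(np.abs(g[~active]) - fit.alpha, 0.0)
    viol_active = np.abs(g[active] - fit.alpha * np.sign(fit.coef[active]))
    parts = [v for v in (viol_zero, viol_active) if v.size]
    return float(max(v.max() for v in parts)) if parts else 0.0


def select_features(fit: LassoFit) -> list[str]:
    """Names of nonzero-coefficient features, in original column order."""
    sel = fit.selected
    if not sel:
        raise EmptySelectionError(
            "LASSO selected no features; caller may fall back to the full feature set"
        )
    return sel


def train_svm(
    X_sel: np.ndarray | pd.DataFrame,
    y: Sequence,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> SvmModel:
    """Linear-kernel soft-margin SVM with C tuned by inner stratified CV.

    Accuracy is the tuning criterion; ties prefer the smaller (more
    regularized) C. The final model is refit at the chosen C on all rows.
    """
    if isinstance(X_sel, pd.DataFrame):
        names = list(X_sel.columns)
        Xa = X_sel.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X_sel, dtype=float)
        names = [f"f{j}" for j in range(Xa.shape[1])]
    if Xa.shape[1] == 0:
        raise ValueError("no features to train on")
    y01 = _encode_labels(y)
    if len(np.unique(y01)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.allclose(Xa, Xa[0]):
        raise ValueError("degenerate design: all rows identical")

    def _fit(C: float, X: np.ndarray, yy: np.ndarray) -> LinearSVC:
        # hinge loss + L2 in the dual (the classic soft-margin linear SVM)
        clf = LinearSVC(loss="hinge", C=C, max_iter=50_000, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X, yy)
        return clf

    counts = np.bincount(y01, minlength=2)
    k = int(min(inner_folds, counts.min()))
    if k >= 2:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(Xa, y01))
        accs = []
        for C in C_grid:
            fold_acc = [
                float(np.mean(_fit(C, Xa[tr], y01[tr]).predict(Xa[va]) == y01[va]))
                for tr, va in splits
            ]
            accs.append(float(np.mean(fold_acc)))
        best_C = None
        best_acc = -np.inf
        for C, acc in sorted(zip(C_grid, accs)):  # ascending C: strict > keeps smaller C on ties
            if acc > best_acc:
                best_acc, best_C = acc, C
    else:
        best_C = 1.0  # too few per-class rows to tune; standard default

    final = _fit(best_C, Xa, y01)
    return SvmModel(
        w=final.coef_.ravel().copy(),
        b=float(final.intercept_[0]),
        C=float(best_C),
        feature_names=names,
        estimator=final,
    )


def rank_auc(y_true01: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC from midranks (Mann-Whitney), with half credit for score ties."""
    y = np.asarray(y_true01)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = sstats.rankdata(s)  # midranks
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    y_true: Sequence, y_pred: Sequence, scores: Sequence[float] | None = None
) -> Metrics:
    """Confusion counts, accuracy, sensitivity/specificity and rank-based AUC.

    Positive class is ``remitted``. A rate whose denominator is empty (a class
    absent from y_true) is reported as None — flagged missing, never 0.
    """
    yt = _encode_labels(y_true)
    yp = _encode_labels(y_pred)
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred length mismatch")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    acc = (tp + tn) / len(yt)
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    auc = None
    if scores is not None and sens is not None and spec is not None:
        auc = rank_auc(yt, np.asarray(scores, dtype=float))
    return Metrics(tp, tn, fp, fn, acc, sens, spec, auc)


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "auc")


def _feature_frame(table) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    if isinstance(table, FeatureTable):
        return table.features, table.labels, dict(table.tags)
    X, y = table
    if not isinstance(X, pd.DataFrame):
        X = np.asarray(X)
        X = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    return X, pd.Series(np.asarray(y), index=X.index), {c: "" for c in X.columns}


def _stratified_folds(y01: np.ndarray, n_folds: int, rng_seed: int):
    """Shuffled stratified folds; re-shuffles (logged) if a training fold would
    lose a class — impossible under stratification with adequate counts, kept
    as a guard for tiny strata."""
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed + attempt)
        splits = list(skf.split(np.zeros(len(y01)), y01))
        if all(len(np.unique(y01[tr])) == 2 for tr, _ in splits):
            if attempt:
                warnings.warn(f"refolded {attempt} time(s) to keep both classes in training")
            return splits
    raise ValueError("cannot build folds with both classes in every training set")


def _fit_predict_fold(
    X_tr: pd.DataFrame,
    y_tr: np.ndarray,
    X_va: pd.DataFrame,
    seed: int,
    lasso_kwargs: dict,
    svm_kwargs: dict,
    preselected: list[str] | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One CV fold: (optionally) select on the training rows, train, score."""
    if preselected is None:
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0, ddof=1).replace(0.0, 1.0)
        Xt = (X_tr - mu) / sd
        Xv = (X_va - mu) / sd
        fit = fit_lasso_cv(Xt, y_tr, seed=seed, **lasso_kwargs)
        try:
            cols = select_features(fit)
        except EmptySelectionError:
            warnings.warn("empty LASSO selection in a fold; falling back to all features")
            cols = list(Xt.columns)
    else:
        Xt, Xv, cols = X_tr, X_va, preselected
    model = train_svm(Xt[cols], y_tr, seed=seed, **svm_kwargs)
    scores = model.decision_scores(Xv[cols].to_numpy(dtype=float))
    preds = (scores > 0).astype(int)
    return preds, scores, cols


def _summarize(repeat_metrics: list[list[Metrics]]) -> tuple[dict, dict]:
    repeat_means: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for rep in repeat_metrics:
        for m in METRIC_NAMES:
            vals = [getattr(f, m) for f in rep if getattr(f, m) is not None]
            repeat_means[m].append(float(np.mean(vals)) if vals else float("nan"))
    summary = {
        m: (float(np.nanmean(v)), float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0)
        for m, v in repeat_means.items()
    }
    return repeat_means, summary


def repeated_cv_evaluate(
    table: FeatureTable | tuple,
    mode: str = "paper_faithful",
    outer_folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    lasso_kwargs: Mapping | None = None,
    svm_kwargs: Mapping | None = None,
    label: str = "",
) -> ModelResult:
    """Shuffled, stratified k-fold CV of the normalize->LASSO->SVM pipeline,
    repeated with fresh shuffles and averaged across repeats.

    ``mode='paper_faithful'`` normalizes and LASSO-selects once on the full
    stratum before cross-validating the SVM (the published order of
    operations; optimistically biased by selection leakage).
    ``mode='nested'`` refits normalization statistics and the selection inside
    every training fold (leakage-free). Per-fold metrics are averaged within
    each repeat; the summary reports mean ± SD across repeats.
    """
    if mode not in ("paper_faithful", "nested"):
        raise ValueError(f"mode must be 'paper_faithful' or 'nested', got {mode!r}")
    lasso_kwargs = dict(lasso_kwargs or {})
    svm_kwargs = dict(svm_kwargs or {})
    X, y_raw, tags = _feature_frame(table)
    y01 = _encode_labels(y_raw)
    counts = np.bincount(y01, minlength=2)
    if counts.min() < outer_folds:
        raise ValueError(
            f"need >= {outer_folds} subjects per class, got {counts.tolist()}"
        )

    # Full-data normalization + selection: the model paper_faithful CV reuses,
    # and the reporting model (weights/ranks) for both modes.
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1).replace(0.0, 1.0)
    Z = (X - mu) / sd
    full_fit = fit_lasso_cv(Z, y01, seed=seed, **lasso_kwargs)
    try:
        full_selected = select_features(full_fit)
    except EmptySelectionError:
        warnings.warn("empty LASSO selection on the full stratum; using all features")
        full_selected = list(Z.columns)

    sel_counts: dict[str, int] = {}
    n_fold_fits = 0
    all_fold_metrics: list[list[Metrics]] = []
    for r in range(repeats):
        fold_seed = seed * 10_000 + r
        splits = _stratified_folds(y01, outer_folds, fold_seed)
        rep_metrics: list[Metrics] = []
        for tr, va in splits:
            if mode == "paper_faithful":
                preds, scores, cols = _fit_predict_fold(
                    Z.iloc[tr], y01[tr], Z.iloc[va], fold_seed,
                    lasso_kwargs, svm_kwargs, preselected=full_selected,
                )
            else:
                preds, scores, cols = _fit_predict_fold(
                    X.iloc[tr], y01[tr], X.iloc[va], fold_seed,
                    lasso_kwargs, svm_kwargs, preselected=None,
                )
            n_fold_fits += 1
            for c in cols:
                sel_counts[c] = sel_counts.get(c, 0) + 1
            rep_metrics.append(compute_metrics(y01[va], preds, scores))
        all_fold_metrics.append(rep_metrics)

    repeat_means, summary = _summarize(all_fold_metrics)
    final_model = train_svm(Z[full_selected], y01, seed=seed, **svm_kwargs)
    ranks = rank_features(final_model, full_selected)
    group_diff = {
        c: float(Z.loc[y01 == 1, c].mean() - Z.loc[y01 == 0, c].mean())
        for c in full_selected
    }
    return ModelResult(
        mode=mode,
        fold_metrics=all_fold_metrics,
        repeat_means=repeat_means,
        summary=summary,
        selected_features=full_selected,
        selection_frequency={c: k / n_fold_fits for c, k in sorted(sel_counts.items())},
        feature_weights={n: float(w) for n, w, _ in ranks},
        feature_ranks=ranks,
        feature_group_diff=group_diff,
        feature_tags=tags,
        n_subjects=len(X),
        n_features=X.shape[1],
        outer_folds=outer_folds,
        repeats=repeats,
        seed=seed,
        label=label,
    )


def holdout_evaluate(
    table: FeatureTable | tuple,
    train_fraction: float = 0.70,
    seed: int = 0,
    lasso_kwargs: Mapping | None = None,
    svm_kwargs: Mapping | None = None,
) -> Metrics:
    """Stratified 70:30 holdout check with the whole pipeline fit on the
    training split only (normalize -> select -> train)."""
    X, y_raw, _ = _feature_frame(table)
    y01 = _encode_labels(y_raw)
    if np.bincount(y01, minlength=2).min() < 10:
        raise ValueError("stratum too small for a holdout split; use repeated CV instead")
    idx_tr, idx_va = train_test_split(
        np.arange(len(y01)),
        train_size=train_fraction,
        stratify=y01,
        random_state=seed,
        shuffle=True,
    )
    preds, scores, _ = _fit_predict_fold(
        X.iloc[idx_tr], y01[idx_tr], X.iloc[idx_va], seed,
        dict(lasso_kwargs or {}), dict(svm_kwargs or {}), preselected=None,
    )
    return compute_metrics(y01[idx_va], preds, scores)


def compare_models(result_a: ModelResult, result_b: ModelResult) -> ComparisonResult:
    """Paired two-sided t test on per-repeat mean accuracies.

    Pairing is by repeat index under a shared fold-seed schedule. Repeat-level
    pairing reuses the same subjects across repeats, so the test is
    anti-conservative; the caveat is carried in the result.
    """
    a = np.asarray(result_a.repeat_means["accuracy"], dtype=float)
    b = np.asarray(result_b.repeat_means["accuracy"], dtype=float)
    if len(a) != len(b):
        raise ValueError(f"mismatched repeat counts: {len(a)} vs {len(b)}")
    diff = a - b
    if np.allclose(diff, 0.0):
        return ComparisonResult(p_value=1.0, direction="none", mean_diff=0.0)
    t, p = sstats.ttest_rel(a, b)
    direction = "A" if diff.mean() > 0 else "B"
    return ComparisonResult(p_value=float(p), direction=direction, mean_diff=float(diff.mean()))


def rank_features(model: SvmModel, feature_names: Sequence[str]) -> list[tuple[str, float, int]]:
    """Order features by |SVM weight| descending (rank 1 = most important).

    Ties break lexicographically by name for determinism.
    """
    if len(feature_names) != len(model.w):
        raise ValueError("feature_names length must match the weight vector")
    order = sorted(zip(feature_names, model.w), key=lambda t: (-abs(t[1]), t[0]))
    return [(name, float(w), i + 1) for i, (name, w) in enumerate(order)]
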
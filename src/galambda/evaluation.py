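"""Model fitting and evaluation: ROC/AUC, Youden accuracy, bootstrap CIs,
decision curves, and the consolidated per-selector report.

The classifier throughout is a linear logistic model on the selected
features, fitted by penalized maximum likelihood with a tiny ridge guard
(1e-6) so that perfectly separable tiny subspaces still yield a finite,
deterministic fit.  Discrimination is summarized by the trapezoidal AUC
(identical to the pair-counting estimator with ties counted 1/2) and by
the accuracy at the threshold maximizing the Youden index (TPR - FPR).
Confidence intervals are percentile bootstrap over (score, label) pairs,
resampled with replacement stratified by class.  Clinical utility uses
decision-curve net benefit, NB(pt) = TP/N - FP/N * pt/(1-pt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .datamodel import FeatureTable, RunConfig, SplitSpec

logger = logging.getLogger("galambda")

__all__ = [
    "RocCurve",
    "EvalReport",
    "DecisionCurve",
    "LogisticModel",
    "fit_logistic",
    "roc_auc",
    "youden_accuracy",
    "bootstrap_ci",
    "decision_curve",
    "cv_logistic_scores",
    "evaluate_pipeline",
]

_RIDGE_GUARD = 1e-6


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class DecisionCurve:
    pt: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray


@dataclass
class EvalReport:
    selector: str
    selected: tuple[int, ...]
    selected_names: tuple[str, ...]
    cv_auc: float
    cv_accuracy: float
    test_auc: float
    test_accuracy: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    youden_threshold_cv: float = float("nan")
    youden_threshold_test: float = float("nan")

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"selector": self.selector}
        for key in ("cv_auc", "cv_accuracy", "test_auc", "test_accuracy"):
            row[key] = getattr(self, key)
            lo, hi = self.ci.get(key, (float("nan"), float("nan")))
            row[f"{key}_ci_lo"], row[f"{key}_ci_hi"] = lo, hi
        return row


class LogisticModel:
    """Thin deterministic wrapper: coefficients, intercept, probabilities."""

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = float(intercept)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = np.asarray(X, dtype=float) @ self.coef + self.intercept
        return expit(eta)


def fit_logistic(
    table: FeatureTable | np.ndarray,
    feature_indices: Sequence[int] | None = None,
    labels: np.ndarray | None = None,
) -> LogisticModel:
    """Maximum-likelihood logistic fit with a small ridge guard.

    Accepts either a FeatureTable plus column indices, or a raw design
    matrix (already restricted to the features of interest) plus labels.
    """
    if isinstance(table, FeatureTable):
        if feature_indices is None or len(feature_indices) == 0:
            raise ValueError("need at least one feature")
        X = table.values[:, np.asarray(feature_indices, dtype=int)]
        y = table.labels
    else:
        X = np.asarray(table, dtype=float)
        y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n = len(y)
    # sklearn minimizes  sum loss + (1/(2C)) ||w||^2 ; guard lambda=1e-6
    # newton-cholesky: exact Newton steps, fast at n >> p (the regime of
    # every fit here) and robust under the ridge guard near separation
    clf = LogisticRegression(
        C=1.0 / (_RIDGE_GUARD * n), solver="newton-cholesky", max_iter=200
    )
    clf.fit(X, y)
    return LogisticModel(clf.coef_.ravel(), clf.intercept_[0])


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve and trapezoidal AUC over all distinct score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def youden_accuracy(
    curve: RocCurve, scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Threshold maximizing TPR - FPR (ties -> lower threshold) and the
    accuracy of the induced classifier ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    j = curve.tpr - curve.fpr
    best = np.max(j)
    candidates = curve.thresholds[np.isclose(j, best)]
    thr = float(np.min(candidates))
    pred = (scores >= thr).astype(int)
    acc = float(np.mean(pred == labels))
    return thr, acc


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a metric over (score, label) pairs.

    Resampling is with replacement, stratified by class (class counts
    preserved), so every resample contains both classes.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos, size=len(pos), replace=True),
                rng.choice(neg, size=len(neg), replace=True),
            ]
        )
        vals[b] = metric(scores[idx], labels[idx])
    lo = float(np.percentile(vals, 100 * (1 - level) / 2))
    hi = float(np.percentile(vals, 100 * (1 + level) / 2))
    return lo, hi


def decision_curve(
    probabilities: np.ndarray,
    labels: np.ndarray,
    pt_grid: np.ndarray | None = None,
) -> DecisionCurve:
    """Net benefit of acting on model predictions across risk thresholds.

    ``nb_model(pt) = TP/N - FP/N * pt/(1-pt)`` with predictions
    ``probability >= pt``; treat-all and treat-none reference curves are
    included.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if pt_grid is None:
        pt_grid = np.arange(0.01, 0.601, 0.01)
    pt_grid = np.asarray(pt_grid, dtype=float)
    if np.any((pt_grid <= 0) | (pt_grid >= 1)):
        raise ValueError("pt thresholds must lie in (0, 1)")
    n = len(labels)
    prevalence = labels.mean()
    nb_model = np.empty_like(pt_grid)
    for i, pt in enumerate(pt_grid):
        pred = probabilities >= pt
        tp = np.count_nonzero(pred & (labels == 1))
        fp = np.count_nonzero(pred & (labels == 0))
        nb_model[i] = tp / n - (pt / (1 - pt)) * fp / n
    nb_all = prevalence - (1 - prevalence) * pt_grid / (1 - pt_grid)
    nb_none = np.zeros_like(pt_grid)
    return DecisionCurve(pt=pt_grid, nb_model=nb_model, nb_all=nb_all, nb_none=nb_none)


def cv_logistic_scores(
    X: np.ndarray,
    y: np.ndarray,
    feature_indices: Sequence[int],
    folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Pooled out-of-fold probabilities of a logistic model on a fixed
    feature set.  This single routine backs both the GA fitness and the
    reported CV metrics, so the two agree exactly."""
    idx = np.asarray(feature_indices, dtype=int)
    y = np.asarray(y, dtype=int)
    out = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        model = fit_logistic(X[tr][:, idx], labels=y[tr])
        out[te] = model.predict_proba(X[te][:, idx])
    return out


def cv_logistic_auc(
    X: np.ndarray,
    y: np.ndarray,
    feature_indices: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    pooled: bool = True,
) -> float:
    """Cross-validated AUC of a logistic model on a fixed feature set."""
    if len(feature_indices) == 0:
        return 0.5
    if pooled:
        scores = cv_logistic_scores(X, y, feature_indices, folds, seed)
        return roc_auc(scores, y).auc
    idx = np.asarray(feature_indices, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        model = fit_logistic(X[tr][:, idx], labels=y[tr])
        aucs.append(roc_auc(model.predict_proba(X[te][:, idx]), y[te]).auc)
    return float(np.mean(aucs))


def evaluate_pipeline(
    table: FeatureTable,
    split: SplitSpec,
    selector: str,
    config: RunConfig | None = None,
) -> tuple[EvalReport, dict]:
    """Run one selector end-to-end and assemble the full report.

    ``selector`` is one of ``galambda``, ``standard-ga``,
    ``conventional-lasso``.  Selection and model fitting see training rows
    only; CV metrics come from pooled out-of-fold predictions on the
    training set, test metrics from the single model fitted on all
    training rows and applied to the held-out rows.
    """
    from . import ga as _ga  # local import: ga depends on this module

    config = config or RunConfig()
    train = table.subset_rows(split.train_indices)
    test = table.subset_rows(split.test_indices)
    df_max = config.df_max(train.n_samples)

    if selector == "conventional-lasso":
        selected = _ga.conventional_lasso_select(
            train, config.alpha, config.rho, config.cv_folds, df_max,
            config.stage_seed("lasso"),
        )
    elif selector == "galambda":
        best, _ = _ga.evolve(train, config)
        selected = np.asarray(best.final_features, dtype=int)
    elif selector == "standard-ga":
        selected = _ga.standard_ga_select(train, config)
    else:
        raise ValueError(f"unknown selector {selector!r}")
    selected = np.asarray(selected, dtype=int)

    eval_seed = config.stage_seed("evaluation")
    if len(selected) == 0:
        logger.warning("%s selected no features; reporting chance level", selector)
        cv_scores = np.full(train.n_samples, 0.5)
        test_scores = np.full(test.n_samples, 0.5)
        model = None
    else:
        cv_scores = cv_logistic_scores(
            train.values, train.labels, selected, config.cv_folds, eval_seed
        )
        model = fit_logistic(train, selected)
        test_scores = model.predict_proba(test.values[:, selected])

    def _auc(s: np.ndarray, l: np.ndarray) -> float:
        return roc_auc(s, l).auc

    def _youden_acc(s: np.ndarray, l: np.ndarray) -> float:
        return youden_accuracy(roc_auc(s, l), s, l)[1]

    cv_curve = roc_auc(cv_scores, train.labels)
    test_curve = roc_auc(test_scores, test.labels)
    thr_cv, acc_cv = youden_accuracy(cv_curve, cv_scores, train.labels)
    thr_te, acc_te = youden_accuracy(test_curve, test_scores, test.labels)

    ci = {}
    for key, (s, l) in {
        "cv_auc": (cv_scores, train.labels),
        "cv_accuracy": (cv_scores, train.labels),
        "test_auc": (test_scores, test.labels),
        "test_accuracy": (test_scores, test.labels),
    }.items():
        metric = _auc if key.endswith("auc") else _youden_acc
        ci[key] = bootstrap_ci(
            metric, s, l, config.bootstrap_samples, config.ci_level, eval_seed
        )

    report = EvalReport(
        selector=selector,
        selected=tuple(int(i) for i in selected),
        selected_names=tuple(table.feature_names[i] for i in selected),
        cv_auc=cv_curve.auc,
        cv_accuracy=acc_cv,
        test_auc=test_curve.auc,
        test_accuracy=acc_te,
        ci=ci,
        youden_threshold_cv=thr_cv,
        youden_threshold_test=thr_te,
    )
    curves = {
        "roc_cv": cv_curve,
        "roc_test": test_curve,
        "decision_test": decision_curve(test_scores, test.labels),
        "cv_scores": cv_scores,
        "test_scores": test_scores,
    }
    return report, curves
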
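"""Candidate-feature preselection: rank-sum screening + correlation pruning.

Radiomic feature spaces are heavily redundant, so before any combinatorial
search two filters are applied on the TRAINING rows only:

1. a two-sided Mann-Whitney U test per feature against the binary outcome;
   features with p >= alpha are dropped (no multiple-testing correction —
   this is a deliberately permissive screen, default alpha = 0.05);
2. iterative Pearson-correlation pruning: while any surviving pair has
   |r| >= rho (default 0.8), the pair with the largest |r| is examined and
   the member with the higher mean absolute correlation to all current
   survivors is removed.

A small grid search over (alpha, rho), scored by cross-validated AUC of
the conventional lasso-plus-logistic pipeline, reproduces the threshold
tuning used for the conventional baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .datamodel import FeatureTable

logger = logging.getLogger("galambda")

__all__ = [
    "PreselectionResult",
    "mann_whitney_u",
    "correlation_prune",
    "preselect",
    "grid_search_thresholds",
]


@dataclass(frozen=True)
class PreselectionResult:
    kept_indices: tuple[int, ...]
    p_values: np.ndarray
    dropped_by_test: tuple[int, ...]
    dropped_by_correlation: tuple[int, ...]
    thresholds_used: tuple[float, float]


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two samples.

    Uses the exact null distribution when ``m * n <= 400`` and there are
    no ties, otherwise the normal approximation with tie and continuity
    correction.  Returns ``(U, p)`` where U is the statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) * len(y) <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _feature_p_values(table: FeatureTable) -> np.ndarray:
    pos = table.labels == 1
    p = np.empty(table.n_features)
    for j in range(table.n_features):
        col = table.values[:, j]
        if np.ptp(col) == 0:
            p[j] = 1.0  # constant feature can never discriminate
            continue
        _, p[j] = mann_whitney_u(col[pos], col[~pos])
    return p


def correlation_prune(
    table: FeatureTable, indices: np.ndarray, rho_threshold: float
) -> np.ndarray:
    """Iteratively remove one member of every strongly correlated pair.

    While any surviving pair has ``|r| >= rho_threshold``: take the pair
    with the largest |r| (ties broken lexicographically) and drop the
    member whose mean absolute correlation to all current survivors is
    higher (ties: drop the later index).  Constant features are dropped
    up front.  Deterministic.
    """
    if not (0 < rho_threshold <= 1):
        raise ValueError("rho_threshold must lie in (0, 1]")
    indices = np.asarray(indices, dtype=int)
    if len(indices) <= 1:
        return indices.copy()
    X = table.values[:, indices]
    const = np.ptp(X, axis=0) == 0
    if const.any():
        logger.warning("dropping %d constant features before pruning", const.sum())
    alive = np.flatnonzero(~const)
    if len(alive) <= 1:
        return indices[alive]
    C = np.abs(np.corrcoef(X[:, alive], rowvar=False))
    np.fill_diagonal(C, 0.0)
    keep = list(range(len(alive)))
    while True:
        sub = C[np.ix_(keep, keep)]
        if sub.size == 0 or sub.max() < rho_threshold:
            break
        a, b = np.unravel_index(np.argmax(sub), sub.shape)
        if a > b:
            a, b = b, a
        mean_a = sub[a].sum() / (len(keep) - 1)
        mean_b = sub[b].sum() / (len(keep) - 1)
        victim = b if mean_b >= mean_a else a
        del keep[victim]
    return indices[alive[np.asarray(keep, dtype=int)]]


def preselect(
    table: FeatureTable, alpha: float = 0.05, rho: float = 0.8
) -> PreselectionResult:
    """U-test screen then correlation pruning on a (training) table."""
    p = _feature_p_values(table)
    pass_test = np.flatnonzero(p < alpha)
    dropped_test = np.flatnonzero(p >= alpha)
    kept = correlation_prune(table, pass_test, rho)
    dropped_corr = np.setdiff1d(pass_test, kept)
    return PreselectionResult(
        kept_indices=tuple(int(i) for i in kept),
        p_values=p,
        dropped_by_test=tuple(int(i) for i in dropped_test),
        dropped_by_correlation=tuple(int(i) for i in dropped_corr),
        thresholds_used=(float(alpha), float(rho)),
    )


def write_report(
    result: PreselectionResult,
    feature_names: tuple[str, ...],
    path,
) -> None:
    """Write the preselection outcome (per-feature p-value and fate) as
    delimited text."""
    import pandas as pd

    fate = {}
    for i in result.kept_indices:
        fate[i] = "kept"
    for i in result.dropped_by_test:
        fate[i] = "dropped_by_test"
    for i in result.dropped_by_correlation:
        fate[i] = "dropped_by_correlation"
    df = pd.DataFrame(
        {
            "feature": list(feature_names),
            "p_value": result.p_values,
            "fate": [fate[i] for i in range(len(feature_names))],
        }
    )
    df.to_csv(path, index=False)


def grid_search_thresholds(
    table: FeatureTable,
    alpha_grid: tuple[float, ...] = (0.01, 0.025, 0.05, 0.075, 0.10),
    rho_grid: tuple[float, ...] = (0.70, 0.75, 0.80, 0.85, 0.90),
    folds: int = 5,
    seed: int = 0,
    df_max: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Pick (alpha, rho) maximizing CV AUC of the conventional pipeline.

    For each grid point: within every CV fold, preselect on the fold's
    training rows, run the conventional lasso selection, fit a logistic
    model and score the held-out rows; the grid cell records the mean
    per-fold AUC.  Argmax ties resolve to smaller alpha, then smaller rho.
    A grid point with zero kept features in a fold contributes AUC 0.5.
    """
    from .evaluation import fit_logistic, roc_auc  # local: avoid cycle
    from .lasso import cv_lasso, selected_features

    if not alpha_grid or not rho_grid:
        raise ValueError("grids must be nonempty")
    y = table.labels
    if len(np.unique(y)) < 2:
        raise ValueError("table must contain both classes")
    surface = np.zeros((len(alpha_grid), len(rho_grid)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(table.values, y))
    for ia, alpha in enumerate(alpha_grid):
        for ir, rho in enumerate(rho_grid):
            aucs = []
            for tr, te in splits:
                train = table.subset_rows(tr)
                pres = preselect(train, alpha, rho)
                if not pres.kept_indices:
                    logger.warning(
                        "grid point (%.3g, %.3g): no features kept", alpha, rho
                    )
                    aucs.append(0.5)
                    continue
                cand = np.asarray(pres.kept_indices)
                fit = cv_lasso(
                    train.values[:, cand], train.labels, folds=folds,
                    seed=seed, df_max=df_max,
                )
                sel = cand[selected_features(fit, "min_mse")]
                if not len(sel):
                    aucs.append(0.5)
                    continue
                model = fit_logistic(train, sel)
                scores = model.predict_proba(table.values[te][:, sel])
                aucs.append(roc_auc(scores, y[te]).auc)
            surface[ia, ir] = float(np.mean(aucs))
    best_flat = np.argmax(surface)  # C order: ties -> smaller alpha then rho
    ia, ir = np.unravel_index(best_flat, surface.shape)
    return float(alpha_grid[ia]), float(rho_grid[ir]), surface
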
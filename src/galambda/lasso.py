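"""LASSO regularization path with cross-validation.

The model is the Gaussian (squared-error) lasso on a binary response,

    min_{b, beta}  sum_i (y_i - b - x_i' beta)^2 / (2N) + lambda * ||beta||_1,

fitted over a geometric lambda grid running from ``lambda_max`` — the
smallest penalty at which every coefficient is zero,
``max_j |x_j' (y - ybar)| / N`` for column-standardized X — down to
``lambda_max * lambda_min_ratio``.  The logistic model enters only later,
at fitness/evaluation time: selection here is two-stage by design.

Coefficient columns are stored with lambda ASCENDING, so the last column
belongs to the largest penalty and is identically zero.  The genetic
search reads this matrix from the high-penalty end to find the features
that survive strong shrinkage ("excellent genes").

The per-column minimization is delegated to scikit-learn's coordinate
descent (warm-started along the path, tolerance tight enough that the KKT
subgradient conditions hold to well below 1e-7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import _cd_fast as _cd
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.utils import check_random_state

__all__ = ["LassoFit", "lasso_path", "cv_lasso", "selected_features"]

_STD_TOL = 1e-6
# shared RNG for the cyclic (non-randomized) coordinate descent; unused
# state under cyclic updates, so sharing keeps results deterministic
_CD_RNG = check_random_state(0)


@dataclass
class LassoFit:
    """A lasso path: coefficients over an ascending lambda grid.

    ``B`` is ``nvars x nlambdas``; column ``j`` solves the problem at
    ``lambdas[j]``.  ``mse``/``index_min_mse`` are populated only by
    :func:`cv_lasso`.
    """

    B: np.ndarray
    intercepts: np.ndarray
    lambdas: np.ndarray
    mse: np.ndarray | None = None
    index_min_mse: int | None = None

    def __post_init__(self) -> None:
        if self.B.shape[1] != len(self.lambdas) or len(self.intercepts) != len(
            self.lambdas
        ):
            raise ValueError("inconsistent path dimensions")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambdas must be strictly increasing")

    @property
    def df(self) -> np.ndarray:
        """Number of nonzero coefficients per lambda."""
        return np.count_nonzero(self.B, axis=0)

    @property
    def min_mse(self) -> float:
        if self.mse is None or self.index_min_mse is None:
            raise ValueError("CV fields not populated")
        return float(self.mse[self.index_min_mse])


def _check_standardized(X: np.ndarray) -> None:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    # all-zero columns are tolerated: they arise when a fold's constant
    # column is centered, and their coefficient is necessarily zero
    zero_col = np.all(X == 0, axis=0)
    if np.any((sd < _STD_TOL) & ~zero_col):
        raise ValueError("degenerate all-constant column in X")
    bad = ~zero_col & ((np.abs(mu) > 1e-6) | (np.abs(sd - 1) > 1e-4))
    if np.any(bad):
        raise ValueError("X must be column-standardized (mean 0, sd 1)")


def standardize(
    X: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Column-standardize; constant columns are mapped to zeros (sd -> 1)."""
    if stats is None:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd < _STD_TOL, 1.0, sd)
        stats = (mu, sd)
    mu, sd = stats
    return (X - mu) / sd, stats


def _lambda_grid(
    X: np.ndarray, yc: np.ndarray, nlambdas: int, lambda_min_ratio: float
) -> np.ndarray:
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ yc)) / n
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, nlambdas)


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    nlambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    df_max: int | None = None,
    lambdas: np.ndarray | None = None,
) -> LassoFit:
    """Fit the full lasso path on standardized ``X``.

    ``y`` may be the raw 0/1 response; it is centered internally and the
    per-lambda intercept is its mean (X columns have mean zero).  If
    ``df_max`` is given, the path is truncated at the first lambda —
    walking from the largest down — whose solution exceeds ``df_max``
    nonzero coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_standardized(X)
    if nlambdas < 2:
        raise ValueError("nlambdas must be >= 2")
    ybar = y.mean()
    yc = y - ybar
    if lambdas is None:
        grid_desc = _lambda_grid(X, yc, nlambdas, lambda_min_ratio)
    else:
        grid_desc = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    # Walk the descending grid with warm starts, one coordinate-descent
    # solve per lambda, so that a df cap stops computation early: the slow
    # small-lambda tail of a p > n path is never solved once the cap trips.
    n, p = X.shape
    Xf = np.asfortranarray(X)
    tol_scaled = 1e-12 * float(yc @ yc)
    if tol_scaled == 0.0:
        tol_scaled = 1e-12
    w = np.zeros(p)
    coefs = np.empty((p, len(grid_desc)))
    k = 0
    for lam in grid_desc:
        w, _gap, _tol, _iters = _cd.enet_coordinate_descent(
            w, lam * n, 0.0, Xf, yc, 100_000, tol_scaled, _CD_RNG, False, False
        )
        coefs[:, k] = w
        k += 1
        if df_max is not None and np.count_nonzero(w) > df_max:
            break
    coefs = coefs[:, :k]
    grid_desc = grid_desc[:k]
    if df_max is not None:
        nz = np.count_nonzero(coefs, axis=0)
        over = np.flatnonzero(nz > df_max)
        if len(over):
            keep = over[0]  # descending order: truncate at the first violation
            if keep < 2:
                keep = 2
            grid_desc = grid_desc[:keep]
            coefs = coefs[:, :keep]
    order = np.argsort(grid_desc)  # ascending for storage
    lambdas_asc = grid_desc[order]
    B = coefs[:, order]
    intercepts = np.full(len(lambdas_asc), ybar)
    return LassoFit(B=B, intercepts=intercepts, lambdas=lambdas_asc)


def cv_lasso(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    df_max: int | None = None,
    nlambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    stratified: bool = True,
) -> LassoFit:
    """Lasso path with k-fold CV mean squared error per lambda.

    ``X`` is raw (unstandardized); standardization statistics are computed
    on the fitting rows only and applied to held-out rows, both for the
    full fit and within every fold.  The lambda grid is shared: it comes
    from the full fit.  ``index_min_mse`` points at the lambda minimizing
    the CV MSE; ties resolve to the larger lambda (sparser model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds < 2 or n < folds:
        raise ValueError("need 2 <= folds <= n")

    Xs, _ = standardize(X)
    full = lasso_path(Xs, y, nlambdas, lambda_min_ratio, df_max=df_max)
    grid = full.lambdas

    if stratified and len(np.unique(y)) == 2 and folds <= min(np.bincount(y.astype(int))):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y.astype(int))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X)

    sq_err = np.zeros((folds, len(grid)))
    for k, (tr, te) in enumerate(split_iter):
        Xtr, stats = standardize(X[tr])
        Xte, _ = standardize(X[te], stats)
        fit = lasso_path(Xtr, y[tr], lambdas=grid)
        pred = Xte @ fit.B + fit.intercepts  # (n_te, nlambdas)
        sq_err[k] = np.mean((pred - y[te][:, None]) ** 2, axis=0)
    mse = sq_err.mean(axis=0)
    # ties -> larger lambda: scan from the high-penalty end (last column)
    index_min = len(mse) - 1 - int(np.argmin(mse[::-1]))
    full.mse = mse
    full.index_min_mse = index_min
    return full


def selected_features(fit: LassoFit, at: int | float | str = "min_mse") -> np.ndarray:
    """Indices (ascending, 0-based) of nonzero coefficients at a lambda.

    ``at`` may be ``"min_mse"`` (requires CV fields), an integer column
    index, or a float lambda value present in the grid.
    """
    if isinstance(at, str):
        if at != "min_mse":
            raise ValueError("at must be 'min_mse', an index or a lambda value")
        if fit.index_min_mse is None:
            raise ValueError("CV fields not populated")
        col = fit.index_min_mse
    elif isinstance(at, (int, np.integer)):
        if not 0 <= at < len(fit.lambdas):
            raise IndexError("lambda index out of range")
        col = int(at)
    else:
        hits = np.flatnonzero(np.isclose(fit.lambdas, at, rtol=1e-12, atol=0))
        if not len(hits):
            raise ValueError("lambda value not on the grid")
        col = int(hits[0])
    return np.flatnonzero(fit.B[:, col] != 0)


def export_path(fit: LassoFit, path: str, feature_names: list[str] | None = None) -> None:
    """Dump (lambda, df, mse, coefficients) as delimited text for audit."""
    import pandas as pd

    p = fit.B.shape[0]
    names = feature_names or [f"x{j}" for j in range(p)]
    df = pd.DataFrame(
        {
            "lambda": fit.lambdas,
            "df": fit.df,
            "mse": fit.mse if fit.mse is not None else np.nan,
        }
    )
    for j, nm in enumerate(names):
        df[nm] = fit.B[j]
    df.to_csv(path, index=False)
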
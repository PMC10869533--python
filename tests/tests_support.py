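"""Independent numerical oracles shared across test modules.

These deliberately avoid the package's own code paths: the lasso oracle
is a from-scratch proximal-gradient solver, the AUC oracle counts
concordant pairs directly, and the KKT check evaluates the subgradient
conditions from their algebraic definition.
"""

import numpy as np


def fista_lasso(X, y, lam, iters=40000, tol=1e-12):
    """Proximal-gradient (FISTA) minimizer of
    ||y - Xb||^2 / (2n) + lam * ||b||_1 on centered y."""
    n, p = X.shape
    yc = y - y.mean()
    L = np.linalg.norm(X, 2) ** 2 / n
    b = np.zeros(p)
    z = b.copy()
    t = 1.0
    for _ in range(iters):
        g = X.T @ (X @ z - yc) / n
        b_new = z - g / L
        b_new = np.sign(b_new) * np.maximum(np.abs(b_new) - lam / L, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = b_new + (t - 1) / t_new * (b_new - b)
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            break
        b, t = b_new, t_new
    return b


def kkt_violation(X, y, B, lambdas):
    """Worst subgradient violation of the 1/(2n) lasso across columns:
    |x_j'r|/n <= lam for zero coefficients, x_j'r/n = lam*sign(b_j) else."""
    n = X.shape[0]
    yc = y - y.mean()
    worst = 0.0
    for k, lam in enumerate(lambdas):
        b = B[:, k]
        g = X.T @ (yc - X @ b) / n
        zero = b == 0
        if zero.any():
            worst = max(worst, np.max(np.abs(g[zero])) - lam)
        if (~zero).any():
            worst = max(worst, np.max(np.abs(g[~zero] - lam * np.sign(b[~zero]))))
    return worst


def pair_count_auc(scores, labels):
    """Concordant-pair AUC estimator, ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        total += np.sum(sp > neg) + 0.5 * np.sum(sp == neg)
    return total / (len(pos) * len(neg))
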
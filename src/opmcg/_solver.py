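"""Elastic-net logistic regression by coordinate descent, plus fast AUC.

Minimizes, for each penalty value lambda on a (descending, warm-started)
path,

    (1/n) sum_i log(1 + exp(-(2 y_i - 1) * (b0 + x_i' beta)))
        + lambda * (alpha * ||beta||_1 + (1 - alpha)/2 * ||beta||_2^2)

with an unpenalized intercept, via cyclic coordinate descent under the
standard quadratic majorization of the logistic loss (curvature bound 1/4).
Columns are expected standardized; a zero-variance column keeps a zero
coefficient.  alpha = 1 is the lasso, alpha = 0 ridge.

The kernels are numba-compiled: the stability-selection bootstrap runs this
solver tens of thousands of times (resamples x folds x path points), which
rules out per-fit Python overhead.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sigmoid(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def enet_logistic_path(X, y, lambdas, alpha, tol, max_iter):
    """Coefficient path over a descending lambda grid with warm starts.

    Each lambda is solved by iteratively reweighted least squares: the
    logistic loss is replaced by its local quadratic approximation (weights
    w = p(1-p), working response z = eta + (y - p)/w) and the penalized
    weighted least-squares problem is solved by cyclic coordinate descent.
    The sigmoid is evaluated once per outer reweighting, not once per
    coordinate, which is what makes the bootstrap affordable.

    Parameters
    ----------
    X : (n, p) float64, standardized feature matrix.
    y : (n,) float64 of 0/1 labels.
    lambdas : (L,) float64, fitted in the order given (pass descending).
    alpha : elastic-net mixing in [0, 1] (1 = lasso).
    tol : convergence threshold on the largest coefficient update.
    max_iter : cap on total inner coordinate sweeps per lambda.

    Returns
    -------
    intercepts : (L,) and coefs : (L, p).
    """
    n, p = X.shape
    L = lambdas.size
    intercepts = np.zeros(L)
    coefs = np.zeros((L, p))

    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        b0 = 0.0
    else:
        b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    eta = np.full(n, b0)

    w = np.empty(n)
    resid = np.empty(n)
    xtwx = np.empty(p)

    for li in range(L):
        lam = lambdas[li]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        sweeps_left = max_iter
        for _outer in range(50):
            # quadratic approximation at the current eta
            wsum = 0.0
            for i in range(n):
                pi = _sigmoid(eta[i])
                if pi < 1e-5:
                    pi = 1e-5
                elif pi > 1.0 - 1e-5:
                    pi = 1.0 - 1e-5
                w[i] = pi * (1.0 - pi)
                resid[i] = (y[i] - pi) / w[i]  # z - b0 - X beta
                wsum += w[i]
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                xtwx[j] = s / n

            outer_delta = 0.0
            active_only = False
            while sweeps_left > 0:
                sweeps_left -= 1
                maxd = 0.0
                # unpenalized intercept
                g0 = 0.0
                for i in range(n):
                    g0 += w[i] * resid[i]
                db = g0 / wsum
                if db != 0.0:
                    b0 += db
                    for i in range(n):
                        resid[i] -= db
                ad = abs(db)
                if ad > maxd:
                    maxd = ad
                for j in range(p):
                    if xtwx[j] <= 0.0:
                        continue
                    if active_only and beta[j] == 0.0:
                        continue
                    g = 0.0
                    for i in range(n):
                        g += w[i] * X[i, j] * resid[i]
                    g /= n
                    zj = g + xtwx[j] * beta[j]
                    if zj > l1:
                        bnew = (zj - l1) / (xtwx[j] + l2)
                    elif zj < -l1:
                        bnew = (zj + l1) / (xtwx[j] + l2)
                    else:
                        bnew = 0.0
                    d = bnew - beta[j]
                    if d != 0.0:
                        beta[j] = bnew
                        for i in range(n):
                            resid[i] -= X[i, j] * d
                        ad = abs(d)
                        if ad > maxd:
                            maxd = ad
                if maxd > outer_delta:
                    outer_delta = maxd
                if maxd < 0.1 * tol:
                    if active_only:
                        # active set converged; verify with a full sweep
                        active_only = False
                    else:
                        break
                else:
                    # iterate on the current nonzero set between full sweeps
                    active_only = True
            # rebuild eta = b0 + X beta exactly to avoid drift
            for i in range(n):
                s = b0
                for j in range(p):
                    if beta[j] != 0.0:
                        s += X[i, j] * beta[j]
                eta[i] = s
            if outer_delta < tol or sweeps_left <= 0:
                break
        intercepts[li] = b0
        coefs[li] = beta
    return intercepts, coefs


@njit(cache=True)
def fast_auc(y, scores):
    """Mann-Whitney AUC with midrank tie handling; NaN if one class absent."""
    n = y.size
    order = np.argsort(scores)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[order[j + 1]] == scores[order[i]]:
            j += 1
        midrank = 0.5 * (i + j) + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    n_pos = 0
    rank_sum = 0.0
    for i in range(n):
        if y[i] == 1.0:
            n_pos += 1
            rank_sum += ranks[i]
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    return (rank_sum - n_pos * (n_pos + 1.0) / 2.0) / (n_pos * n_neg)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize; zero-variance columns get sd 1 (stay zero)."""
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    return (X - means) / sds, means, sds
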
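"""Numba inner loops for coordinate-descent LASSO and leave-one-out CV.

All kernels work on Gram-matrix summaries (X'X, X'y), so one sweep of
cyclic coordinate descent costs O(m^2) independent of sample size, and a
leave-one-out fold is a rank-one downdate of the full-data Gram matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def soft_threshold_scalar(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


@njit(cache=True)
def cd_solve(gram, xty, n, lam, beta, tol, max_iter):
    """Cyclic coordinate descent on (1/(2n))||y - Xb||^2 + lam*||b||_1.

    Updates ``beta`` in place; returns the number of sweeps used, or -1
    if max_iter sweeps did not bring the max coefficient change under tol.
    The cyclic order is fixed (0..m-1), which deterministically prefers
    the lowest-index column among exact duplicates.
    """
    m = gram.shape[0]
    for it in range(max_iter):
        max_change = 0.0
        for j in range(m):
            denom = gram[j, j] / n
            if denom <= 0.0:
                beta[j] = 0.0
                continue
            # partial residual correlation for coordinate j
            gj = 0.0
            for k in range(m):
                gj += gram[j, k] * beta[k]
            rho = xty[j] / n - gj / n + denom * beta[j]
            new = soft_threshold_scalar(rho, lam) / denom
            change = abs(new - beta[j])
            if change > max_change:
                max_change = change
            beta[j] = new
        if max_change < tol:
            return it + 1
    return -1


@njit(cache=True)
def cd_path(gram, xty, n, lambdas, tol, max_iter):
    """Warm-started coordinate-descent fits along a decreasing penalty path."""
    m = gram.shape[0]
    L = lambdas.shape[0]
    betas = np.zeros((L, m))
    beta = np.zeros(m)
    for l in range(L):
        cd_solve(gram, xty, n, lambdas[l], beta, tol, max_iter)
        betas[l] = beta
    return betas


@njit(cache=True)
def loo_cv_mse(X, y, lambdas, tol, max_iter):
    """Leave-one-out CV squared errors, one column per path point.

    For each held-out row the full-data Gram summaries are downdated by
    that row's rank-one contribution, the path is refit with warm
    starts, and the held-out squared prediction error is recorded.
    Returns an (N, L) matrix of squared errors.
    """
    n, m = X.shape
    L = lambdas.shape[0]
    gram = X.T @ X
    xty = X.T @ y
    errs = np.zeros((n, L))
    for i in range(n):
        gram_i = gram - np.outer(X[i], X[i])
        xty_i = xty - X[i] * y[i]
        beta = np.zeros(m)
        for l in range(L):
            cd_solve(gram_i, xty_i, n - 1, lambdas[l], beta, tol, max_iter)
            pred = 0.0
            for j in range(m):
                pred += X[i, j] * beta[j]
            errs[i, l] = (y[i] - pred) ** 2
    return errs


@njit(cache=True)
def kfold_cv_mse(X, y, fold_ids, n_folds, lambdas, tol, max_iter):
    """Per-fold mean squared prediction error, (n_folds, L)."""
    n, m = X.shape
    L = lambdas.shape[0]
    gram = X.T @ X
    xty = X.T @ y
    fold_mse = np.zeros((n_folds, L))
    for f in range(n_folds):
        gram_f = gram.copy()
        xty_f = xty.copy()
        n_held = 0
        for i in range(n):
            if fold_ids[i] == f:
                gram_f -= np.outer(X[i], X[i])
                xty_f -= X[i] * y[i]
                n_held += 1
        beta = np.zeros(m)
        for l in range(L):
            cd_solve(gram_f, xty_f, n - n_held, lambdas[l], beta, tol, max_iter)
            sse = 0.0
            for i in range(n):
                if fold_ids[i] == f:
                    pred = 0.0
                    for j in range(m):
                        pred += X[i, j] * beta[j]
                    sse += (y[i] - pred) ** 2
            fold_mse[f, l] = sse / n_held
    return fold_mse
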
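"""Independent reference implementations used only to check the package.

Each oracle deliberately avoids the code path it verifies: exact
rational enumeration for the HWE test, a smooth box-constrained
reformulation solved by scipy for the LASSO, explicit projection
matrices for the partial F-test, and a from-scratch fold loop for
cross-validation.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np
from scipy import stats
from scipy.optimize import minimize


def hwe_enumeration_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by full rational enumeration of genotype tables.

    Conditional on allele counts, P(h heterozygotes) =
    n! / (a! h! b!) * 2^h * n_minor! n_major! / (2n)!; the p-value sums
    probabilities no larger than the observed table's.
    """
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    n_major = 2 * n - n_minor
    if n_minor == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        b = (n_minor - h) // 2
        a = n - h - b
        return (
            Fraction(factorial(n), factorial(a) * factorial(h) * factorial(b))
            * Fraction(2) ** h
            * Fraction(factorial(n_minor) * factorial(n_major), factorial(2 * n))
        )

    hets = range(n_minor % 2, min(n_minor, n_major) + 1, 2)
    p_obs = prob(n_Aa)
    return float(sum(p for h in hets if (p := prob(h)) <= p_obs))


def lasso_bruteforce(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve (1/(2N))||y - Xb||^2 + lam*||b||_1 via the split u-v program.

    With b = u - v, u,v >= 0 the objective is smooth under box
    constraints, solved by L-BFGS-B; independent of coordinate descent.
    """
    n, m = X.shape

    def f(z):
        u, v = z[:m], z[m:]
        b = u - v
        r = y - X @ b
        return r @ r / (2 * n) + lam * (u.sum() + v.sum())

    def grad(z):
        u, v = z[:m], z[m:]
        g = -X.T @ (y - X @ (u - v)) / n
        return np.concatenate([g + lam, -g + lam])

    res = minimize(
        f,
        np.zeros(2 * m),
        jac=grad,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * m),
        options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12},
    )
    z = res.x
    return z[:m] - z[m:]


def partial_f_projection(y: np.ndarray, S: np.ndarray, C: np.ndarray):
    """Partial F via explicit hat matrices P = X (X'X)^-1 X' (full-rank designs)."""
    n = y.size
    P_c = C @ np.linalg.solve(C.T @ C, C.T)
    full = np.hstack([C, S])
    P_f = full @ np.linalg.solve(full.T @ full, full.T)
    rss_r = float(y @ (np.eye(n) - P_c) @ y)
    rss_f = float(y @ (np.eye(n) - P_f) @ y)
    df1 = S.shape[1]
    df2 = n - full.shape[1]
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


def loo_cv_bruteforce(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Leave-one-out CV MSE curve with per-fold fits from scratch, no warm starts."""
    n = X.shape[0]
    errs = np.zeros((n, lambdas.size))
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        for l, lam in enumerate(lambdas):
            # the fold objective is normalized by the fold's own sample size
            b = lasso_bruteforce(Xi, yi, lam)
            errs[i, l] = (y[i] - X[i] @ b) ** 2
    return errs.mean(axis=0)
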
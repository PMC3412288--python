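"""Coordinate-descent LASSO with a penalty path and cross-validated selection.

The per-gene SNP filter: standardize a gene's dosage columns, fit the
L1-penalized least-squares path

    (1/(2N)) ||y - X beta||^2 + lambda ||beta||_1

by cyclic coordinate descent with warm starts, pick the penalty that
minimizes leave-one-out cross-validated mean squared error (ties go to
the larger penalty, i.e. the sparser model; no 1-SE rule), and return
the nonzero support with coefficients back-transformed to the original
dosage scale.

The 1/(2N) factor keeps lambda comparable across sample sizes and
matches the parameterization of the standard coordinate-descent
software for this model; lambda values are internal plumbing, never a
scientific output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 10_000
DEFAULT_N_POINTS = 100
DEFAULT_PATH_RATIO = 1e-3


class ConvergenceError(RuntimeError):
    """Coordinate descent hit max_iter; carries the final KKT violation."""

    def __init__(self, kkt_violation: float, max_iter: int):
        self.kkt_violation = kkt_violation
        super().__init__(
            f"coordinate descent did not converge in {max_iter} sweeps "
            f"(KKT violation {kkt_violation:.3e})"
        )


@dataclass
class LassoFit:
    """Result of CV-selected LASSO on one gene's dosage columns.

    ``beta`` is on the original dosage scale (per extra minor allele),
    length = number of input columns, zeros for dropped/unselected SNPs.
    """

    beta: np.ndarray
    lambda_path: np.ndarray
    cv_mse: np.ndarray
    lambda_star: float
    selected: np.ndarray  # int indices into the original columns
    dropped_constant: list[int] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return int(self.selected.size)


def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0), the scalar L1 proximal map."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return float(np.sign(z) * max(abs(z) - gamma, 0.0))


def kkt_violation(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """Worst-case violation of the LASSO stationarity conditions.

    For the (1/(2N)) objective: |x_j'r/N| <= lam for zero coefficients
    and x_j'r/N = lam * sign(beta_j) for nonzero ones (r = residual).
    """
    n = X.shape[0]
    g = X.T @ (y - X @ beta) / n
    viol = 0.0
    for j in range(beta.size):
        if beta[j] == 0.0:
            viol = max(viol, abs(g[j]) - lam)
        else:
            viol = max(viol, abs(g[j] - lam * np.sign(beta[j])))
    return max(viol, 0.0)


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    beta0: np.ndarray | None = None,
) -> np.ndarray:
    """Solve one penalized least-squares problem by cyclic coordinate descent.

    ``X`` should have standardized columns (constant columns excluded
    beforehand) and ``y`` should be centered; the solver itself only
    requires finite inputs. Raises :class:`ConvergenceError` if max_iter
    sweeps do not converge.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    n, m = X.shape
    gram = X.T @ X
    xty = X.T @ y
    beta = np.zeros(m) if beta0 is None else beta0.astype(float).copy()
    sweeps = _kernels.cd_solve(gram, xty, n, lam, beta, tol, max_iter)
    if sweeps < 0:
        raise ConvergenceError(kkt_violation(X, y, beta, lam), max_iter)
    return beta


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the all-zero vector is optimal: ||X'y||_inf / N."""
    return float(np.abs(X.T @ y).max()) / X.shape[0]


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    n_points: int = DEFAULT_N_POINTS,
    ratio: float = DEFAULT_PATH_RATIO,
) -> np.ndarray:
    """Log-spaced decreasing path from lambda_max down to ratio * lambda_max.

    If y is orthogonal to every column (lambda_max = 0) the path is the
    single point 0, where the all-zero vector is already optimal.
    """
    lmax = lambda_max(X, y)
    if lmax == 0.0:
        return np.array([0.0])
    return np.geomspace(lmax, ratio * lmax, n_points)


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_folds: int | None = None,
    seed: int | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[float, np.ndarray]:
    """Choose the penalty by cross-validated mean squared error.

    Leave-one-out by default (``n_folds=None``), which is deterministic;
    k-fold uses ``seed`` for the fold assignment. Ties in CV error go to
    the larger penalty (the sparser model). Returns (lambda_star, cv_mse
    per path point).
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("cross-validation requires N >= 3")
    if lambdas is None:
        lambdas = lambda_path(X, y)
    lambdas = np.ascontiguousarray(lambdas, dtype=float)
    if n_folds is None:
        errs = _kernels.loo_cv_mse(X, y, lambdas, tol, max_iter)
        cv_mse = errs.mean(axis=0)
    else:
        if n < n_folds:
            raise ValueError(f"N={n} too small for {n_folds} folds")
        rng = np.random.default_rng(seed)
        fold_ids = np.asarray(rng.permutation(np.arange(n) % n_folds), dtype=np.int64)
        fold_mse = _kernels.kfold_cv_mse(X, y, fold_ids, n_folds, lambdas, tol, max_iter)
        cv_mse = fold_mse.mean(axis=0)
    # path is decreasing, argmin takes the first (largest-lambda) minimizer
    lambda_star = float(lambdas[int(np.argmin(cv_mse))])
    return lambda_star, cv_mse


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Center and unit-scale columns; flags constant columns for exclusion.

    Returns (Z, means, sds, constant_mask); constant columns come back
    as zeros with sd set to 1 so the caller can drop them.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    const = sds == 0.0
    safe_sds = np.where(const, 1.0, sds)
    Z = (X - means) / safe_sds
    Z[:, const] = 0.0
    return Z, means, safe_sds, const


def select_snps(
    G_gene: np.ndarray,
    y_resid: np.ndarray,
    n_points: int = DEFAULT_N_POINTS,
    ratio: float = DEFAULT_PATH_RATIO,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LassoFit:
    """CV-selected LASSO on one gene's dosage columns.

    ``y_resid`` is the covariate-adjusted phenotype (genotypes are not
    residualized). Standardization happens internally and coefficients
    are back-transformed to the per-minor-allele dosage scale. A gene
    whose columns are all constant yields an empty selection.
    """
    G_gene = np.asarray(G_gene, dtype=float)
    if G_gene.ndim == 1:
        G_gene = G_gene.reshape(-1, 1)
    y = np.asarray(y_resid, dtype=float)
    y_c = y - y.mean()
    Z, _, sds, const = standardize_columns(G_gene)
    keep = ~const
    dropped = list(np.where(const)[0])
    if dropped:
        logger.info("dropped %d constant genotype column(s) before LASSO", len(dropped))
    m_total = G_gene.shape[1]
    if not keep.any():
        return LassoFit(
            beta=np.zeros(m_total),
            lambda_path=np.array([0.0]),
            cv_mse=np.array([float(np.mean(y_c**2))]),
            lambda_star=0.0,
            selected=np.array([], dtype=int),
            dropped_constant=dropped,
        )
    Zk = np.ascontiguousarray(Z[:, keep])
    lambdas = lambda_path(Zk, y_c, n_points=n_points, ratio=ratio)
    if lambdas.size == 1 and lambdas[0] == 0.0:
        # y orthogonal to every column: all-zero fit
        return LassoFit(
            beta=np.zeros(m_total),
            lambda_path=lambdas,
            cv_mse=np.array([float(np.mean(y_c**2))]),
            lambda_star=0.0,
            selected=np.array([], dtype=int),
            dropped_constant=dropped,
        )
    lambda_star, cv_mse = cv_select_lambda(Zk, y_c, lambdas=lambdas, tol=tol, max_iter=max_iter)
    beta_std = lasso_fit(Zk, y_c, lambda_star, tol=tol, max_iter=max_iter)
    # numerical support threshold: exact-duplicate columns leave O(eps)
    # residue on the higher-index copy, which is not a real selection
    floor = 1e-10 * max(1.0, float(np.abs(beta_std).max()))
    beta_std[np.abs(beta_std) < floor] = 0.0
    beta = np.zeros(m_total)
    beta[np.where(keep)[0]] = beta_std / sds[keep]
    selected = np.where(beta != 0.0)[0]
    return LassoFit(
        beta=beta,
        lambda_path=lambdas,
        cv_mse=cv_mse,
        lambda_star=lambda_star,
        selected=selected,
        dropped_constant=dropped,
    )
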
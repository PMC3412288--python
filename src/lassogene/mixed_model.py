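"""Mixed-model partial F-tests for related samples (twin/sibling cohorts).

The variance model is y = C a + S b + g + e with g ~ N(0, sigma_g^2 K)
for a kinship matrix K and e ~ N(0, sigma_e^2 I). The variance ratio
delta = sigma_e^2 / sigma_g^2 is estimated once by REML under the
reduced (covariates-only) model on the eigenbasis of K, then all data
are whitened by (sigma_g^2 K + sigma_e^2 I)^(-1/2) and the ordinary
partial F machinery is applied to the whitened data. Estimating the
variance components a single time under the null and reusing them for
every test is the standard single-component approximation that keeps
genome-wide scans tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .assoc import partial_f_test
from .datatypes import GenotypeMatrix

DELTA_GRID = np.geomspace(1e-5, 1e5, 100)


@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix aligned to the cohort's subjects."""

    K: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.subject_ids)
        if self.K.shape != (n, n):
            raise ValueError("kinship shape does not match subject ids")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("kinship matrix is not positive semidefinite")

    def eigendecompose(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (clipped at 0) and eigenvectors; compute once per cohort."""
        w, U = np.linalg.eigh(self.K)
        return np.clip(w, 0.0, None), U


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2


def kinship_from_genotypes(G: GenotypeMatrix) -> KinshipMatrix:
    """Realized relationship matrix K = Z Z' / M from standardized dosages.

    Constant SNPs are excluded from the standardization. The diagonal is
    ~1 in expectation for outbred samples.
    """
    Z = G.dosages - G.dosages.mean(axis=0)
    sd = Z.std(axis=0)
    ok = sd > 0
    if ok.sum() < 2:
        raise ValueError("kinship estimation needs at least 2 polymorphic SNPs")
    Z = Z[:, ok] / sd[ok]
    K = Z @ Z.T / ok.sum()
    K = (K + K.T) / 2.0
    return KinshipMatrix(K=K, subject_ids=list(G.subject_ids))


def _reml_loglik(delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    """REML log-likelihood (up to constants) at variance ratio delta.

    ``xi`` are the nonzero-space eigenvalues of the projected kinship
    S K S (S the residual-maker of the reduced design) and ``eta2`` the
    squared rotated residuals; both have length n - rank(X).
    """
    q = xi.size
    denom = xi + delta
    return -0.5 * (q * np.log(np.sum(eta2 / denom)) + np.sum(np.log(denom)))


def reml_delta(y: np.ndarray, X_design: np.ndarray, kinship: KinshipMatrix) -> VarianceComponents:
    """REML estimate of (sigma_g^2, sigma_e^2) under the design X_design.

    Profiles the likelihood over delta on a log grid in [1e-5, 1e5] with
    local refinement. A likelihood flat up to the upper bound (no
    detectable genetic variance) returns the bound with a warning, which
    makes the downstream whitened test coincide with OLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X_design, dtype=float)
    n = y.size
    rank_x = int(np.linalg.matrix_rank(X))
    q = n - rank_x
    if q < 2:
        raise ValueError("too few residual degrees of freedom for REML")
    Qx, _ = np.linalg.qr(X)
    SKS = kinship.K - Qx @ (Qx.T @ kinship.K)
    SKS = SKS - (SKS @ Qx) @ Qx.T
    SKS = (SKS + SKS.T) / 2.0
    w, U = np.linalg.eigh(SKS)
    # keep the q eigenpairs spanning the residual space (largest eigenvalues)
    order = np.argsort(w)[::-1][:q]
    xi = np.clip(w[order], 0.0, None)
    eta = U[:, order].T @ y
    eta2 = eta**2
    ll = np.array([_reml_loglik(d, xi, eta2) for d in DELTA_GRID])
    best = int(np.argmax(ll))
    lo = DELTA_GRID[max(best - 1, 0)]
    hi = DELTA_GRID[min(best + 1, DELTA_GRID.size - 1)]
    res = minimize_scalar(
        lambda t: -_reml_loglik(np.exp(t), xi, eta2),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
    )
    delta = float(np.exp(res.x))
    if _reml_loglik(delta, xi, eta2) < ll[best]:
        delta = float(DELTA_GRID[best])
    if best == DELTA_GRID.size - 1:
        warnings.warn(
            "REML likelihood maximal at the upper delta bound; genetic variance "
            "indistinguishable from zero, test reduces to OLS",
            RuntimeWarning,
        )
        delta = float(DELTA_GRID[-1])
    sigma_g2 = float(np.sum(eta2 / (xi + delta)) / q)
    return VarianceComponents(sigma_g2=sigma_g2, sigma_e2=delta * sigma_g2, delta=delta)


def whitening_matrix(kinship: KinshipMatrix, vc: VarianceComponents) -> np.ndarray:
    """(sigma_g^2 K + sigma_e^2 I)^(-1/2) via the eigenbasis of K, rescaled.

    The overall variance scale cancels in the F statistic, so the
    whitener is normalized to (K + delta I)^(-1/2); only the ratio delta
    matters.
    """
    w, U = kinship.eigendecompose()
    d = w + vc.delta
    if np.any(d <= 0):
        raise ValueError("singular marginal covariance; delta too small for this K")
    return (U / np.sqrt(d)) @ U.T


def mixed_partial_f_test(
    y: np.ndarray,
    S: np.ndarray,
    C: np.ndarray,
    kinship: KinshipMatrix,
    vc: VarianceComponents | None = None,
) -> tuple[float, int, int, float]:
    """Partial F-test of the SNP block S under the kinship variance model.

    Variance components are estimated by REML under the reduced
    (covariates-only) model unless supplied, then y, S and C are
    whitened and passed to the ordinary partial F-test. With K = I the
    whitener is a scalar multiple of the identity and the result equals
    the OLS partial F exactly.
    """
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    if vc is None:
        vc = reml_delta(y, C, kinship)
    W = whitening_matrix(kinship, vc)
    return partial_f_test(W @ y, W @ np.asarray(S, dtype=float), W @ C)


def read_snp_list(path: str) -> list[str]:
    """One snp_id per line; the discovery-selected set for replication mode."""
    with open(path) as fh:
        snps = [line.strip() for line in fh if line.strip()]
    if not snps:
        raise ValueError(f"SNP list {path} is empty")
    return snps
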
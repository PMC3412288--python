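"""Joint multi-SNP association tests and the univariate GWAS baseline.

The gene-level test compares nested linear models by a partial F-test:
the full model contains the LASSO-selected SNP dosages plus covariates,
the reduced model only the covariates. The LASSO is purely a filter —
the full model re-fits all coefficients by least squares. Gene-level
genome-wide significance uses a Bonferroni threshold alpha / n_genes.

Two nested cross-validation schemes are provided for sensitivity
analysis: selection in a fifth of the sample with testing in the rest
(averaged over the five folds), and selection/testing in random halves
(averaged over trials).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import GeneMap, GenotypeMatrix, PhenotypeFrame
from .lasso import select_snps

logger = logging.getLogger(__name__)

#: Smallest positive normal double; the documented p-value floor.
P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class GeneTestResult:
    gene_id: str
    n_snps_total: int
    n_snps_selected: int
    F: float
    df1: int
    df2: int
    p: float
    significant: bool
    selected_snp_ids: list[str] | None = None


@dataclass
class UnivariateResult:
    snp_id: str
    beta: float
    t: float
    p: float


def design_with_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept column prepended to the covariate block (empty block allowed)."""
    ones = np.ones((n, 1))
    if covariates is None or covariates.size == 0:
        return ones
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C.reshape(-1, 1)
    return np.hstack([ones, C])


def residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Least-squares residual of y on the columns of C."""
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


def partial_f_test(
    y: np.ndarray, S: np.ndarray, C: np.ndarray
) -> tuple[float, int, int, float]:
    """Partial F-test of the SNP block S given covariates C (incl. intercept).

    F = ((RSS_reduced - RSS_full)/df1) / (RSS_full/df2), with df1 the
    rank of S after projecting out C and df2 = N - rank(C) - df1.
    Columns of S aliased with C (or with earlier S columns) are dropped
    in column order and logged; if everything is aliased, df1 = 0 and
    p = 1 by the empty-selection convention. A perfect full-model fit
    returns the documented p floor with a warning.
    """
    y = np.asarray(y, dtype=float)
    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S.reshape(-1, 1)
    C = np.asarray(C, dtype=float)
    n = y.shape[0]
    rank_c = int(np.linalg.matrix_rank(C))
    if n <= rank_c + S.shape[1]:
        raise ValueError(
            f"N={n} too small for {rank_c} covariate and {S.shape[1]} SNP parameters"
        )
    # project the SNP block off the covariates and drop aliased columns
    Qc, _ = np.linalg.qr(C)
    S_perp = S - Qc @ (Qc.T @ S)
    scale = max(float(np.abs(S_perp).max()), 1.0)
    keep_cols: list[int] = []
    basis: list[np.ndarray] = []
    for j in range(S_perp.shape[1]):
        v = S_perp[:, j].copy()
        for b in basis:
            v -= b * (b @ S_perp[:, j])
        nv = np.linalg.norm(v)
        if nv > 1e-8 * scale * np.sqrt(n):
            basis.append(v / nv)
            keep_cols.append(j)
    df1 = len(keep_cols)
    n_dropped = S.shape[1] - df1
    if n_dropped:
        logger.info("dropped %d aliased SNP column(s) from the full model", n_dropped)
    df2 = n - rank_c - df1
    rss_reduced = float(np.sum((y - Qc @ (Qc.T @ y)) ** 2))
    if df1 == 0:
        return 0.0, 0, df2, 1.0
    full = np.hstack([C, S[:, keep_cols]])
    r_full = residualize(y, full)
    rss_full = float(r_full @ r_full)
    if rss_full <= 0.0 or rss_full < 1e-14 * rss_reduced:
        warnings.warn("full model fits perfectly; p-value floored", RuntimeWarning)
        return float("inf"), df1, df2, P_FLOOR
    F = ((rss_reduced - rss_full) / df1) / (rss_full / df2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1, df2))
    return F, df1, df2, max(p, P_FLOOR)


def bonferroni_gene_threshold(alpha: float = 0.05, n_genes: int = 1) -> float:
    """Genome-wide gene-level significance threshold alpha / n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    return alpha / n_genes


def genotype_pcs(G: GenotypeMatrix, k: int = 4) -> np.ndarray:
    """Top-k principal components of the standardized dosage matrix.

    A stand-in for ancestry/population-structure covariates (MDS-style
    axes); constant SNPs contribute nothing.
    """
    Z = G.dosages - G.dosages.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Z / sd
    k = min(k, min(Z.shape) - 1)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    return U[:, :k] * s[:k]


def _gene_blocks(G: GenotypeMatrix, gene_map: GeneMap) -> dict[str, list[int]]:
    idx = G.snp_index()
    blocks = {}
    for gene, snps in gene_map.by_gene().items():
        cols = [idx[s] for s in snps if s in idx]
        if cols:
            blocks[gene] = cols
    return blocks


def gene_scan(
    G: GenotypeMatrix,
    gene_map: GeneMap,
    P: PhenotypeFrame,
    alpha: float = 0.05,
    n_genes: int | None = None,
) -> list[GeneTestResult]:
    """Per-gene LASSO selection followed by a joint partial F-test.

    The phenotype is residualized on the covariates before selection;
    the F-test then re-fits selected SNPs together with covariates in
    the full model against a covariates-only reduced model. Results are
    sorted by p (ties by gene id). ``n_genes`` sets the Bonferroni
    denominator (default: number of genes scanned).
    """
    if G.n_subjects != P.n_subjects or G.subject_ids != P.subject_ids:
        raise ValueError("genotypes and phenotypes are not subject-aligned; join first")
    C = design_with_intercept(P.covariates, P.n_subjects)
    y = P.phenotype
    y_resid = residualize(y, C)
    blocks = _gene_blocks(G, gene_map)
    threshold = bonferroni_gene_threshold(alpha, n_genes if n_genes is not None else len(blocks))
    results: list[GeneTestResult] = []
    for gene, cols in blocks.items():
        fit = select_snps(G.dosages[:, cols], y_resid)
        if fit.n_selected == 0:
            results.append(
                GeneTestResult(
                    gene_id=gene,
                    n_snps_total=len(cols),
                    n_snps_selected=0,
                    F=0.0,
                    df1=0,
                    df2=P.n_subjects - C.shape[1],
                    p=1.0,
                    significant=False,
                    selected_snp_ids=[],
                )
            )
            continue
        sel_cols = [cols[j] for j in fit.selected]
        F, df1, df2, p = partial_f_test(y, G.dosages[:, sel_cols], C)
        results.append(
            GeneTestResult(
                gene_id=gene,
                n_snps_total=len(cols),
                n_snps_selected=fit.n_selected,
                F=F,
                df1=df1,
                df2=df2,
                p=p,
                significant=p <= threshold,
                selected_snp_ids=[G.snp_ids[c] for c in sel_cols],
            )
        )
    results.sort(key=lambda r: (r.p, r.gene_id))
    return results


def univariate_scan(G: GenotypeMatrix, P: PhenotypeFrame) -> list[UnivariateResult]:
    """Single-SNP additive tests with covariates: per-SNP t on the dosage slope.

    Computed by the Frisch-Waugh identity: both phenotype and dosage are
    residualized on the covariates+intercept, and the slope t-test uses
    df = N - rank(C) - 1. Constant SNPs return t = 0, p = 1.
    """
    C = design_with_intercept(P.covariates, P.n_subjects)
    Qc, _ = np.linalg.qr(C)
    rank_c = int(np.linalg.matrix_rank(C))
    y_perp = P.phenotype - Qc @ (Qc.T @ P.phenotype)
    G_perp = G.dosages - Qc @ (Qc.T @ G.dosages)
    df = P.n_subjects - rank_c - 1
    out: list[UnivariateResult] = []
    yy = float(y_perp @ y_perp)
    for j, snp in enumerate(G.snp_ids):
        g = G_perp[:, j]
        gg = float(g @ g)
        if gg <= 1e-12 * P.n_subjects:
            out.append(UnivariateResult(snp, 0.0, 0.0, 1.0))
            continue
        beta = float(g @ y_perp) / gg
        rss = yy - beta * beta * gg
        rss = max(rss, 0.0)
        if rss == 0.0:
            out.append(UnivariateResult(snp, beta, float("inf"), P_FLOOR))
            continue
        se = np.sqrt(rss / df / gg)
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        out.append(UnivariateResult(snp, beta, t, max(p, P_FLOOR)))
    return out


def gene_min_p(results: list[UnivariateResult], gene_map: GeneMap) -> dict[str, float]:
    """Per-gene minimum univariate p over the gene's member SNPs."""
    by_snp = {r.snp_id: r.p for r in results}
    out = {}
    for gene, snps in gene_map.by_gene().items():
        ps = [by_snp[s] for s in snps if s in by_snp]
        if ps:
            out[gene] = min(ps)
    return out


def nested_cv_scan(
    G: GenotypeMatrix,
    gene_map: GeneMap,
    P: PhenotypeFrame,
    scheme: str = "fifth_folds",
    n_trials: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Out-of-sample select-then-test: averaged per-gene p-values.

    ``fifth_folds``: SNP selection in one fifth of the subjects, the
    partial F-test in the remaining four fifths, averaged over the five
    folds. ``half_split``: selection in a random half, testing in the
    other half, averaged over ``n_trials`` trials. A split with an empty
    selection contributes p = 1. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = P.n_subjects
    if scheme == "fifth_folds":
        perm = rng.permutation(n)
        splits = [
            (np.sort(perm[f::5]), np.sort(np.concatenate([perm[g::5] for g in range(5) if g != f])))
            for f in range(5)
        ]
    elif scheme == "half_split":
        splits = []
        for _ in range(n_trials):
            perm = rng.permutation(n)
            half = n // 2
            splits.append((np.sort(perm[:half]), np.sort(perm[half:])))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    blocks = _gene_blocks(G, gene_map)
    sums = {g: 0.0 for g in blocks}
    for sel_rows, test_rows in splits:
        if sel_rows.size < 3 or test_rows.size < 3:
            raise ValueError("sample too small for the requested split scheme")
        C_sel = design_with_intercept(P.covariates[sel_rows], sel_rows.size)
        y_sel_resid = residualize(P.phenotype[sel_rows], C_sel)
        C_test = design_with_intercept(P.covariates[test_rows], test_rows.size)
        y_test = P.phenotype[test_rows]
        for gene, cols in blocks.items():
            fit = select_snps(G.dosages[np.ix_(sel_rows, cols)], y_sel_resid)
            if fit.n_selected == 0:
                sums[gene] += 1.0
                continue
            sel_cols = [cols[j] for j in fit.selected]
            *_, p = partial_f_test(y_test, G.dosages[np.ix_(test_rows, sel_cols)], C_test)
            sums[gene] += p
    return {g: s / len(splits) for g, s in sums.items()}


def results_to_frame(results: list[GeneTestResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "n_snps_total": [r.n_snps_total for r in results],
            "n_snps_selected": [r.n_snps_selected for r in results],
            "F": [r.F for r in results],
            "df1": [r.df1 for r in results],
            "df2": [r.df2 for r in results],
            "p": [r.p for r in results],
            "significant": [r.significant for r in results],
            "selected_snp_ids": [
                ",".join(r.selected_snp_ids) if r.selected_snp_ids else "" for r in results
            ],
        }
    )


def univariate_to_frame(results: list[UnivariateResult], G: GenotypeMatrix):
    import pandas as pd

    meta = {s: (c, p) for s, c, p in zip(G.snp_ids, G.chromosomes, G.positions)}
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "chr": [meta[r.snp_id][0] for r in results],
            "pos": [meta[r.snp_id][1] for r in results],
            "beta": [r.beta for r in results],
            "t": [r.t for r in results],
            "p": [r.p for r in results],
        }
    )
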
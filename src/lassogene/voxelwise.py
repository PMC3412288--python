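"""Mass-univariate partial F-tests across voxel phenotypes, with FDR control.

The post-hoc mapping analysis: a FIXED selected-SNP block is tested at
every voxel of a subjects-by-voxels phenotype table. The projections of
the covariate and SNP designs are computed once and reused across
voxels, so the vectorized map is numerically identical to looping the
scalar partial F-test per voxel. Multiplicity across voxels is handled
by Benjamini-Hochberg step-up FDR (the FDR dialect implemented here; a
pluggable strategy hook allows spatial variants).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assoc import P_FLOOR
from .mixed_model import KinshipMatrix, VarianceComponents, whitening_matrix


@dataclass
class PhenotypeMap:
    """Voxelwise quantitative phenotypes: N subjects x V voxels, no missing."""

    values: np.ndarray
    voxel_ids: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("voxel phenotype table must be 2-D")
        n, v = self.values.shape
        if len(self.subject_ids) != n or len(self.voxel_ids) != v:
            raise ValueError("voxel table labels do not match its shape")
        if v < 1:
            raise ValueError("at least one voxel required")
        if np.isnan(self.values).any():
            raise ValueError("voxel phenotypes contain missing values")


@dataclass
class FdrResult:
    q: float
    p_threshold: float
    mask: np.ndarray  # (V,) bool
    prop_significant: float


def voxelwise_f_map(
    Y: PhenotypeMap,
    S: np.ndarray,
    C: np.ndarray,
    kinship: KinshipMatrix | None = None,
    vc: VarianceComponents | None = None,
) -> np.ndarray:
    """Per-voxel partial F p-values for a fixed SNP block S given covariates C.

    With a kinship matrix the whole problem is whitened first (variance
    components must then be supplied or are estimated per the mixed
    model under the reduced design of the FIRST voxel's phenotype — in
    practice pass ``vc`` estimated on the scalar summary phenotype).
    """
    Yv = Y.values
    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S.reshape(-1, 1)
    C = np.asarray(C, dtype=float)
    if kinship is not None:
        if vc is None:
            from .mixed_model import reml_delta

            vc = reml_delta(Yv[:, 0], C, kinship)
        W = whitening_matrix(kinship, vc)
        Yv, S, C = W @ Yv, W @ S, W @ C
    n = Yv.shape[0]
    rank_c = int(np.linalg.matrix_rank(C))
    Qc, _ = np.linalg.qr(C)
    S_perp = S - Qc @ (Qc.T @ S)
    # orthonormal basis of the SNP block after removing covariate overlap
    scale = max(float(np.abs(S_perp).max()), 1.0)
    Qs_full, Rs = np.linalg.qr(S_perp)
    keep = np.abs(np.diag(Rs)) > 1e-8 * scale * np.sqrt(n)
    Qs = Qs_full[:, keep]
    df1 = int(keep.sum())
    df2 = n - rank_c - df1
    if df1 == 0:
        return np.ones(Yv.shape[1])
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom for the voxel map")
    Yc = Yv - Qc @ (Qc.T @ Yv)
    rss_reduced = np.sum(Yc**2, axis=0)
    proj = Qs.T @ Yc
    explained = np.sum(proj**2, axis=0)
    rss_full = np.maximum(rss_reduced - explained, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (explained / df1) / (rss_full / df2)
    F = np.where(rss_full <= 1e-14 * np.maximum(rss_reduced, 1e-300), np.inf, F)
    p = stats.f.sf(F, df1, df2)
    return np.maximum(p, P_FLOOR)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up at level q.

    The adaptive threshold is the largest order statistic p_(i) with
    p_(i) <= i*q/V (0.0 when nothing is rejected, giving an empty mask).
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    mask = multipletests(pvals, alpha=q, method="fdr_bh")[0]
    p_threshold = float(pvals[mask].max()) if mask.any() else 0.0
    return FdrResult(
        q=q, p_threshold=p_threshold, mask=mask, prop_significant=float(mask.mean())
    )


#: Pluggable FDR strategies keyed by name (hook for spatial variants).
FDR_STRATEGIES: dict[str, Callable[[np.ndarray, float], FdrResult]] = {"bh": bh_fdr}


def map_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float, float]:
    """Significant proportions of two voxel masks and their Jaccard overlap."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks have different lengths")
    union = int((a | b).sum())
    jaccard = float((a & b).sum() / union) if union else 1.0
    return float(a.mean()), float(b.mean()), jaccard


def read_phenotype_map(path: str) -> PhenotypeMap:
    """Subjects-by-voxels TSV keyed by a subject_id column."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError("voxel phenotype table must have a subject_id column")
    voxels = [c for c in df.columns if c != "subject_id"]
    return PhenotypeMap(
        values=df[voxels].to_numpy(dtype=float),
        voxel_ids=voxels,
        subject_ids=list(df["subject_id"]),
    )


def write_phenotype_map(Y: PhenotypeMap, path: str) -> None:
    df = pd.DataFrame(Y.values, columns=Y.voxel_ids)
    df.insert(0, "subject_id", Y.subject_ids)
    df.to_csv(path, sep="\t", index=False)


def write_fdr_result(voxel_ids: list[str], pvals: np.ndarray, fdr: FdrResult, path: str) -> None:
    pd.DataFrame(
        {"voxel_id": voxel_ids, "p": pvals, "significant": fdr.mask}
    ).to_csv(path, sep="\t", index=False)
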
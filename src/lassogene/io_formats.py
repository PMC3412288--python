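"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* VCF 4.x (GT field only), parsed with :mod:`cyvcf2`; dosages are recoded
  so they always count the MINOR allele.
* ``dosage_tsv``: tab-separated, header ``snp_id chr pos ref alt <subj>...``,
  one row per SNP, values in [0, 2] (``NA`` = missing, mean-imputed per
  SNP at read time). Positions are 1-based (VCF convention).
* Gene map TSV: ``snp_id<TAB>gene_id``.
* Phenotype TSV with a ``subject_id`` key column, one phenotype column
  and any number of covariate columns.
* Kinship: square TSV with a subject-id header row and column.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import GeneMap, GenotypeMatrix, PhenotypeFrame

logger = logging.getLogger(__name__)

DOSAGE_META_COLS = ["snp_id", "chr", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _recode_minor(dosage: np.ndarray, ref: str, alt: str) -> tuple[np.ndarray, tuple[str, str]]:
    """Flip a dosage column so it counts the minor allele.

    Ties at frequency exactly 0.5 call the alt allele minor, so the
    recode is deterministic. Returns the column and a (major, minor)
    allele pair.
    """
    f_alt = float(np.nanmean(dosage)) / 2.0
    if f_alt > 0.5:
        return 2.0 - dosage, (alt, ref)
    return dosage, (ref, alt)


def read_genotypes(path: str, format: str = "dosage_tsv", skip_multiallelic: bool = False) -> GenotypeMatrix:
    """Read genotypes from a VCF or a rectangular dosage table.

    Dosages in the returned matrix count minor alleles; SNP order is the
    file order. Missing entries (``NA`` in dosage_tsv, ``./.`` in VCF)
    are mean-imputed per SNP and the imputation count is logged.
    """
    if format == "vcf":
        return _read_vcf(path, skip_multiallelic=skip_multiallelic)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: str, skip_multiallelic: bool = False) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    subject_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    alleles: list[tuple[str, str]] = []
    n_imputed = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            if skip_multiallelic:
                logger.warning("skipping multi-allelic site at line record %d (%s)", i + 1, var.ID)
                continue
            raise ValueError(
                f"multi-allelic site in record {i + 1} ({var.CHROM}:{var.POS}); "
                "pass skip_multiallelic=True to drop such sites"
            )
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown/missing, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        missing = gt == 2
        alt_count = np.where(gt == 3, 2.0, gt)
        if missing.any():
            n_imputed += int(missing.sum())
            alt_count[missing] = np.nan
            alt_count[missing] = np.nanmean(alt_count)
        dosage, pair = _recode_minor(alt_count, var.REF, var.ALT[0])
        cols.append(dosage)
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        positions.append(int(var.POS))
        alleles.append(pair)
    if n_imputed:
        logger.info("mean-imputed %d missing genotype calls", n_imputed)
    if not cols:
        raise ValueError(f"no usable variant records in {path}")
    return GenotypeMatrix(
        dosages=np.column_stack(cols),
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=np.asarray(positions),
        alleles=alleles,
        subject_ids=subject_ids,
    )


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chr": str})
    for col in DOSAGE_META_COLS:
        if col not in df.columns:
            raise ValueError(f"dosage_tsv missing required column {col!r}")
    subj_cols = [c for c in df.columns if c not in DOSAGE_META_COLS]
    if not subj_cols:
        raise ValueError("dosage_tsv has no subject columns")
    mat = df[subj_cols].to_numpy(dtype=float).T  # (N, M)
    n_missing = int(np.isnan(mat).sum())
    if n_missing:
        col_means = np.nanmean(mat, axis=0)
        idx = np.where(np.isnan(mat))
        mat[idx] = col_means[idx[1]]
        logger.info("mean-imputed %d missing dosages", n_missing)
    bad = np.where((mat < 0) | (mat > 2))
    if bad[0].size:
        # +2 -> 1-based line number past the header
        raise ValueError(f"dosage out of [0,2] at data line {bad[0][0] + 2} in {path}")
    cols = []
    alleles = []
    for j, (ref, alt) in enumerate(zip(df["ref"], df["alt"])):
        dosage, pair = _recode_minor(mat[:, j], str(ref), str(alt))
        cols.append(dosage)
        alleles.append(pair)
    return GenotypeMatrix(
        dosages=np.column_stack(cols),
        snp_ids=list(df["snp_id"]),
        chromosomes=list(df["chr"]),
        positions=df["pos"].to_numpy(dtype=int),
        alleles=alleles,
        subject_ids=subj_cols,
    )


def write_genotypes(G: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as dosage_tsv (minor-allele counts, 1-based positions)."""
    df = pd.DataFrame(
        {
            "snp_id": G.snp_ids,
            "chr": G.chromosomes,
            "pos": G.positions,
            "ref": [a[0] for a in G.alleles],
            "alt": [a[1] for a in G.alleles],
        }
    )
    dosages = pd.DataFrame(G.dosages.T, columns=G.subject_ids)
    pd.concat([df, dosages], axis=1).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene map
# ---------------------------------------------------------------------------

def read_gene_map(path: str, snp_ids: list[str] | None = None) -> GeneMap:
    """Read a two-column (snp_id, gene_id) TSV into a GeneMap.

    A SNP listed for more than one gene is assigned to the
    lexicographically first gene id (a deterministic tie-break; keeping
    one-gene membership keeps the gene tests structurally independent).
    If ``snp_ids`` is given, map entries for unknown SNPs are dropped
    and the count is logged.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["snp_id", "gene_id"], dtype=str)
    if df.empty:
        raise ValueError(f"gene map {path} is empty")
    assignments: dict[str, str] = {}
    n_multi = 0
    for snp, gene in zip(df["snp_id"], df["gene_id"]):
        if snp in assignments:
            n_multi += 1
            if gene < assignments[snp]:
                assignments[snp] = gene
        else:
            assignments[snp] = gene
    if n_multi:
        logger.warning(
            "%d SNP(s) mapped to multiple genes; kept the lexicographically first gene", n_multi
        )
    if snp_ids is not None:
        known = set(snp_ids)
        dropped = [s for s in assignments if s not in known]
        if dropped:
            logger.info("dropped %d mapped SNP(s) absent from the genotype matrix", len(dropped))
        assignments = {s: g for s, g in assignments.items() if s in known}
        if not assignments:
            raise ValueError("no mapped SNPs remain after intersecting with the genotypes")
    return GeneMap(assignments=sorted(assignments.items()))


def write_gene_map(gm: GeneMap, path: str) -> None:
    pd.DataFrame(gm.assignments).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str, phenotype_col: str | None = None) -> PhenotypeFrame:
    """Read a phenotype/covariate TSV keyed by ``subject_id``.

    The phenotype is the named column, or the first non-key column when
    ``phenotype_col`` is None; all remaining numeric columns become
    covariates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError("phenotype table must have a subject_id column")
    value_cols = [c for c in df.columns if c != "subject_id"]
    if not value_cols:
        raise ValueError("phenotype table has no value columns")
    if phenotype_col is None:
        phenotype_col = value_cols[0]
    if phenotype_col not in value_cols:
        raise ValueError(f"phenotype column {phenotype_col!r} not found")
    cov_cols = [c for c in value_cols if c != phenotype_col]
    return PhenotypeFrame(
        subject_ids=list(df["subject_id"]),
        phenotype=df[phenotype_col].to_numpy(dtype=float),
        covariates=df[cov_cols].to_numpy(dtype=float) if cov_cols else np.empty((len(df), 0)),
        covariate_names=cov_cols,
    )


def write_phenotypes(P: PhenotypeFrame, path: str, phenotype_name: str = "phenotype") -> None:
    df = pd.DataFrame({"subject_id": P.subject_ids, phenotype_name: P.phenotype})
    for j, name in enumerate(P.covariate_names):
        df[name] = P.covariates[:, j]
    df.to_csv(path, sep="\t", index=False)


def join_cohort(G: GenotypeMatrix, P: PhenotypeFrame) -> tuple[GenotypeMatrix, PhenotypeFrame]:
    """Align a genotype matrix and phenotype frame on shared subjects.

    Both outputs are restricted to the id intersection in sorted order
    (so the join is invariant to input row order and idempotent).
    Subjects with any missing phenotype or covariate are dropped and
    logged.
    """
    ok = ~(np.isnan(P.phenotype) | np.isnan(P.covariates).any(axis=1))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d subject(s) with missing phenotype/covariates", n_dropped)
    p_ids = {sid for sid, keep in zip(P.subject_ids, ok) if keep}
    shared = sorted(set(G.subject_ids) & p_ids)
    if not shared:
        raise ValueError("no shared subjects between genotypes and phenotypes")
    g_idx = {s: i for i, s in enumerate(G.subject_ids)}
    p_idx = {s: i for i, s in enumerate(P.subject_ids)}
    g_rows = [g_idx[s] for s in shared]
    p_rows = [p_idx[s] for s in shared]
    return G.subset_subjects(g_rows), P.subset(p_rows)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def read_kinship(path: str) -> tuple[np.ndarray, list[str]]:
    """Read a square kinship TSV with subject-id header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError("kinship row and column subject ids disagree")
    return df.to_numpy(dtype=float), ids


def write_kinship(K: np.ndarray, subject_ids: list[str], path: str) -> None:
    pd.DataFrame(K, index=subject_ids, columns=subject_ids).to_csv(path, sep="\t")
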
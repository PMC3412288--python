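"""Core in-memory containers shared by every stage of the pipeline.

All downstream modules (QC, LASSO selection, association, mixed model,
voxelwise maps) consume only these types; file formats are handled in
:mod:`lassogene.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenotypeMatrix:
    """Additive minor-allele dosages for N subjects at M SNPs.

    Dosages are counts of the minor allele in {0, 1, 2}; fractional
    values in [0, 2] are permitted for imputed input.
    """

    dosages: np.ndarray  # (N, M) float
    snp_ids: list[str]
    chromosomes: list[str]
    positions: np.ndarray  # (M,) int, 1-based
    alleles: list[tuple[str, str]]  # (major, minor) per SNP
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        n, m = self.dosages.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match dosage rows")
        for name, arr in (
            ("snp_ids", self.snp_ids),
            ("chromosomes", self.chromosomes),
            ("positions", self.positions),
            ("alleles", self.alleles),
        ):
            if len(arr) != m:
                raise ValueError(f"{name} length does not match dosage columns")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids are not unique")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids are not unique")
        with np.errstate(invalid="ignore"):
            if np.any((self.dosages < 0) | (self.dosages > 2)):
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.snp_ids)}

    def subset_snps(self, cols: np.ndarray | list[int]) -> "GenotypeMatrix":
        cols = np.asarray(cols, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, cols],
            snp_ids=[self.snp_ids[j] for j in cols],
            chromosomes=[self.chromosomes[j] for j in cols],
            positions=self.positions[cols],
            alleles=[self.alleles[j] for j in cols],
            subject_ids=list(self.subject_ids),
        )

    def subset_subjects(self, rows: np.ndarray | list[int]) -> "GenotypeMatrix":
        rows = np.asarray(rows, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[rows, :],
            snp_ids=list(self.snp_ids),
            chromosomes=list(self.chromosomes),
            positions=self.positions.copy(),
            alleles=list(self.alleles),
            subject_ids=[self.subject_ids[i] for i in rows],
        )


@dataclass
class GeneMap:
    """Assignment of SNP ids to gene ids (intragenic SNPs only).

    Each SNP belongs to at most one gene; genes are iterated in
    lexicographic order so every scan is deterministic.
    """

    assignments: list[tuple[str, str]]  # (snp_id, gene_id)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("gene map is empty")
        seen: set[str] = set()
        for snp, _ in self.assignments:
            if snp in seen:
                raise ValueError(f"SNP {snp} assigned to more than one gene")
            seen.add(snp)

    def genes(self) -> list[str]:
        return sorted({g for _, g in self.assignments})

    def snps_for_gene(self, gene_id: str) -> list[str]:
        return [s for s, g in self.assignments if g == gene_id]

    def by_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.assignments:
            out.setdefault(g, []).append(s)
        return {g: out[g] for g in sorted(out)}


@dataclass
class PhenotypeFrame:
    """Subject-aligned quantitative phenotype plus covariate columns."""

    subject_ids: list[str]
    phenotype: np.ndarray  # (N,)
    covariates: np.ndarray  # (N, C)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates.reshape(-1, 1)
        n = len(self.subject_ids)
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match subject_ids")
        if self.covariates.shape[0] != n:
            raise ValueError("covariate rows do not match subject_ids")
        if self.covariate_names and len(self.covariate_names) != self.covariates.shape[1]:
            raise ValueError("covariate_names length mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset(self, rows: np.ndarray | list[int]) -> "PhenotypeFrame":
        rows = np.asarray(rows, dtype=int)
        return PhenotypeFrame(
            subject_ids=[self.subject_ids[i] for i in rows],
            phenotype=self.phenotype[rows],
            covariates=self.covariates[rows, :],
            covariate_names=list(self.covariate_names),
        )
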
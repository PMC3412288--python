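"""Synthetic cohorts with the statistical structure the method assumes.

Genotypes are common variants (target MAF drawn inside ``maf_range``)
with AR(1) linkage disequilibrium within genes: each haplotype carries
latent standard Gaussians with lag-one correlation ``ld_rho``,
thresholded at each SNP's MAF quantile, and the two haplotypes sum to
the additive dosage. Genes are independent blocks (no inter-gene LD),
matching the per-gene modelling unit. Hardy-Weinberg equilibrium holds
by construction (independent haplotypes); the optional ``inbreeding``
knob copies a subject's first haplotype with the given probability to
create testable HWE violations.

Phenotypes are additive: a sum of per-SNP effects (in phenotype-SD
units, applied to standardized dosages) plus age and sex covariate
effects and Gaussian noise. Voxelwise maps place the genetic signal on
a contiguous voxel "footprint" with independent noise elsewhere.

Family mode generates parental haplotypes and drops them down one
generation: siblings draw one whole haplotype per gene from each
parent (expected additive relationship 0.5), monozygotic twins
duplicate genotypes, and the returned kinship is the true pedigree
relationship matrix.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import norm

from .datatypes import GenotypeMatrix, PhenotypeFrame
from .mixed_model import KinshipMatrix
from .voxelwise import PhenotypeMap


@dataclass
class SimConfig:
    """All knobs of the generator; the seed is mandatory.

    Defaults emulate a single-site quantitative-imaging GWAS cohort:
    a few hundred elderly subjects, common variants (MAF 0.15-0.5),
    strong within-gene LD, sparse causal SNPs in one or a few genes with
    effects stated in phenotype-SD units, age/sex covariate effects and
    unit residual noise.
    """

    seed: int
    n_subjects: int = 300
    genes: list[tuple[str, int]] = field(default_factory=lambda: [("GENE%02d" % i, 10) for i in range(1, 21)])
    maf_range: tuple[float, float] = (0.15, 0.5)
    ld_rho: float = 0.7
    causal: list[tuple[str, int, float]] = field(default_factory=list)  # (gene, snp_index, effect)
    covariate_effects: tuple[float, float] = (-0.03, 0.5)  # per-year age, sex offset
    noise_sd: float = 1.0
    inbreeding: float = 0.0
    n_families: int = 0
    family_size: int = 2
    mz_twins: bool = False
    n_voxels: int = 0
    voxel_footprint: int = 0
    voxel_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["genes"] = [tuple(g) for g in d["genes"]]
        d["causal"] = [tuple(c) for c in d["causal"]]
        d["maf_range"] = tuple(d["maf_range"])
        d["covariate_effects"] = tuple(d["covariate_effects"])
        return cls(**d)


def _gene_mafs(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    lo, hi = config.maf_range
    return {g: rng.uniform(lo, hi, size=m) for g, m in config.genes}


def _haplotypes(n_hap: int, mafs: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Binary minor-allele indicators for n_hap haplotypes at len(mafs) SNPs."""
    m = mafs.size
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    thresholds = norm.ppf(1.0 - mafs)
    return (z > thresholds).astype(float)


def _fold_to_minor(dosages: np.ndarray, alleles: list[tuple[str, str]]) -> None:
    """Flip columns whose realized frequency exceeds 0.5 so dosages count minors."""
    freq = dosages.mean(axis=0) / 2.0
    for j in np.where(freq > 0.5)[0]:
        dosages[:, j] = 2.0 - dosages[:, j]
        alleles[j] = (alleles[j][1], alleles[j][0])


def _metadata(config: SimConfig) -> tuple[list[str], list[str], np.ndarray, list[tuple[str, str]]]:
    snp_ids, chroms, positions, alleles = [], [], [], []
    for gi, (gene, m) in enumerate(config.genes):
        chrom = str(gi % 22 + 1)
        base = 10_000 + 100_000 * gi
        for j in range(m):
            snp_ids.append(f"{gene}_snp{j}")
            chroms.append(chrom)
            positions.append(base + 1000 * j)
            alleles.append(("A", "C"))
    return snp_ids, chroms, np.asarray(positions), alleles


def gene_map_rows(config: SimConfig) -> list[tuple[str, str]]:
    """(snp_id, gene_id) assignments implied by the config."""
    return [(f"{gene}_snp{j}", gene) for gene, m in config.genes for j in range(m)]


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Unrelated subjects: two independent haplotypes per subject per gene."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mafs = _gene_mafs(config, rng)
    n = config.n_subjects
    blocks = []
    for gene, m in config.genes:
        h1 = _haplotypes(n, mafs[gene], config.ld_rho, rng)
        h2 = _haplotypes(n, mafs[gene], config.ld_rho, rng)
        if config.inbreeding > 0:
            same = rng.random(n) < config.inbreeding
            h2[same] = h1[same]
        blocks.append(h1 + h2)
    dosages = np.hstack(blocks)
    snp_ids, chroms, positions, alleles = _metadata(config)
    _fold_to_minor(dosages, alleles)
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=positions,
        alleles=alleles,
        subject_ids=[f"S{i:05d}" for i in range(n)],
    )


def simulate_families(config: SimConfig) -> tuple[GenotypeMatrix, KinshipMatrix]:
    """Family-structured cohort plus its true pedigree relationship matrix.

    The first ``n_families * family_size`` subjects are full siblings
    within consecutive families (the first two of each family are
    monozygotic twins when ``mz_twins``); any remaining subjects up to
    ``n_subjects`` are unrelated singletons.
    """
    if config.n_families < 1 or config.family_size < 1:
        raise ValueError("family mode needs n_families >= 1 and family_size >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mafs = _gene_mafs(config, rng)
    n_fam_subj = config.n_families * config.family_size
    n_single = max(config.n_subjects - n_fam_subj, 0)
    n_total = n_fam_subj + n_single
    blocks = []
    for gene, m in config.genes:
        rows = np.empty((n_total, m))
        r = 0
        for _ in range(config.n_families):
            parents = _haplotypes(4, mafs[gene], config.ld_rho, rng)  # mom0 mom1 dad0 dad1
            kids = []
            for c in range(config.family_size):
                if config.mz_twins and c == 1:
                    kids.append(kids[0])
                    continue
                mom = parents[rng.integers(0, 2)]
                dad = parents[2 + rng.integers(0, 2)]
                kids.append(mom + dad)
            for kid in kids:
                rows[r] = kid
                r += 1
        if n_single:
            h1 = _haplotypes(n_single, mafs[gene], config.ld_rho, rng)
            h2 = _haplotypes(n_single, mafs[gene], config.ld_rho, rng)
            rows[r:] = h1 + h2
        blocks.append(rows)
    dosages = np.hstack(blocks)
    snp_ids, chroms, positions, alleles = _metadata(config)
    _fold_to_minor(dosages, alleles)
    subject_ids = [f"F{f:03d}_C{c}" for f in range(config.n_families) for c in range(config.family_size)]
    subject_ids += [f"U{i:05d}" for i in range(n_single)]
    K = np.eye(n_total)
    for f in range(config.n_families):
        lo = f * config.family_size
        for a in range(config.family_size):
            for b in range(a + 1, config.family_size):
                rel = 1.0 if (config.mz_twins and {a, b} == {0, 1}) else 0.5
                K[lo + a, lo + b] = K[lo + b, lo + a] = rel
    G = GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=positions,
        alleles=alleles,
        subject_ids=subject_ids,
    )
    return G, KinshipMatrix(K=K, subject_ids=subject_ids)


def _standardized(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    return (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)


def _genetic_signal(G: GenotypeMatrix, config: SimConfig) -> np.ndarray:
    idx = G.snp_index()
    signal = np.zeros(G.n_subjects)
    for gene, snp_index, effect in config.causal:
        snp_id = f"{gene}_snp{snp_index}"
        if snp_id not in idx:
            raise ValueError(f"causal SNP {snp_id} not present in the genotype matrix")
        signal += effect * _standardized(G.dosages[:, idx[snp_id]])
    return signal


def simulate_phenotype(
    G: GenotypeMatrix, config: SimConfig
) -> tuple[PhenotypeFrame, PhenotypeMap | None]:
    """Additive quantitative trait (and optional voxel map) for a cohort.

    y = sum_causal effect * standardized dosage + age/sex effects +
    N(0, noise_sd). Age is drawn N(75, 6) years and centered before its
    per-year slope applies; sex is Bernoulli(1/2). The optional voxel
    map carries the same genetic signal on the first ``voxel_footprint``
    voxels only, covariate effects everywhere, and independent noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = G.n_subjects
    age = rng.normal(75.0, 6.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    age_beta, sex_beta = config.covariate_effects
    signal = _genetic_signal(G, config)
    cov_part = age_beta * (age - age.mean()) + sex_beta * sex
    y = signal + cov_part + rng.normal(0.0, config.noise_sd, size=n)
    P = PhenotypeFrame(
        subject_ids=list(G.subject_ids),
        phenotype=y,
        covariates=np.column_stack([age, sex]),
        covariate_names=["age", "sex"],
    )
    if config.n_voxels < 1:
        return P, None
    fp = min(config.voxel_footprint, config.n_voxels)
    values = rng.normal(0.0, config.voxel_noise_sd, size=(n, config.n_voxels))
    values += cov_part[:, None]
    values[:, :fp] += signal[:, None]
    Y = PhenotypeMap(
        values=values,
        voxel_ids=[f"vox{v:04d}" for v in range(config.n_voxels)],
        subject_ids=list(G.subject_ids),
    )
    return P, Y
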
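# lassogene

Gene-centric association testing for quantitative (typically
imaging-derived) phenotypes. Instead of testing each SNP one at a time,
`lassogene` treats the **gene** as the unit of association: within each
gene it selects a sparse subset of SNPs by LASSO regression, then tests
the selected set **jointly** with a partial F-test. Sparse selection
tames the multicollinearity created by linkage disequilibrium, and joint
modelling pools sub-threshold signals spread across several variants in
the same gene — signals a univariate GWAS would miss.

It is aimed at imaging-genetics and quantitative-trait studies of
moderate size (hundreds of subjects), where single-variant effects are
individually too weak to survive genome-wide correction.

## Method

For one gene, let `X` be the N×m matrix of intragenic SNP dosages
(additive minor-allele counts 0/1/2) and `y` the phenotype residualized
on covariates (age, sex, ancestry axes). SNP selection solves the LASSO

    β* = argmin_β  (1/2N) ‖y − Xβ‖² + λ ‖β‖₁

by cyclic coordinate descent along a decreasing penalty path, with λ
chosen by leave-one-out cross-validation under the mean-squared-error
criterion. The nonzero support of β* is a *filter*, not the final model:
the selected dosage columns S enter a nested-model comparison

    full:     y ~ covariates + S        reduced:  y ~ covariates
    F = ((RSS_red − RSS_full)/df₁) / (RSS_full/df₂)

whose upper-tail p-value is the gene's association statistic. Gene-level
genome-wide significance uses Bonferroni correction, α / n_genes (0.05
over 18,284 genes gives 2.73 × 10⁻⁶). A gene whose selection is empty
reports p = 1.

For related cohorts (twins/siblings) the same contrast runs under a
variance-component model y ~ N(Cβ, σ²_g K + σ²_e I) with kinship K: the
ratio δ = σ²_e/σ²_g is estimated once by REML under the covariates-only
model, all data are whitened by (K + δI)^(−1/2), and the ordinary
partial-F machinery applies. Post-hoc, the fixed selected-SNP set can be
tested at every voxel of a subjects×voxels phenotype table, with
Benjamini–Hochberg FDR across voxels.

A simulator generates LD-block-structured common-variant genotypes
(latent AR(1) Gaussian haplotypes), sparse within-gene causal effects,
age/sex covariates, voxel maps with a spatial effect footprint, and
family structure with the true pedigree kinship — so the entire pipeline
is testable without any external data. See `docs/methods.md` for model
details and design choices.

## Worked example

Simulate 400 subjects, 8 genes × 6 SNPs, with three causal SNPs of
0.4–0.5 phenotype-SD each in `GENE01`; then run QC and the gene scan:

```sh
lassogene simulate --seed 11 --n-subjects 400 --n-genes 8 --snps-per-gene 6 \
    --causal "GENE01:0:0.5,GENE01:3:0.5,GENE01:5:0.4" --out-prefix cohort
lassogene qc --genotypes cohort.dosages.tsv --out qc.tsv
lassogene gene-scan --genotypes cohort.dosages.tsv --gene-map cohort.genemap.tsv \
    --phenotypes cohort.phenotypes.tsv --n-genes 18284 --out scan.tsv
```

which prints

```
kept 48/48 SNPs
threshold 2.73e-06; 1 significant gene(s) of 8
```

and writes `scan.tsv`, whose top rows are

```
gene_id  n_snps_total  n_snps_selected  F      df1  df2  p         significant
GENE01   6             6                63.51  6    391  8.18e-55  True
GENE05   6             2                1.81   2    395  0.164     False
GENE02   6             0                0.0    0    397  1.0       False
```

The planted gene is detected far beyond the 18,284-gene Bonferroni
threshold (2.73 × 10⁻⁶); a null gene with a small incidental selection
stays non-significant, and a gene whose cross-validated selection is
empty reports p = 1 by convention. `lassogene replicate --snp-list ...
--kinship ...` carries a discovery-selected SNP set into a related
cohort via the mixed model, and `lassogene voxelwise` maps a fixed SNP
set across voxel phenotypes with FDR control.

The same objects are available as a library
(`lassogene.gene_scan`, `lassogene.select_snps`,
`lassogene.mixed_partial_f_test`, ...).

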
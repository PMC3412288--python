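# Methods

## The statistical procedure

The unit of inference is the gene. For a cohort of N subjects the
pipeline is:

1. **QC.** Keep SNPs with minor-allele frequency strictly greater than
   0.1 and exact Hardy–Weinberg p ≥ 5.7 × 10⁻⁷. The MAF screen reflects
   the fact that cohorts of a few hundred subjects are underpowered for
   rarer variants; the HWE screen flags genotyping/imputation
   artifacts. The HWE test is the Levene–Haldane exact test
   (enumeration over heterozygote counts conditional on allele counts,
   summing probabilities no larger than the observed table's): at a
   threshold as deep as 5.7 × 10⁻⁷ the χ² approximation is unreliable,
   the exact tail is not. Fractional (imputed) dosages are hard-called
   by rounding for the HWE count only; all regression steps use the
   fractional values.
2. **Selection.** Per gene, the phenotype is residualized on the
   covariates (genotypes are not residualized), the gene's dosage
   columns are standardized, and the L1-penalized least-squares path is
   fit by cyclic coordinate descent. Leave-one-out cross-validation
   picks the penalty minimizing mean squared prediction error; ties go
   to the larger penalty (the sparser model) and no one-standard-error
   rule is applied. Coefficients are back-transformed to the
   per-minor-allele dosage scale and the nonzero support is the gene's
   selected SNP set.
3. **Joint test.** The selected dosages S enter a partial F-test of the
   full model (covariates + S, coefficients re-fit by least squares —
   the LASSO is only a filter) against the covariates-only reduced
   model, with df₁ = rank of S after projecting out the covariates and
   df₂ = N − rank(C) − df₁. Genes with empty selections report p = 1,
   which keeps them in the Bonferroni denominator. Gene-level
   significance is α/n_genes.
4. **Related cohorts.** The same contrast under
   y ~ N(Cβ, σ²_g K + σ²_e I): REML estimates δ = σ²_e/σ²_g once under
   the reduced model (spectral form on the eigenbasis of the projected
   kinship, 100-point log grid on [10⁻⁵, 10⁵] plus bounded local
   refinement), then y, S, C are whitened by (K + δI)^(−1/2) and the
   ordinary F machinery applies. In replication mode the SNP set is the
   discovery selection, supplied as a list; no re-selection happens, and
   listed SNPs absent from the replication genotypes are dropped with a
   logged count.
5. **Voxel maps.** For a fixed S, per-voxel partial F-tests share one
   projection of C and S, so the vectorized map is numerically equal to
   looping the scalar test. Voxel multiplicity is controlled by
   Benjamini–Hochberg step-up FDR (`FDR_STRATEGIES` is a hook for
   spatial variants, which need a spatial model this package does not
   presume).

## Numerical conventions

- The LASSO objective is (1/2N)‖y − Xβ‖² + λ‖β‖₁. The 1/N factor keeps
  λ comparable across sample sizes and matches the parameterization of
  the standard coordinate-descent software for this model; λ is
  internal plumbing and never a reported quantity, so the choice cannot
  affect scientific output.
- Penalty path: 100 log-spaced points from λ_max = ‖Xᵀy‖_∞/N down to
  10⁻³ λ_max, warm-started. Convergence: max coefficient change
  < 10⁻⁷ per sweep, max 10,000 sweeps; non-convergence raises an error
  carrying the KKT violation.
- Cross-validation reuses the full-data standardization and penalty
  path for every fold; each leave-one-out fold is a rank-one downdate
  of the Gram summaries, so a fold costs O(m²) per path point rather
  than O(Nm). This differs from software that re-standardizes per fold;
  with hundreds of subjects the difference is far below selection noise.
- Exact-duplicate columns: the fixed cyclic update order (ascending
  column index) deterministically assigns the shared signal to the
  lowest-index copy; an O(machine-eps) residue on the other copy is
  zeroed by a 10⁻¹⁰ relative support threshold.
- Aliased columns in the tested SNP block are dropped in column order
  (Gram–Schmidt with a scaled 10⁻⁸ tolerance); df₁ is the post-drop
  rank. A block entirely inside the covariate span gives df₁ = 0 and
  p = 1. A perfect full-model fit floors the p-value at the smallest
  positive normal double and warns.
- Minor-allele tie at frequency exactly 0.5: the alt allele is called
  minor, so recoding is deterministic. Positions are 1-based. Missing
  dosages (`NA`, `./.`) are mean-imputed per SNP at read time with a
  logged count — a desk-scale stand-in for haplotype-based imputation.
- A SNP mapped to several overlapping genes is assigned to the
  lexicographically first gene id: one-gene membership keeps the gene
  tests structurally independent, and no principled assignment exists
  without transcript annotation.
- Variance components are estimated once under the reduced model and
  reused for every gene (the standard single-fit approximation); the
  whitener is normalized to (K + δI)^(−1/2) since the overall variance
  scale cancels in F, which also makes the test invariant to scaling K.

## What the simulator emulates — and what it does not

Genotypes: per gene, two haplotypes per subject, each a latent AR(1)
Gaussian (correlation `ld_rho`, default 0.7) thresholded at each SNP's
target MAF (drawn from 0.15–0.5 by default, matching a common-variant
panel after the MAF > 0.1 screen). AR(1) was chosen as a single
interpretable LD knob; genes are independent blocks, matching the
per-gene modelling unit. Because haplotypes are independent, HWE holds
by construction and default data pass the HWE filter; the `inbreeding`
knob copies haplotypes within subjects to create violations for testing
the filter. Phenotypes are additive in standardized dosages with
effects in phenotype-SD units, plus a per-year age slope (−0.03/year
around a mean age of 75, an elderly single-cohort profile), a sex
offset (0.5 SD) and unit Gaussian noise. Families drop whole parental
haplotypes per gene (no recombination within genes), giving sibs an
expected additive relationship of 0.5 and MZ twins identical genotypes;
the returned kinship is the true pedigree matrix.

Not emulated: recombination and coalescent genealogy, inter-gene LD,
population stratification, genotyping error, dominance/epistasis, and
non-Gaussian phenotype tails. Passing tests therefore demonstrate the
machinery's correctness and calibration under the model's own
assumptions, not robustness to these real-data complications.

## Calibration caveat for the in-sample scheme

Selecting SNPs on y and then F-testing the same y is anticonservative:
under a global null the scan produces many more p < 0.05 genes than 5%
(the simulations here show a several-fold excess whenever
cross-validation retains any SNPs). The package implements this
in-sample scheme as the primary workflow because it is the procedure
under study, and exposes two nested cross-validation schemes
(`fifth_folds`, `half_split`) that decouple selection from testing at a
substantial power cost. Null-calibration claims in the test suite are
therefore made only for *fixed* SNP sets, which isolates the F-test's
correctness from selection effects; the nested schemes' upward shift of
null p-values relative to the in-sample scan is itself a tested
property. The package does not adjudicate between the schemes.

## Problem sizes

Simulation-based checks use a few hundred to a thousand replicates at
N = 200–500 subjects with genes of 6–10 SNPs — sizes at which the
Monte-Carlo error bands quoted in the tests (3 binomial SEs) are a few
percentage points, and small enough that the full suite and the
acceptance script each run in well under a minute of compute per
criterion.

## Known limitations

- Leave-one-out CV at very large N is O(N·path·m²) per gene; k-fold CV
  is available but changes the selection slightly.
- The EMMAX-style single variance-component fit under-corrects when the
  tested SNP block itself explains substantial variance.
- BH FDR ignores spatial smoothness of voxel maps; a spatially
  informed variant would plug into `FDR_STRATEGIES`.
- Mean imputation of missing dosages shrinks per-SNP variance slightly
  relative to haplotype-based imputation.
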
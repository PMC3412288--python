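"""SNP-level quality control: minor-allele frequency and exact HWE filters.

Defaults reproduce a common-variant GWAS screen: keep SNPs with
MAF > 0.1 (strictly greater) and exact Hardy-Weinberg equilibrium
p >= 5.7e-7. The HWE test is the Levene-Haldane exact test (enumeration
over heterozygote counts with fixed allele counts), which is reliable in
the deep tail the 5.7e-7 threshold targets, where the chi-square
approximation is not. Fractional (imputed) dosages are hard-called to
the nearest genotype for the HWE test only; all downstream modelling
uses the fractional values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import GenotypeMatrix

DEFAULT_MAF_THRESHOLD = 0.1
DEFAULT_HWE_THRESHOLD = 5.7e-7


@dataclass
class QcReport:
    """Per-SNP QC metrics and keep/drop verdicts covering all input SNPs."""

    snp_ids: list[str]
    maf: np.ndarray
    hwe_p: np.ndarray
    keep: np.ndarray  # bool
    reasons: list[set[str]]  # subsets of {"low_maf", "hwe_fail"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "maf": self.maf,
                "hwe_p": self.hwe_p,
                "keep": self.keep,
                "reasons": [",".join(sorted(r)) for r in self.reasons],
            }
        )

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compute_maf(dosage_column: np.ndarray) -> float:
    """Minor-allele frequency of one dosage column: min(f, 1-f), f = sum/(2N)."""
    d = np.asarray(dosage_column, dtype=float)
    if d.size == 0:
        raise ValueError("empty dosage column")
    if np.any((d < 0) | (d > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    f = float(d.sum()) / (2.0 * d.size)
    return min(f, 1.0 - f)


def _log_het_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of each feasible heterozygote count.

    Under the Levene-Haldane distribution the heterozygote count n_Aa,
    given n diploid genotypes and n_minor copies of the minor allele, has

        P(n_Aa) = 2^{n_Aa} n! n_minor! n_major! / (n_AA! n_Aa! n_aa! (2n)!)

    with n_aa = (n_minor - n_Aa)/2, n_AA = n - n_Aa - n_aa; n_Aa shares
    the parity of n_minor.
    """
    n_major = 2 * n - n_minor
    hets = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    n_aa = (n_minor - hets) // 2
    n_AA = n - hets - n_aa
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(n_AA + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa + 1)
        - gammaln(2 * n + 1)
    )
    return hets, logp


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE p-value for genotype counts (hom, het, hom).

    Sums, over all heterozygote counts compatible with the observed
    allele counts, the probabilities no larger than that of the observed
    table. Monomorphic SNPs return p = 1. Labelling of the two
    homozygote classes is immaterial.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0
    hets, logp = _log_het_probs(n, n_minor)
    p_obs = logp[hets == n_Aa][0]
    # 1e-12 relative slack so ties in probability are included
    probs = np.exp(logp)
    p = float(probs[logp <= p_obs + 1e-12].sum())
    return min(p, 1.0)


def hard_call(dosage_column: np.ndarray) -> tuple[int, int, int]:
    """Round fractional dosages to genotype counts (n_AA, n_Aa, n_aa).

    AA denotes the major-allele homozygote (dosage 0). Half-integer
    dosages round to the nearest even genotype (numpy convention).
    """
    calls = np.rint(np.asarray(dosage_column, dtype=float)).astype(int)
    return int((calls == 0).sum()), int((calls == 1).sum()), int((calls == 2).sum())


def apply_qc(
    G: GenotypeMatrix,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    hwe_threshold: float = DEFAULT_HWE_THRESHOLD,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs by MAF and exact-HWE thresholds.

    Retains SNPs with maf > maf_threshold (strict) and hwe_p >=
    hwe_threshold. Raises if every SNP is removed.
    """
    maf = np.array([compute_maf(G.dosages[:, j]) for j in range(G.n_snps)])
    hwe_p = np.array([hwe_exact_test(*hard_call(G.dosages[:, j])) for j in range(G.n_snps)])
    keep = (maf > maf_threshold) & (hwe_p >= hwe_threshold)
    reasons: list[set[str]] = []
    for j in range(G.n_snps):
        r: set[str] = set()
        if maf[j] <= maf_threshold:
            r.add("low_maf")
        if hwe_p[j] < hwe_threshold:
            r.add("hwe_fail")
        reasons.append(r)
    report = QcReport(list(G.snp_ids), maf, hwe_p, keep, reasons)
    if not keep.any():
        raise ValueError(
            "QC removed every SNP; review maf_threshold/hwe_threshold against the data"
        )
    return G.subset_snps(np.where(keep)[0]), report
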
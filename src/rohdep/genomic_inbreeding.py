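"""SNP quality control and the GRM-diagonal inbreeding coefficient F_GRM.

F_GRM uses VanRaden's genomic relationship matrix with the base allele
frequency fixed at 0.5 for every locus: with dosage x_ij of allele B,
g_ii = sum_j (x_ij - 1)^2 / (m/2) and F_GRM = g_ii - 1, which reduces to
2 x (observed homozygosity fraction) - 1 and ranges over [-1, 1].
Only the diagonal is formed; the full GRM is available behind a debug flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact two-sided Hardy-Weinberg test (Wigginton-style).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote-count configurations no more probable than the observed one.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("HWE test undefined for zero total count")
    n_rare = 2 * min(n_hom_a, n_hom_b) + n_het
    # possible het counts share parity with n_rare
    het_lo = n_rare % 2
    het_hi = min(n_rare, 2 * n - n_rare)
    hets = np.arange(het_lo, het_hi + 1, 2)
    # probabilities via the standard recurrence, anchored mid-range for
    # numerical stability
    probs = np.empty(len(hets))
    mid_idx = len(hets) // 2
    probs[mid_idx] = 1.0
    for k in range(mid_idx, len(hets) - 1):
        h = hets[k]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        # P(h+2)/P(h) = 4*hom_r*hom_c / ((h+2)*(h+1))
        probs[k + 1] = probs[k] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    for k in range(mid_idx, 0, -1):
        h = hets[k]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        # P(h-2)/P(h) = h*(h-1) / (4*(hom_r+1)*(hom_c+1))
        probs[k - 1] = probs[k] * h * (h - 1.0) / (4.0 * (hom_r + 1.0)
                                                   * (hom_c + 1.0))
    probs /= probs.sum()
    obs = probs[(n_het - het_lo) // 2]
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


@dataclass
class QcReport:
    n_input_snps: int
    n_removed_nonautosomal: int
    n_removed_hwe: int
    n_removed_maf: int
    kept_snp_ids: list = field(repr=False)

    @property
    def n_kept(self) -> int:
        return len(self.kept_snp_ids)


def snp_qc(geno: GenotypeMatrix, hwe_threshold: float = 1e-3,
           maf_threshold: float | None = None, autosomes_only: bool = True,
           n_autosomes: int = 29):
    """Filter SNPs: non-autosomal, HWE exact p < threshold, then optionally
    MAF < threshold (the MAF filter applies to the GRM/HBD inputs, not to the
    ROH path).  MISSING codes are rejected."""
    if geno.has_missing():
        raise ValueError("snp_qc requires complete genotypes (no MISSING)")
    codes = geno.codes
    keep = np.ones(geno.n_snps, dtype=bool)
    chrom = geno.snp_map["chrom"].to_numpy()
    if autosomes_only:
        keep &= (chrom >= 1) & (chrom <= n_autosomes)
    n_auto_removed = int((~keep).sum())

    n0 = (codes == 0).sum(axis=0)
    n1 = (codes == 1).sum(axis=0)
    n2 = (codes == 2).sum(axis=0)
    hwe_removed = 0
    for j in np.flatnonzero(keep):
        if hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j])) < hwe_threshold:
            keep[j] = False
            hwe_removed += 1

    maf_removed = 0
    if maf_threshold is not None:
        freq_b = codes.mean(axis=0) / 2.0
        maf = np.minimum(freq_b, 1.0 - freq_b)
        drop = keep & (maf < maf_threshold)
        maf_removed = int(drop.sum())
        keep &= ~drop

    report = QcReport(geno.n_snps, n_auto_removed, hwe_removed, maf_removed,
                      list(geno.snp_map.loc[keep, "snp_id"]))
    return geno.subset_snps(keep), report


@dataclass
class FgrmResult:
    g_diag: pd.Series
    f_grm: pd.Series


def compute_fgrm(geno: GenotypeMatrix, return_full_grm: bool = False):
    """F_GRM = diagonal of VanRaden's GRM with p_j = 0.5 everywhere, minus 1."""
    if geno.n_snps == 0:
        raise ValueError("no SNPs left for F_GRM")
    if geno.has_missing():
        raise ValueError("compute_fgrm requires complete genotypes")
    z = geno.codes.astype(np.float64) - 1.0  # x - 2p with p = 0.5
    denom = geno.n_snps / 2.0  # 2 * sum_j p(1-p) = m/2
    g_diag = (z * z).sum(axis=1) / denom
    res = FgrmResult(pd.Series(g_diag, index=geno.samples, name="g_ii"),
                     pd.Series(g_diag - 1.0, index=geno.samples, name="F_GRM"))
    if return_full_grm:
        return res, (z @ z.T) / denom
    return res
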
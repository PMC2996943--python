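"""Per-SNP signal-ratio correction (CPA) estimated from heterozygotes.

A heterozygote carries one copy of each allele, so any systematic departure
of the channel-A/channel-B signal ratio from 1 measures preferential
amplification/hybridization.  The per-SNP correction factor is the ratio of
channel means across heterozygous samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import GENO_Aa, CPATable, GenotypeMatrix, IntensityTable, ValidationError


@dataclass(frozen=True)
class LognormalFit:
    """Maximum-likelihood lognormal fit to a set of correction factors."""

    mu: float
    sigma: float
    n: int
    gof: float  # Kolmogorov-Smirnov distance to the fitted CDF

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0


@dataclass(frozen=True)
class CPAComparison:
    """Pearson correlation of log2 correction factors between two tables."""

    r: float
    n_shared: int


def estimate_cpa(intens: IntensityTable, genos: GenotypeMatrix,
                 min_het: int = 3) -> CPATable:
    """Estimate the per-SNP correction factor from heterozygous samples.

    For each SNP the estimate is mean(s1)/mean(s2) over unmasked
    heterozygotes.  SNPs with fewer than ``min_het`` heterozygotes fall back
    to 1.0 (no adjustment) and are flagged; a zero heterozygote mean in the
    s2 channel makes the estimate missing, never infinite.  ``cv`` is the
    coefficient of variation of the per-individual ratios s1/s2, available
    when at least two heterozygotes have positive s2.
    """
    if min_het < 1:
        raise ValidationError("min_het must be >= 1")
    if intens.shape != genos.shape:
        raise ValidationError("intensity and genotype tables have different shapes")
    if not np.array_equal(intens.annotation.snp_id, genos.annotation.snp_id):
        raise ValidationError("intensity and genotype tables cover different SNPs")
    if intens.samples != genos.samples:
        raise ValidationError("intensity and genotype tables cover different samples")

    het = (genos.calls == GENO_Aa) & ~intens.mask
    n_het = het.sum(axis=1)

    s1 = np.where(het, intens.s1, 0.0)
    s2 = np.where(het, intens.s2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean1 = s1.sum(axis=1) / np.maximum(n_het, 1)
        mean2 = s2.sum(axis=1) / np.maximum(n_het, 1)

    n_snps = intens.shape[0]
    cpa = np.ones(n_snps)
    fallback = n_het < min_het
    missing = np.zeros(n_snps, dtype=bool)

    estimable = ~fallback
    zero_denom = estimable & (mean2 <= 0)
    missing[zero_denom] = True
    good = estimable & ~zero_denom
    cpa[good] = mean1[good] / mean2[good]
    zero_num = good & (cpa <= 0)
    # an all-zero s1 channel over heterozygotes is as unusable as zero s2
    missing[zero_num] = True
    cpa[missing] = 1.0

    cv = np.full(n_snps, np.nan)
    for i in np.nonzero(good & ~zero_num & (n_het >= 2))[0]:
        sel = het[i] & (intens.s2[i] > 0)
        if sel.sum() >= 2:
            ratios = intens.s1[i, sel] / intens.s2[i, sel]
            cv[i] = ratios.std(ddof=1) / cpa[i]

    return CPATable(
        snp_id=intens.annotation.snp_id.copy(), cpa=cpa, n_het=n_het,
        cv=cv, fallback=fallback, missing=missing,
        annotation=intens.annotation,
    )


def fit_lognormal(cpa: CPATable, min_snps: int = 10) -> LognormalFit:
    """ML lognormal fit to usable (non-fallback, non-missing) CPA values.

    Equivalent to a normal fit on ln(CPA); ``gof`` is the KS distance to the
    fitted CDF.  Fewer than ``min_snps`` usable values is an error; a
    zero-variance sample returns a fit flagged degenerate (sigma = 0).
    """
    usable = ~cpa.fallback & ~cpa.missing
    vals = cpa.cpa[usable]
    if len(vals) < min_snps:
        raise ValidationError(
            f"need >= {min_snps} usable CPA values, got {len(vals)}"
        )
    logs = np.log(vals)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))  # ML estimate
    if sigma == 0.0:
        return LognormalFit(mu=mu, sigma=0.0, n=len(vals), gof=1.0)
    ks = stats.kstest(logs, stats.norm(loc=mu, scale=sigma).cdf)
    return LognormalFit(mu=mu, sigma=sigma, n=len(vals), gof=float(ks.statistic))


def compare_cpa(a: CPATable, b: CPATable) -> CPAComparison:
    """Pearson r of log2(CPA) over the shared usable SNPs of two tables."""
    usable_a = {s: v for s, v, ok in zip(a.snp_id, a.log2_cpa, ~a.fallback & ~a.missing) if ok}
    usable_b = {s: v for s, v, ok in zip(b.snp_id, b.log2_cpa, ~b.fallback & ~b.missing) if ok}
    shared = sorted(set(usable_a) & set(usable_b))
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 shared usable SNPs to compare, got {len(shared)}"
        )
    x = np.array([usable_a[s] for s in shared])
    y = np.array([usable_b[s] for s in shared])
    r = stats.pearsonr(x, y).statistic
    return CPAComparison(r=float(r), n_shared=len(shared))
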
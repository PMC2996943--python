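"""Individual- and population-level allele-frequency estimation.

Two routes: allele counting from genotype calls (0, 0.5, 1 per genotype)
and intensity measuring, where the channel-A share of total signal is
computed after scaling the B channel by the SNP's correction factor.
The pooled route applies the same ratio to pool-level signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import (
    GENO_NOCALL,
    AlleleFreqMatrix,
    CPATable,
    IntensityTable,
    PooledIntensity,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FreqEstimate:
    value: float | None            # in [0, 1]; None when missing
    variance: float | None = None  # None when not computable
    method: str = "counting"       # counting | intensity | pooled
    n: int = 1

    @property
    def missing(self) -> bool:
        return self.value is None


def freq_counting(call: int) -> FreqEstimate:
    """Allele-A frequency within one genotype: copies of A divided by 2."""
    if call == GENO_NOCALL:
        return FreqEstimate(None, method="counting")
    if call not in (0, 1, 2):
        raise ValidationError(f"invalid genotype code {call}")
    return FreqEstimate(call / 2.0, method="counting")


def freq_intensity(s1: float, s2: float, cpa: float) -> FreqEstimate:
    """Adjusted channel share s1 / (s1 + cpa * s2)."""
    if cpa <= 0 or not np.isfinite(cpa):
        raise ValidationError(f"cpa must be positive, got {cpa}")
    if s1 < 0 or s2 < 0:
        raise ValidationError("intensities must be nonnegative")
    if s1 == 0 and s2 == 0:
        return FreqEstimate(None, method="intensity")
    return FreqEstimate(s1 / (s1 + cpa * s2), method="intensity")


def freq_matrix(intens: IntensityTable, cpa: CPATable) -> AlleleFreqMatrix:
    """Element-wise adjusted frequencies for a whole intensity table.

    Masked inputs stay masked; SNPs whose correction factor is missing get a
    fully masked row (with a warning).  Fallback factors (1.0) are applied
    as-is so that a frequency always exists.
    """
    if not np.array_equal(intens.annotation.snp_id, cpa.snp_id):
        raise ValidationError("intensity table and CPA table cover different SNPs")
    k = cpa.cpa[:, None]
    s1, s2 = intens.s1, intens.s2
    denom = s1 + k * s2
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, s1 / np.where(denom > 0, denom, 1.0), 0.0)
    mask = intens.mask | (denom <= 0)
    if cpa.missing.any():
        n_miss = int(cpa.missing.sum())
        logger.warning("%d SNPs have missing CPA; their rows are masked", n_miss)
        mask[cpa.missing, :] = True
    freq = np.where(mask, 0.0, freq)
    return AlleleFreqMatrix(intens.annotation, list(intens.samples), freq, mask)


def popfreq_from_genotypes(calls: np.ndarray) -> FreqEstimate:
    """Population frequency as the mean counting frequency over called samples.

    Variance is the binomial p(1-p)/(2n) expected under random mating.
    """
    calls = np.asarray(calls)
    called = calls != GENO_NOCALL
    n = int(called.sum())
    if n == 0:
        return FreqEstimate(None, method="counting", n=0)
    p = float(calls[called].mean() / 2.0)
    var = p * (1.0 - p) / (2.0 * n)
    return FreqEstimate(p, variance=var, method="counting", n=n)


def popfreq_from_intensities(freqs: np.ndarray, mask: np.ndarray = None) -> FreqEstimate:
    """Population frequency as the mean of individual intensity-based values."""
    freqs = np.asarray(freqs, dtype=float)
    if mask is None:
        mask = ~np.isfinite(freqs)
    ok = ~np.asarray(mask, dtype=bool)
    n = int(ok.sum())
    if n == 0:
        return FreqEstimate(None, method="intensity", n=0)
    vals = freqs[ok]
    p = float(vals.mean())
    var = float(vals.var(ddof=1) / n) if n >= 2 else None
    return FreqEstimate(p, variance=var, method="intensity", n=n)


def popfreq_pooled(pool: PooledIntensity, cpa: float) -> FreqEstimate:
    """Population frequency from a DNA pool's channel signals."""
    if cpa <= 0 or not np.isfinite(cpa):
        raise ValidationError(f"cpa must be positive, got {cpa}")
    if pool.missing or (pool.s1_pool == 0 and pool.s2_pool == 0):
        return FreqEstimate(None, method="pooled", n=pool.pool_size)
    value = pool.s1_pool / (pool.s1_pool + cpa * pool.s2_pool)
    return FreqEstimate(value, method="pooled", n=pool.pool_size)
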
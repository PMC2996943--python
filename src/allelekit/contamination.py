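"""Tumor/normal mixture model for allele frequencies and purity inversion.

A sample is a mixture of 100(1-p)% tumor cells, in which the two alleles of
a germline-heterozygous SNP are present in a:b copies, and 100p% normal
cells with the balanced 1:1 ratio.  The observed frequency of the first
allele is then

    f1 = (p + a*(1-p)) / ((2 - (a+b))*p + (a+b))

which inverts in closed form to recover p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import GENO_Aa, ValidationError


@dataclass(frozen=True)
class MixtureModel:
    a: int  # tumor copies of the first allele
    b: int  # tumor copies of the second allele
    p: float  # normal-cell fraction

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValidationError("allele copy numbers must be nonnegative")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError("p must lie in [0, 1]")
        if self.a == 0 and self.b == 0 and self.p == 0:
            raise ValidationError("a, b and p cannot all be zero")


@dataclass(frozen=True)
class ContaminationEstimate:
    p_raw: float          # closed-form inversion, possibly outside [0, 1]
    in_range: bool
    f1: float | None = None   # segment-average low-band frequency, if any
    n_used: int | None = None

    @property
    def p(self) -> float:
        """Raw estimate clipped to [0, 1] (use p_raw + in_range to audit)."""
        return float(min(max(self.p_raw, 0.0), 1.0))


def mixture_freqs(model: MixtureModel) -> tuple[float, float]:
    """Allele frequencies (f1, f2) produced by the mixture; f1 + f2 = 1."""
    a, b, p = model.a, model.b, model.p
    denom = (2 - (a + b)) * p + (a + b)
    if denom <= 0:
        raise ValidationError("degenerate mixture: zero total allele copies")
    f1 = (p + a * (1 - p)) / denom
    f2 = ((1 - b) * p + b) / denom
    return f1, f2


def estimate_contamination(f1: float, f2: float, a: int, b: int,
                           tol: float = 1e-6) -> ContaminationEstimate:
    """Closed-form normal-cell fraction from observed allele frequencies.

        p = (a*(1 - f1) - b*f1) / ((1 - b)*f1 - (1 - a)*f2)

    valid when (1-a)*f2 != (1-b)*f1.  The raw value is reported with an
    in-range flag rather than silently clipped.
    """
    if abs(f1 + f2 - 1.0) > tol:
        raise ValidationError(f"f1 + f2 must equal 1 (got {f1 + f2})")
    denom = (1 - b) * f1 - (1 - a) * f2
    if denom == 0:
        raise ValidationError(
            "degenerate model: (1-a)*f2 == (1-b)*f1, contamination unidentifiable"
        )
    p_raw = (a * (1 - f1) - b * f1) / denom
    return ContaminationEstimate(p_raw=float(p_raw),
                                 in_range=bool(0.0 <= p_raw <= 1.0))


def segment_contamination(freqs: np.ndarray, calls: np.ndarray, a: int, b: int,
                          mask: np.ndarray = None,
                          min_snps: int = 10) -> ContaminationEstimate | None:
    """Contamination from a called segment's allele frequencies.

    Only SNPs heterozygous in the germline sense contribute.  Because allele
    labels are arbitrary per SNP, frequencies are folded to min(f, 1-f) and
    the segment f1 is the mean of the sub-0.5 folded values.  Fewer than
    ``min_snps`` usable SNPs yields None (missing).
    """
    freqs = np.asarray(freqs, dtype=float)
    calls = np.asarray(calls)
    if mask is None:
        mask = ~np.isfinite(freqs)
    usable = ~np.asarray(mask, dtype=bool) & (calls == GENO_Aa)
    folded = np.minimum(freqs[usable], 1.0 - freqs[usable])
    folded = folded[folded < 0.5]
    if len(folded) < min_snps:
        return None
    f1 = float(folded.mean())
    est = estimate_contamination(f1, 1.0 - f1, a, b)
    return ContaminationEstimate(p_raw=est.p_raw, in_range=est.in_range,
                                 f1=f1, n_used=len(folded))
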
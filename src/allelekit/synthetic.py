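"""Seeded generators for genotypes, two-channel intensities, pools and
tumor-mixture samples.

The generative model matches what the estimators assume: random-mating
genotype sampling per SNP, a per-SNP lognormal signal-ratio factor kappa,
and multiplicative lognormal intensity noise with a chosen coefficient of
variation.  Channels for absent alleles emit a 1% noise floor rather than
exact zeros so divide-by-zero paths see realistic background.

All randomness flows through numpy's PCG64 Generator seeded from the
config, so identical seeds give identical tables on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contamination import MixtureModel, mixture_freqs
from .core_io import (
    GENO_NOCALL,
    GenotypeMatrix,
    IntensityTable,
    PooledIntensity,
    SnpAnnotation,
    ValidationError,
)

NULL_CHANNEL_FLOOR = 0.01  # fraction of base_signal emitted by a zero-copy channel
SNP_SPACING_BP = 10_000


@dataclass(frozen=True)
class AberrationSpec:
    """A genomic region carrying tumor allele copies a:b mixed with fraction p
    of normal cells, applied to one sample."""

    chromosome: str
    start_snp: int  # 0-based index within the chromosome, inclusive
    end_snp: int    # inclusive
    a: int
    b: int
    p: float

    def __post_init__(self):
        if self.start_snp < 0 or self.end_snp < self.start_snp:
            raise ValidationError("invalid aberration SNP range")
        MixtureModel(self.a, self.b, max(self.p, 1e-12))  # validates a, b, p


@dataclass
class SimConfig:
    n_snps: int = 1000
    n_samples: int = 100
    maf_low: float = 0.1
    maf_high: float = 0.5
    cpa_log_sd: float = 0.5     # SD of ln(kappa)
    noise_cv: float = 0.10      # CV of multiplicative intensity noise
    base_signal: float = 1000.0
    seed: int = 0
    n_chromosomes: int = 1
    nocall_rate: float = 0.0
    sex_mode: bool = False

    def __post_init__(self):
        if self.n_snps < 1 or self.n_samples < 1 or self.n_chromosomes < 1:
            raise ValidationError("counts must be >= 1")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValidationError("need 0 < maf_low <= maf_high <= 0.5")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.base_signal <= 0:
            raise ValidationError("base_signal must be positive")
        if not 0 <= self.nocall_rate < 1:
            raise ValidationError("nocall_rate must be in [0, 1)")


@dataclass
class Truth:
    """Generative ground truth kept alongside the observable tables."""

    pop_freq: np.ndarray        # per-SNP allele-A frequency
    kappa: np.ndarray           # per-SNP signal-ratio factor
    genotypes: np.ndarray       # true copies of allele A (no NoCall)
    config: SimConfig
    sex: list[str] = None       # 'M'/'F' per sample in sex_mode
    aberrations: list[tuple[str, AberrationSpec]] = field(default_factory=list)


@dataclass
class Cohort:
    annotation: SnpAnnotation
    genotypes: GenotypeMatrix
    intensities: IntensityTable
    truth: Truth


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    s = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-s ** 2 / 2, sigma=s, size=shape)


def _make_annotation(n_snps: int, n_chromosomes: int,
                     chrom_names: list[str] | None = None) -> SnpAnnotation:
    if chrom_names is None:
        chrom_names = [str(i + 1) for i in range(n_chromosomes)]
    per = [n_snps // n_chromosomes] * n_chromosomes
    for i in range(n_snps % n_chromosomes):
        per[i] += 1
    chroms, positions, ids = [], [], []
    k = 0
    for c, n in zip(chrom_names, per):
        for j in range(n):
            chroms.append(c)
            positions.append((j + 1) * SNP_SPACING_BP)
            ids.append(f"snp{k:06d}")
            k += 1
    n = len(ids)
    return SnpAnnotation(
        np.array(ids, dtype=object), np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(["A"] * n, dtype=object), np.array(["C"] * n, dtype=object),
    )


def _intensities_from_copies(rng, copies_a: np.ndarray, copies_b: np.ndarray,
                             kappa: np.ndarray, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Channel signals given per-(SNP, sample) allele copy numbers."""
    base = cfg.base_signal
    floor = base * NULL_CHANNEL_FLOOR
    e1 = _noise(rng, cfg.noise_cv, copies_a.shape)
    e2 = _noise(rng, cfg.noise_cv, copies_a.shape)
    s1 = np.where(copies_a > 0,
                  kappa[:, None] * base * (copies_a / 2.0), floor) * e1
    s2 = np.where(copies_b > 0, base * (copies_b / 2.0), floor) * e2
    return s1, s2


def simulate_cohort(cfg: SimConfig, kappa: np.ndarray = None,
                    chrom_names: list[str] | None = None) -> Cohort:
    """Generate a full cohort: annotation, genotype calls, intensities, truth.

    Per SNP: the allele-A frequency is uniform on [maf_low, maf_high], the
    two alleles of each individual are independent Bernoulli draws (random
    mating), and kappa = exp(Normal(0, cpa_log_sd^2)) unless supplied.
    """
    rng = np.random.default_rng(cfg.seed)
    ann = _make_annotation(cfg.n_snps, cfg.n_chromosomes, chrom_names)
    r, c = cfg.n_snps, cfg.n_samples
    pop_freq = rng.uniform(cfg.maf_low, cfg.maf_high, size=r)
    genotypes = rng.binomial(2, pop_freq[:, None], size=(r, c)).astype(np.int8)
    if kappa is None:
        kappa = np.exp(rng.normal(0.0, cfg.cpa_log_sd, size=r))
    else:
        kappa = np.asarray(kappa, dtype=float)
        if kappa.shape != (r,):
            raise ValidationError("kappa must have one value per SNP")

    s1, s2 = _intensities_from_copies(rng, genotypes.astype(float),
                                      (2 - genotypes).astype(float), kappa, cfg)
    calls = genotypes.copy()
    if cfg.nocall_rate > 0:
        nc = rng.random((r, c)) < cfg.nocall_rate
        calls = np.where(nc, GENO_NOCALL, calls).astype(np.int8)

    samples = [f"sample{j:03d}" for j in range(c)]
    truth = Truth(pop_freq=pop_freq, kappa=kappa, genotypes=genotypes, config=cfg)
    return Cohort(
        annotation=ann,
        genotypes=GenotypeMatrix(ann, samples, calls),
        intensities=IntensityTable(ann, samples, s1, s2),
        truth=truth,
    )


def inject_aberration(cohort: Cohort, region: AberrationSpec, sample: str,
                      seed: int = 1) -> Cohort:
    """Overwrite one sample's intensities inside a region with the tumor/normal
    mixture signal implied by its germline genotypes.

    For a germline heterozygote the expected channel proportions follow the
    mixture frequencies for copies a:b; homozygotes keep all copies on one
    allele.  Total copy number scales signals (2p + (a+b)(1-p) vs 2), and
    multiplicative noise is re-drawn.  Returns a new Cohort; the input is
    not modified.
    """
    try:
        j = cohort.intensities.samples.index(sample)
    except ValueError:
        raise ValidationError(f"unknown sample {sample!r}") from None
    slices = cohort.annotation.chrom_slices()
    if region.chromosome not in slices:
        raise ValidationError(f"chromosome {region.chromosome!r} not in panel")
    sl = slices[region.chromosome]
    n_chrom = sl.stop - sl.start
    if region.end_snp >= n_chrom:
        raise ValidationError("aberration region extends past the chromosome")
    rows = np.arange(sl.start + region.start_snp, sl.start + region.end_snp + 1)

    a, b, p = region.a, region.b, region.p
    cfg = cohort.truth.config
    geno = cohort.truth.genotypes[rows, j].astype(float)  # copies of allele A
    c_tot = 2.0 * p + (a + b) * (1.0 - p)
    rng = np.random.default_rng((cfg.seed, seed, j))
    copies_a = np.empty(len(rows))
    copies_b = np.empty(len(rows))
    het = geno == 1
    if het.any():
        if c_tot > 0:
            f1, f2 = mixture_freqs(MixtureModel(a, b, p))
        else:
            f1 = f2 = 0.0
        # which germline haplotype carries the a-copies is arbitrary per SNP,
        # so heterozygotes populate both frequency bands (f1 and f2)
        flip = rng.random(int(het.sum())) < 0.5
        copies_a[het] = np.where(flip, f2, f1) * c_tot
        copies_b[het] = np.where(flip, f1, f2) * c_tot
    hom_a = geno == 2
    copies_a[hom_a] = c_tot
    copies_b[hom_a] = 0.0
    hom_b = geno == 0
    copies_a[hom_b] = 0.0
    copies_b[hom_b] = c_tot
    s1, s2 = _intensities_from_copies(
        rng, copies_a[:, None], copies_b[:, None],
        cohort.truth.kappa[rows], cfg,
    )
    new_s1 = cohort.intensities.s1.copy()
    new_s2 = cohort.intensities.s2.copy()
    new_s1[rows, j] = s1[:, 0]
    new_s2[rows, j] = s2[:, 0]
    intens = IntensityTable(cohort.annotation, list(cohort.intensities.samples),
                            new_s1, new_s2, cohort.intensities.mask.copy())
    truth = Truth(
        pop_freq=cohort.truth.pop_freq, kappa=cohort.truth.kappa,
        genotypes=cohort.truth.genotypes, config=cfg, sex=cohort.truth.sex,
        aberrations=cohort.truth.aberrations + [(sample, region)],
    )
    return Cohort(cohort.annotation, cohort.genotypes, intens, truth)


def simulate_pool(cohort: Cohort, subset: list[str],
                  pool_noise_cv: float = 0.0, seed: int = 2) -> list[PooledIntensity]:
    """Pool channel signals by summation over a subset of samples.

    Optional pool-level multiplicative noise is re-drawn with the given CV.
    """
    if not subset:
        raise ValidationError("pool subset must be nonempty")
    idx = []
    for s in subset:
        try:
            idx.append(cohort.intensities.samples.index(s))
        except ValueError:
            raise ValidationError(f"unknown sample {s!r}") from None
    s1 = cohort.intensities.s1[:, idx].sum(axis=1)
    s2 = cohort.intensities.s2[:, idx].sum(axis=1)
    if pool_noise_cv > 0:
        rng = np.random.default_rng((cohort.truth.config.seed, seed))
        s1 = s1 * _noise(rng, pool_noise_cv, s1.shape)
        s2 = s2 * _noise(rng, pool_noise_cv, s2.shape)
    return [
        PooledIntensity(snp, float(v1), float(v2), len(subset))
        for snp, v1, v2 in zip(cohort.annotation.snp_id, s1, s2)
    ]


def simulate_sex_panel(cfg: SimConfig) -> Cohort:
    """X-chromosome cohort with the first half of samples hemizygous (male).

    Males carry a single X allele per SNP, so their adjusted frequencies sit
    near 0/1 and their genotype calls are homozygous; females follow the
    standard random-mating model.
    """
    if not cfg.sex_mode:
        raise ValidationError("simulate_sex_panel requires sex_mode=True")
    rng = np.random.default_rng(cfg.seed)
    ann = _make_annotation(cfg.n_snps, 1, chrom_names=["X"])
    r, c = cfg.n_snps, cfg.n_samples
    n_male = c // 2
    sex = ["M"] * n_male + ["F"] * (c - n_male)
    pop_freq = rng.uniform(cfg.maf_low, cfg.maf_high, size=r)
    kappa = np.exp(rng.normal(0.0, cfg.cpa_log_sd, size=r))

    copies_a = np.empty((r, c))
    # males: one allele draw; females: two
    male_allele = rng.binomial(1, pop_freq[:, None], size=(r, n_male))
    copies_a[:, :n_male] = male_allele
    copies_a[:, n_male:] = rng.binomial(2, pop_freq[:, None], size=(r, c - n_male))
    total = np.empty((r, c))
    total[:, :n_male] = 1.0
    total[:, n_male:] = 2.0
    copies_b = total - copies_a

    s1, s2 = _intensities_from_copies(rng, copies_a, copies_b, kappa, cfg)
    # calls report copies on the diploid scale; male hemizygotes read as homozygous
    calls = np.where(total == 1, 2 * copies_a, copies_a).astype(np.int8)
    samples = [f"sample{j:03d}" for j in range(c)]
    truth = Truth(pop_freq=pop_freq, kappa=kappa,
                  genotypes=calls.copy(), config=cfg, sex=sex)
    return Cohort(ann, GenotypeMatrix(ann, samples, calls),
                  IntensityTable(ann, samples, s1, s2), truth)
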
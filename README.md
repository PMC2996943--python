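# allelekit

Intensity-based allele-frequency analysis for two-channel SNP-array data.

SNP arrays report a pair of signals per marker — one per allele. Because the
two alleles amplify and hybridize with different efficiency, the raw signal
ratio is biased per SNP. `allelekit` estimates a per-SNP correction factor
from heterozygous samples (whose true allele ratio is 1:1), converts
corrected signals into individual- and population-level allele frequencies
(including DNA pools, where genotypes are unrecoverable), and builds several
analyses on top of the corrected frequencies:

- **CPA estimation** (`allelekit.cpa`): per-SNP signal-ratio correction
  factors from heterozygotes, lognormal summaries, cross-cohort comparison.
- **Allele frequencies** (`allelekit.allelefreq`): counting-based and
  intensity-based individual frequencies, population frequencies from
  individuals or pools.
- **AI/LOH scanning** (`allelekit.aberration`): genotype-specific reference
  envelopes from normal controls, single-point allelic-imbalance and
  loss-of-heterozygosity flags, sliding-window indices, spline smoothing,
  and segment calls against per-anchor control quantiles.
- **Biplots** (`allelekit.biplot`): rank-2 SVD projection of a row-centered
  frequency matrix for sample classification, outlier detection, and SNP
  clustering.
- **Contamination** (`allelekit.contamination`): forward tumor/normal
  mixture model for allele frequencies and closed-form inversion of the
  normal-cell fraction from aberrant-segment frequencies.
- **Synthetic cohorts** (`allelekit.synthetic`): seeded generator of
  genotypes, intensities, pools, aberrant regions, and X-chromosome sex
  panels with the statistical structure the estimators assume.

## Command line

Everything is reachable through one entry point:

```sh
# generate a synthetic cohort (annotation, genotypes, intensities, truth)
allelekit simulate --seed 1 --n-snps 1000 --n-samples 100 --out sim/

# per-SNP correction factors from heterozygotes
allelekit cpa estimate --annotation sim/annotation.tsv \
    --intensities sim/intensities.tsv --genotypes sim/genotypes.tsv \
    --out cpa.tsv
allelekit cpa fit --cpa cpa.tsv
allelekit cpa compare --cpa-a cpa.tsv --cpa-b other_cohort.tsv

# adjusted individual-level frequencies, population frequencies, pools
allelekit freq individual --annotation sim/annotation.tsv \
    --intensities sim/intensities.tsv --cpa cpa.tsv --out freqs.tsv
allelekit freq population --annotation sim/annotation.tsv \
    --genotypes sim/genotypes.tsv --out popfreq.tsv
allelekit freq pooled --pools pools.tsv --cpa cpa.tsv --out poolfreq.tsv

# scan a patient against normal controls
allelekit aberration scan --annotation sim/annotation.tsv \
    --patient-freqs patient.tsv --control-freqs controls.tsv \
    --control-genotypes control_genos.tsv \
    --window 51 --z 3 --out-bed calls.bed --out-track track.tsv

# rank-2 biplot with clustering and outlier detection
allelekit biplot --annotation sim/annotation.tsv --freqs freqs.tsv \
    --k 3 --out-prefix biplot

# normal-cell contamination over an aberrant segment
allelekit purity --annotation sim/annotation.tsv --freqs freqs.tsv \
    --genotypes genos.tsv --sample sample030 \
    --segment chr9:100000-2000000 --model 0:1
```

File formats are plain TSV (long or wide intensity tables, AA/AB/BB/NC
genotype matrices, frequency matrices, CPA tables) plus BED for called
segments. Internal coordinates are 1-based inclusive; BED output is
0-based half-open.

## Notes on defaults

- Reference envelopes are mean ± 3·SD per genotype with the SD floored at
  0.01; both are configurable.
- The sliding window is 51 SNPs, stepping one SNP, truncated at chromosome
  ends; a called segment needs a run of at least `window` exceeding anchors.
- With 100 controls or fewer, the per-anchor control envelope is the
  control maximum rather than an interpolated 95% quantile (the
  interpolated quantile of a moderate control set produces correlated
  false-positive runs on null samples).
- Smoothing uses a cubic smoothing spline; the penalty is chosen by
  generalized cross-validation unless `--smoothing` is given (fixed
  penalties are much faster on long chromosomes).
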
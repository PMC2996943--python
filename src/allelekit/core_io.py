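"""Domain types and tab-delimited readers/writers.

All tables are SNP-major: rows follow the annotation order, which is the
canonical sort (chromosome in natural order 1..22, X; then position; then
snp_id as a stable tie-break).  Missing data is carried as an explicit
boolean mask (True = missing); a zero intensity is data, not missingness.
Coordinates are 1-based inclusive internally; only the BED export converts
to 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Genotype codes: number of copies of allele A; -1 encodes a failed call.
GENO_aa = 0
GENO_Aa = 1
GENO_AA = 2
GENO_NOCALL = -1

_CALL_TO_CODE = {"AA": GENO_AA, "AB": GENO_Aa, "BB": GENO_aa, "NC": GENO_NOCALL}
_CODE_TO_CALL = {v: k for k, v in _CALL_TO_CODE.items()}

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X",)
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


class ValidationError(ValueError):
    """Raised when an input table violates a format or domain contract."""


def chromosome_rank(chrom: str) -> int:
    try:
        return _CHROM_RANK[str(chrom)]
    except KeyError:
        raise ValidationError(
            f"unsupported chromosome {chrom!r}; expected one of 1..22, X"
        ) from None


@dataclass(frozen=True)
class SnpAnnotation:
    """Per-SNP annotation: ids, genomic placement and allele labels.

    Arrays are parallel; records are kept in canonical sorted order.
    """

    snp_id: np.ndarray        # str
    chromosome: np.ndarray    # str, one of CHROMOSOMES
    position: np.ndarray      # int, 1-based
    allele_a: np.ndarray      # str, single nucleotide
    allele_b: np.ndarray      # str

    def __post_init__(self):
        snp_id = np.asarray(self.snp_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=object).astype(str).astype(object)
        pos = np.asarray(self.position, dtype=np.int64)
        aa = np.asarray(self.allele_a, dtype=object)
        ab = np.asarray(self.allele_b, dtype=object)
        n = len(snp_id)
        if not (len(chrom) == len(pos) == len(aa) == len(ab) == n):
            raise ValidationError("annotation arrays have unequal lengths")
        if len(set(snp_id)) != n:
            raise ValidationError("snp_id values are not unique")
        if n and pos.min() < 1:
            bad = snp_id[int(np.argmin(pos))]
            raise ValidationError(f"position < 1 for SNP {bad!r}")
        ranks = np.array([chromosome_rank(c) for c in chrom], dtype=np.int64)
        order = np.lexsort((snp_id, pos, ranks))
        object.__setattr__(self, "snp_id", snp_id[order])
        object.__setattr__(self, "chromosome", chrom[order])
        object.__setattr__(self, "position", pos[order])
        object.__setattr__(self, "allele_a", aa[order])
        object.__setattr__(self, "allele_b", ab[order])

    def __len__(self) -> int:
        return len(self.snp_id)

    def index_of(self, snp_ids) -> np.ndarray:
        """Row indices of the given snp_ids; raises on unknown ids."""
        lookup = {s: i for i, s in enumerate(self.snp_id)}
        out = np.empty(len(snp_ids), dtype=np.int64)
        for j, s in enumerate(snp_ids):
            try:
                out[j] = lookup[s]
            except KeyError:
                raise ValidationError(f"SNP {s!r} not present in annotation") from None
        return out

    def subset(self, rows: np.ndarray) -> "SnpAnnotation":
        return SnpAnnotation(
            self.snp_id[rows], self.chromosome[rows], self.position[rows],
            self.allele_a[rows], self.allele_b[rows],
        )

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome, in canonical order."""
        out: dict[str, slice] = {}
        chroms = self.chromosome
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[str(chroms[start])] = slice(start, i)
                start = i
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id, "chromosome": self.chromosome,
            "position": self.position, "allele_a": self.allele_a,
            "allele_b": self.allele_b,
        })


def _check_matrix(name, arr, n_snps, n_samples, dtype=float):
    arr = np.asarray(arr, dtype=dtype)
    if arr.shape != (n_snps, n_samples):
        raise ValidationError(
            f"{name} has shape {arr.shape}, expected {(n_snps, n_samples)}"
        )
    return arr


@dataclass
class IntensityTable:
    """Two-channel signals per (SNP, sample): s1 for allele A, s2 for allele a."""

    annotation: SnpAnnotation
    samples: list[str]
    s1: np.ndarray
    s2: np.ndarray
    mask: np.ndarray = None  # True where the pair is missing

    def __post_init__(self):
        r, c = len(self.annotation), len(self.samples)
        self.samples = [str(s) for s in self.samples]
        if len(set(self.samples)) != c:
            raise ValidationError("duplicate sample ids")
        self.s1 = _check_matrix("s1", self.s1, r, c)
        self.s2 = _check_matrix("s2", self.s2, r, c)
        if self.mask is None:
            self.mask = np.zeros((r, c), dtype=bool)
        self.mask = _check_matrix("mask", self.mask, r, c, dtype=bool)
        for name, m in (("s1", self.s1), ("s2", self.s2)):
            bad = ~np.isfinite(m) & ~self.mask
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-finite {name} at SNP {self.annotation.snp_id[i]!r}, "
                    f"sample {self.samples[j]!r}"
                )
            neg = (m < 0) & ~self.mask
            if neg.any():
                i, j = np.argwhere(neg)[0]
                raise ValidationError(
                    f"negative {name} at SNP {self.annotation.snp_id[i]!r}, "
                    f"sample {self.samples[j]!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.s1.shape


@dataclass
class GenotypeMatrix:
    """Integer-coded genotype calls aligned with an annotation."""

    annotation: SnpAnnotation
    samples: list[str]
    calls: np.ndarray  # int8 codes GENO_*

    def __post_init__(self):
        r, c = len(self.annotation), len(self.samples)
        self.samples = [str(s) for s in self.samples]
        self.calls = _check_matrix("calls", self.calls, r, c, dtype=np.int8)
        ok = np.isin(self.calls, (GENO_aa, GENO_Aa, GENO_AA, GENO_NOCALL))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"invalid genotype code {self.calls[i, j]} at SNP "
                f"{self.annotation.snp_id[i]!r}, sample {self.samples[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape


@dataclass
class AlleleFreqMatrix:
    """Individual-level allele frequencies in [0, 1] with a missing mask."""

    annotation: SnpAnnotation
    samples: list[str]
    freq: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        r, c = len(self.annotation), len(self.samples)
        self.samples = [str(s) for s in self.samples]
        self.freq = _check_matrix("freq", self.freq, r, c)
        if self.mask is None:
            self.mask = ~np.isfinite(self.freq)
        self.mask = _check_matrix("mask", self.mask, r, c, dtype=bool)
        valid = ~self.mask
        vals = self.freq[valid]
        if vals.size and (not np.isfinite(vals).all() or vals.min() < 0 or vals.max() > 1):
            raise ValidationError("non-missing frequency outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.freq.shape


@dataclass
class CPATable:
    """Per-SNP signal-ratio correction factors estimated from heterozygotes."""

    snp_id: np.ndarray
    cpa: np.ndarray       # positive; 1.0 where fallback
    n_het: np.ndarray     # int
    cv: np.ndarray        # NaN when < 2 heterozygotes
    fallback: np.ndarray  # True where n_het < min_het (cpa forced to 1)
    missing: np.ndarray = None  # True where the ratio was incomputable
    annotation: SnpAnnotation = None

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        n = len(self.snp_id)
        self.cpa = np.asarray(self.cpa, dtype=float)
        self.n_het = np.asarray(self.n_het, dtype=np.int64)
        self.cv = np.asarray(self.cv, dtype=float)
        self.fallback = np.asarray(self.fallback, dtype=bool)
        if self.missing is None:
            self.missing = np.zeros(n, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        for name, a in (("cpa", self.cpa), ("n_het", self.n_het),
                        ("cv", self.cv), ("fallback", self.fallback),
                        ("missing", self.missing)):
            if len(a) != n:
                raise ValidationError(f"CPATable field {name} has wrong length")
        usable = ~self.missing
        if usable.any() and not (self.cpa[usable] > 0).all():
            raise ValidationError("non-positive CPA for a non-missing SNP")

    @property
    def log2_cpa(self) -> np.ndarray:
        out = np.full(len(self.snp_id), np.nan)
        ok = ~self.missing
        out[ok] = np.log2(self.cpa[ok])
        return out

    def __len__(self) -> int:
        return len(self.snp_id)


@dataclass(frozen=True)
class PooledIntensity:
    """Channel signals measured on a DNA pool of ``pool_size`` individuals."""

    snp_id: str
    s1_pool: float
    s2_pool: float
    pool_size: int
    missing: bool = False

    def __post_init__(self):
        if self.pool_size < 1:
            raise ValidationError("pool_size must be >= 1")
        if not self.missing:
            if self.s1_pool < 0 or self.s2_pool < 0:
                raise ValidationError("negative pool intensity")


@dataclass(frozen=True)
class Segment:
    """One aberrant genomic interval, 1-based inclusive in base pairs."""

    chromosome: str
    start_pos: int
    end_pos: int
    label: str               # "AI" or "LOH"
    mean_index: float
    whole_chromosome: bool = False

    def __post_init__(self):
        if self.label not in ("AI", "LOH"):
            raise ValidationError(f"unknown segment label {self.label!r}")
        if self.start_pos > self.end_pos:
            raise ValidationError("segment start after end")


@dataclass
class AberrationCalls:
    """All called segments for a single sample."""

    sample: str
    segments: list[Segment] = field(default_factory=list)

    def merged(self) -> "AberrationCalls":
        """Merge overlapping/abutting same-label segments (warns when it happens)."""
        out: list[Segment] = []
        for label in ("AI", "LOH"):
            segs = sorted(
                (s for s in self.segments if s.label == label),
                key=lambda s: (chromosome_rank(s.chromosome), s.start_pos),
            )
            merged: list[Segment] = []
            for seg in segs:
                if merged and merged[-1].chromosome == seg.chromosome \
                        and seg.start_pos <= merged[-1].end_pos + 1:
                    prev = merged[-1]
                    logger.warning(
                        "merging overlapping %s segments for sample %s on chr%s",
                        label, self.sample, seg.chromosome,
                    )
                    merged[-1] = replace(
                        prev,
                        end_pos=max(prev.end_pos, seg.end_pos),
                        mean_index=(prev.mean_index + seg.mean_index) / 2,
                        whole_chromosome=prev.whole_chromosome or seg.whole_chromosome,
                    )
                else:
                    merged.append(seg)
            out.extend(merged)
        out.sort(key=lambda s: (chromosome_rank(s.chromosome), s.start_pos, s.label))
        return AberrationCalls(self.sample, out)


# ---------------------------------------------------------------------------
# Annotation I/O

def read_annotation(path) -> SnpAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "chromosome", "position", "allele_a", "allele_b"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation file missing columns {missing}")
    return SnpAnnotation(
        df["snp_id"].to_numpy(object),
        df["chromosome"].to_numpy(object),
        df["position"].astype(int).to_numpy(),
        df["allele_a"].to_numpy(object),
        df["allele_b"].to_numpy(object),
    )


def write_annotation(annotation: SnpAnnotation, path) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intensity I/O

def read_intensity_table(path, annotation: SnpAnnotation,
                         dialect: str = "long") -> IntensityTable:
    """Read a two-channel intensity TSV in ``long`` or ``wide`` dialect.

    Long form has columns (snp_id, sample_id, s1, s2); absent pairs are
    masked.  Wide form has a snp_id column followed by ``<sample>.s1`` /
    ``<sample>.s2`` column pairs; empty cells are masked.
    """
    if dialect == "long":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "sample_id": str})
        for col in ("snp_id", "sample_id", "s1", "s2"):
            if col not in df.columns:
                raise ValidationError(f"long-form intensity file missing column {col!r}")
        if df.duplicated(["snp_id", "sample_id"]).any():
            dup = df[df.duplicated(["snp_id", "sample_id"])].iloc[0]
            raise ValidationError(
                f"duplicate row for SNP {dup.snp_id!r}, sample {dup.sample_id!r}"
            )
        samples = sorted(df["sample_id"].unique())
        col_of = {s: j for j, s in enumerate(samples)}
        r, c = len(annotation), len(samples)
        s1 = np.zeros((r, c))
        s2 = np.zeros((r, c))
        mask = np.ones((r, c), dtype=bool)
        rows = annotation.index_of(df["snp_id"].to_numpy(object))
        cols = np.array([col_of[s] for s in df["sample_id"]], dtype=np.int64)
        v1 = df["s1"].to_numpy(float)
        v2 = df["s2"].to_numpy(float)
        for k in range(len(df)):
            if (v1[k] < 0) or (v2[k] < 0):
                raise ValidationError(
                    f"negative intensity at SNP {df['snp_id'].iat[k]!r}, "
                    f"sample {df['sample_id'].iat[k]!r} (row {k + 2})"
                )
        s1[rows, cols] = v1
        s2[rows, cols] = v2
        mask[rows, cols] = ~(np.isfinite(v1) & np.isfinite(v2))
        s1[~np.isfinite(s1)] = 0.0
        s2[~np.isfinite(s2)] = 0.0
        return IntensityTable(annotation, samples, s1, s2, mask)
    elif dialect == "wide":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
        if "snp_id" not in df.columns:
            raise ValidationError("wide-form intensity file missing 'snp_id'")
        samples = []
        for col in df.columns[1:]:
            if col.endswith(".s1"):
                samples.append(col[:-3])
        for s in samples:
            if f"{s}.s2" not in df.columns:
                raise ValidationError(f"wide-form file missing column {s}.s2")
        rows = annotation.index_of(df["snp_id"].to_numpy(object))
        if len(set(rows.tolist())) != len(rows):
            raise ValidationError("duplicate snp_id rows in wide-form file")
        r, c = len(annotation), len(samples)
        s1 = np.zeros((r, c))
        s2 = np.zeros((r, c))
        mask = np.ones((r, c), dtype=bool)
        for j, s in enumerate(samples):
            v1 = df[f"{s}.s1"].to_numpy(float)
            v2 = df[f"{s}.s2"].to_numpy(float)
            neg = (v1 < 0) | (v2 < 0)
            if neg.any():
                k = int(np.argwhere(neg)[0])
                raise ValidationError(
                    f"negative intensity at SNP {df['snp_id'].iat[k]!r}, sample {s!r}"
                )
            ok = np.isfinite(v1) & np.isfinite(v2)
            s1[rows, j] = np.where(ok, v1, 0.0)
            s2[rows, j] = np.where(ok, v2, 0.0)
            mask[rows, j] = ~ok
        return IntensityTable(annotation, samples, s1, s2, mask)
    raise ValidationError(f"unknown intensity dialect {dialect!r}")


def write_intensity_table(table: IntensityTable, path, dialect: str = "long") -> None:
    if dialect == "long":
        recs = []
        for i, snp in enumerate(table.annotation.snp_id):
            for j, sample in enumerate(table.samples):
                if table.mask[i, j]:
                    continue
                recs.append((snp, sample, table.s1[i, j], table.s2[i, j]))
        pd.DataFrame(recs, columns=["snp_id", "sample_id", "s1", "s2"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g")
    elif dialect == "wide":
        data = {"snp_id": table.annotation.snp_id}
        for j, s in enumerate(table.samples):
            v1 = table.s1[:, j].astype(object)
            v2 = table.s2[:, j].astype(object)
            v1[table.mask[:, j]] = np.nan
            v2[table.mask[:, j]] = np.nan
            data[f"{s}.s1"] = v1
            data[f"{s}.s2"] = v2
        pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        raise ValidationError(f"unknown intensity dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Genotype I/O

def read_genotype_matrix(path, annotation: SnpAnnotation) -> GenotypeMatrix:
    """Read a genotype TSV (snp_id column + one AA/AB/BB/NC column per sample)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "snp_id" not in df.columns:
        raise ValidationError("genotype file missing 'snp_id' column")
    samples = list(df.columns[1:])
    rows = annotation.index_of(df["snp_id"].to_numpy(object))
    calls = np.full((len(annotation), len(samples)), GENO_NOCALL, dtype=np.int8)
    for j, s in enumerate(samples):
        for k, code in enumerate(df[s]):
            try:
                calls[rows[k], j] = _CALL_TO_CODE[code]
            except KeyError:
                raise ValidationError(
                    f"unknown genotype code {code!r} at SNP "
                    f"{df['snp_id'].iat[k]!r}, sample {s!r}"
                ) from None
    return GenotypeMatrix(annotation, samples, calls)


def write_genotype_matrix(genos: GenotypeMatrix, path) -> None:
    data = {"snp_id": genos.annotation.snp_id}
    for j, s in enumerate(genos.samples):
        data[s] = [_CODE_TO_CALL[int(c)] for c in genos.calls[:, j]]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele-frequency matrix I/O

def read_freq_matrix(path, annotation: SnpAnnotation) -> AlleleFreqMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    if "snp_id" not in df.columns:
        raise ValidationError("frequency file missing 'snp_id' column")
    samples = list(df.columns[1:])
    rows = annotation.index_of(df["snp_id"].to_numpy(object))
    freq = np.full((len(annotation), len(samples)), np.nan)
    for j, s in enumerate(samples):
        freq[rows, j] = df[s].to_numpy(float)
    mask = ~np.isfinite(freq)
    freq[mask] = 0.0
    return AlleleFreqMatrix(annotation, samples, freq, mask)


def write_freq_matrix(freqs: AlleleFreqMatrix, path) -> None:
    data = {"snp_id": freqs.annotation.snp_id}
    for j, s in enumerate(freqs.samples):
        col = freqs.freq[:, j].astype(object)
        col[freqs.mask[:, j]] = np.nan
        data[s] = col
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# CPA table I/O

def write_cpa_table(cpa: CPATable, path, annotation: SnpAnnotation = None) -> None:
    ann = annotation or cpa.annotation
    df = pd.DataFrame({"snp_id": cpa.snp_id})
    if ann is not None:
        idx = ann.index_of(cpa.snp_id)
        df["chromosome"] = ann.chromosome[idx]
        df["position"] = ann.position[idx]
    df["cpa"] = np.where(cpa.missing, np.nan, cpa.cpa)
    df["log2_cpa"] = cpa.log2_cpa
    df["n_het"] = cpa.n_het
    df["cv"] = cpa.cv
    df["fallback"] = cpa.fallback.astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cpa_table(path, annotation: SnpAnnotation = None) -> CPATable:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    for col in ("snp_id", "cpa", "n_het", "fallback"):
        if col not in df.columns:
            raise ValidationError(f"CPA file missing column {col!r}")
    cpa_vals = df["cpa"].to_numpy(float)
    missing = ~np.isfinite(cpa_vals)
    cpa_vals = np.where(missing, 1.0, cpa_vals)
    cv = df["cv"].to_numpy(float) if "cv" in df.columns else np.full(len(df), np.nan)
    return CPATable(
        df["snp_id"].to_numpy(object), cpa_vals,
        df["n_het"].astype(int).to_numpy(),
        cv, df["fallback"].astype(bool).to_numpy(), missing,
        annotation=annotation,
    )


# ---------------------------------------------------------------------------
# Pooled-intensity I/O

def read_pooled_intensities(path) -> list[PooledIntensity]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    for col in ("snp_id", "s1_pool", "s2_pool", "pool_size"):
        if col not in df.columns:
            raise ValidationError(f"pooled file missing column {col!r}")
    out = []
    for rec in df.itertuples(index=False):
        s1, s2 = float(rec.s1_pool), float(rec.s2_pool)
        miss = not (np.isfinite(s1) and np.isfinite(s2))
        out.append(PooledIntensity(
            rec.snp_id, 0.0 if miss else s1, 0.0 if miss else s2,
            int(rec.pool_size), missing=miss,
        ))
    return out


def write_pooled_intensities(pools: list[PooledIntensity], path) -> None:
    df = pd.DataFrame(
        [(p.snp_id, np.nan if p.missing else p.s1_pool,
          np.nan if p.missing else p.s2_pool, p.pool_size) for p in pools],
        columns=["snp_id", "s1_pool", "s2_pool", "pool_size"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# BED export

def write_regions_bed(calls, path) -> None:
    """Write aberration calls as BED (0-based, half-open).

    ``calls`` is a single AberrationCalls or a list of them.  Same-label
    overlapping segments for one sample are merged with a logged warning.
    """
    if isinstance(calls, AberrationCalls):
        calls = [calls]
    records = []
    for per_sample in calls:
        for seg in per_sample.merged().segments:
            records.append((
                chromosome_rank(seg.chromosome), seg.chromosome,
                seg.start_pos - 1, seg.end_pos,
                f"{seg.label}|{per_sample.sample}",
                seg.mean_index, seg.whole_chromosome,
            ))
    records.sort(key=lambda r: (r[0], r[2], r[4]))
    with open(path, "w") as fh:
        fh.write('track name=aberration_calls description="AI/LOH segment calls"\n')
        for _, chrom, start, end, name, score, whole in records:
            extra = "\twhole_chromosome" if whole else ""
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:.4f}{extra}\n")
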
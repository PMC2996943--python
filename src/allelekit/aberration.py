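"""Sliding-window allelic-imbalance (AI) and LOH/LCSH scanning.

Pipeline: build genotype-specific reference envelopes (mean +/- z*sd per
genotype per SNP) from normal controls; flag each patient SNP whose adjusted
allele frequency falls outside all envelopes (AI) or outside the
heterozygous envelope (LOH/LCSH); average flags in a sliding window along
each chromosome; smooth the window tracks with a cubic smoothing spline; and
call segments where a patient's smoothed track exceeds the per-anchor
95%-quantile of the control tracks over a minimum run of anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .core_io import (
    GENO_NOCALL,
    AberrationCalls,
    AlleleFreqMatrix,
    GenotypeMatrix,
    Segment,
    SnpAnnotation,
    ValidationError,
)

GENOTYPE_ORDER = ("aa", "Aa", "AA")  # axis order for per-genotype arrays


@dataclass
class ReferenceBands:
    """Per-SNP, per-genotype frequency envelopes from a reference cohort."""

    annotation: SnpAnnotation
    mean: np.ndarray      # (n_snps, 3) in GENOTYPE_ORDER; NaN = band missing
    sd: np.ndarray        # floored at sd_floor
    n: np.ndarray         # samples contributing to each band
    z: float
    sd_floor: float

    @property
    def lower(self) -> np.ndarray:
        return self.mean - self.z * self.sd

    @property
    def upper(self) -> np.ndarray:
        return self.mean + self.z * self.sd

    def misordered(self) -> np.ndarray:
        """SNPs whose band centers are not ordered aa < Aa < AA (flag only)."""
        m = self.mean
        with np.errstate(invalid="ignore"):
            return (m[:, 0] >= m[:, 1]) | (m[:, 1] >= m[:, 2])


@dataclass
class PointFlags:
    """Per-(SNP, sample) AI and LOH indicator flags; NaN = undefined."""

    annotation: SnpAnnotation
    samples: list[str]
    ai: np.ndarray   # float matrix of {0, 1, NaN}
    loh: np.ndarray


@dataclass
class WindowTrack:
    """Sliding-window AI/LOH index tracks anchored at each SNP."""

    annotation: SnpAnnotation
    samples: list[str]
    window_size: int
    ai_index: np.ndarray           # (n_snps, n_samples), NaN where undefined
    loh_index: np.ndarray
    ai_smooth: np.ndarray = None   # filled by smooth_track
    loh_smooth: np.ndarray = None

    def sample_track(self, sample: str) -> "WindowTrack":
        j = self.samples.index(sample)
        sel = slice(j, j + 1)
        return WindowTrack(
            self.annotation, [sample], self.window_size,
            self.ai_index[:, sel], self.loh_index[:, sel],
            None if self.ai_smooth is None else self.ai_smooth[:, sel],
            None if self.loh_smooth is None else self.loh_smooth[:, sel],
        )

    def split_samples(self) -> list["WindowTrack"]:
        return [self.sample_track(s) for s in self.samples]


def build_reference_bands(freqs: AlleleFreqMatrix, calls: GenotypeMatrix,
                          z: float = 3.0, sd_floor: float = 0.01) -> ReferenceBands:
    """Mean/SD envelopes per (SNP, genotype) from unmasked reference entries.

    A band needs at least two contributing samples; SDs are floored at
    ``sd_floor`` so constant references still yield a usable interval.
    """
    if freqs.shape != calls.shape:
        raise ValidationError("frequency and genotype tables have different shapes")
    if z <= 0:
        raise ValidationError("z must be positive")
    if sd_floor <= 0:
        raise ValidationError("sd_floor must be positive")
    r = freqs.shape[0]
    mean = np.full((r, 3), np.nan)
    sd = np.full((r, 3), np.nan)
    n = np.zeros((r, 3), dtype=np.int64)
    valid = ~freqs.mask & (calls.calls != GENO_NOCALL)
    for g in range(3):
        sel = valid & (calls.calls == g)
        cnt = sel.sum(axis=1)
        n[:, g] = cnt
        vals = np.where(sel, freqs.freq, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = vals.sum(axis=1) / np.maximum(cnt, 1)
            ssq = (np.where(sel, (freqs.freq - mu[:, None]) ** 2, 0.0)).sum(axis=1)
            s = np.sqrt(ssq / np.maximum(cnt - 1, 1))
        ok = cnt >= 2
        mean[ok, g] = mu[ok]
        sd[ok, g] = np.maximum(s[ok], sd_floor)
    return ReferenceBands(freqs.annotation, mean, sd, n, float(z), float(sd_floor))


def flag_points(freqs: AlleleFreqMatrix, bands: ReferenceBands) -> PointFlags:
    """Single-point AI and LOH flags for every unmasked patient frequency.

    AI: frequency outside every available genotype envelope.  LOH/LCSH:
    frequency outside the heterozygous (Aa) envelope.  A SNP with no
    envelopes (or, for LOH, no Aa envelope) yields undefined flags.
    """
    if not np.array_equal(freqs.annotation.snp_id, bands.annotation.snp_id):
        raise ValidationError("frequency matrix and bands cover different SNPs")
    lower, upper = bands.lower, bands.upper
    have_band = np.isfinite(bands.mean)           # (R, 3)
    any_band = have_band.any(axis=1)
    have_het = have_band[:, 1]

    f = freqs.freq[:, :, None]                     # (R, C, 1)
    with np.errstate(invalid="ignore"):
        inside = (f >= lower[:, None, :]) & (f <= upper[:, None, :])
    inside &= have_band[:, None, :]
    inside_any = inside.any(axis=2)
    inside_het = inside[:, :, 1]

    ai = np.where(~inside_any, 1.0, 0.0)
    loh = np.where(~inside_het, 1.0, 0.0)
    undefined = freqs.mask | ~any_band[:, None]
    ai[undefined] = np.nan
    loh[freqs.mask | ~have_het[:, None]] = np.nan
    return PointFlags(freqs.annotation, list(freqs.samples), ai, loh)


def flag_points_loo(freqs: AlleleFreqMatrix, calls: GenotypeMatrix,
                    z: float = 3.0, sd_floor: float = 0.01) -> PointFlags:
    """Leave-one-out point flags for the reference cohort itself.

    Each control is flagged against envelopes recomputed without its own
    contribution to its genotype class (the other two classes keep the full
    cohort).  Use this for control tracks so that controls and out-of-cohort
    patients face equivalently independent envelopes; flagging controls
    against bands they helped build deflates their flag rate and biases the
    exceedance comparison against the patient.
    """
    full = build_reference_bands(freqs, calls, z=z, sd_floor=sd_floor)
    r, c = freqs.shape
    valid = ~freqs.mask & (calls.calls != GENO_NOCALL)
    f = freqs.freq

    # per-(SNP, genotype) sums for O(1) leave-one-out moments
    sums = np.zeros((r, 3))
    sumsq = np.zeros((r, 3))
    counts = np.zeros((r, 3), dtype=np.int64)
    for g in range(3):
        sel = valid & (calls.calls == g)
        vals = np.where(sel, f, 0.0)
        sums[:, g] = vals.sum(axis=1)
        sumsq[:, g] = (vals ** 2).sum(axis=1)
        counts[:, g] = sel.sum(axis=1)

    g_own = np.where(valid, calls.calls, 0).astype(np.int64)  # dummy 0 where invalid
    rows = np.arange(r)[:, None]
    n_own = counts[rows, g_own]
    s_own = sums[rows, g_own]
    ss_own = sumsq[rows, g_own]
    n_loo = n_own - valid.astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_loo = (s_own - np.where(valid, f, 0.0)) / np.maximum(n_loo, 1)
        var_loo = (ss_own - np.where(valid, f ** 2, 0.0)
                   - n_loo * mean_loo ** 2) / np.maximum(n_loo - 1, 1)
    sd_loo = np.maximum(np.sqrt(np.maximum(var_loo, 0.0)), sd_floor)
    have_own = valid & (n_loo >= 2)
    inside_own = have_own & (np.abs(f - mean_loo) <= z * sd_loo)

    lower, upper = full.lower, full.upper
    have_full = np.isfinite(full.mean)  # (R, 3)
    inside_g = np.zeros((r, c, 3), dtype=bool)
    with np.errstate(invalid="ignore"):
        for g in range(3):
            inside_g[:, :, g] = have_full[:, g][:, None] \
                & (f >= lower[:, g][:, None]) & (f <= upper[:, g][:, None])

    own_onehot = np.zeros((r, c, 3), dtype=bool)
    own_onehot[rows, np.arange(c)[None, :], g_own] = valid
    # own class judged by LOO band; other classes by full-cohort bands
    inside_any = inside_own | (inside_g & ~own_onehot).any(axis=2)
    het_is_own = own_onehot[:, :, 1]
    inside_het = np.where(het_is_own, inside_own, inside_g[:, :, 1])
    have_het = np.where(het_is_own, have_own, have_full[:, 1][:, None])

    any_band = have_own | (have_full[:, None, :] & ~own_onehot).any(axis=2)
    ai = np.where(~inside_any, 1.0, 0.0)
    loh = np.where(~inside_het, 1.0, 0.0)
    ai[freqs.mask | ~any_band] = np.nan
    loh[freqs.mask | ~have_het] = np.nan
    return PointFlags(freqs.annotation, list(freqs.samples), ai, loh)


def _window_mean(flags: np.ndarray, half: int) -> np.ndarray:
    """Mean over a centered window of half-width ``half`` along axis 0,
    truncated at the ends, with NaN flags excluded from both numerator and
    denominator.  Cumulative-sum implementation; anchors whose window holds
    no defined flag are NaN."""
    vals = np.nan_to_num(flags, nan=0.0)
    cnt = np.isfinite(flags).astype(float)
    csum = np.cumsum(vals, axis=0)
    ccnt = np.cumsum(cnt, axis=0)
    csum = np.vstack([np.zeros((1, flags.shape[1])), csum])
    ccnt = np.vstack([np.zeros((1, flags.shape[1])), ccnt])
    n = flags.shape[0]
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1) + 1
    num = csum[hi] - csum[lo]
    den = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def window_indices(flags: PointFlags, window_size: int = 51) -> WindowTrack:
    """Sliding-window mean of the point flags, one anchor per SNP.

    Windows are centered, slide one SNP at a time, never cross chromosome
    boundaries, and are truncated symmetrically-by-clipping at chromosome
    ends.  Undefined flags contribute to neither numerator nor denominator.
    """
    if window_size < 1 or window_size % 2 == 0:
        raise ValidationError("window_size must be a positive odd integer")
    half = window_size // 2
    r, c = flags.ai.shape
    ai_idx = np.full((r, c), np.nan)
    loh_idx = np.full((r, c), np.nan)
    for _, sl in flags.annotation.chrom_slices().items():
        ai_idx[sl] = _window_mean(flags.ai[sl], half)
        loh_idx[sl] = _window_mean(flags.loh[sl], half)
    return WindowTrack(flags.annotation, list(flags.samples), window_size,
                       ai_idx, loh_idx)


def _smooth_vector(x: np.ndarray, y: np.ndarray, lam: float | None,
                   min_anchors: int) -> np.ndarray:
    out = y.copy()
    ok = np.isfinite(y)
    if ok.sum() < min_anchors:
        return out
    xs = x[ok].astype(float)
    # rescale to unit median spacing so a fixed penalty has the same meaning
    # on any marker density; make_smoothing_spline needs strictly increasing x
    step = np.median(np.diff(xs)) if len(xs) > 1 else 1.0
    xs = xs / max(step, 1e-12)
    if np.any(np.diff(xs) <= 0):
        xs = xs + np.arange(len(xs)) * 1e-6
    spline = make_smoothing_spline(xs, y[ok], lam=lam)
    out[ok] = np.clip(spline(xs), 0.0, 1.0)
    return out


def smooth_track(track: WindowTrack, smoothing_param: float | None = None,
                 min_anchors: int = 10) -> WindowTrack:
    """Cubic smoothing spline (GCV-chosen penalty unless given) per chromosome.

    Chromosomes with fewer than ``min_anchors`` defined anchors keep the raw
    track.  Smoothed values are clipped to [0, 1].
    """
    r, c = track.ai_index.shape
    ai_s = np.full((r, c), np.nan)
    loh_s = np.full((r, c), np.nan)
    for _, sl in track.annotation.chrom_slices().items():
        pos = track.annotation.position[sl]
        for j in range(c):
            ai_s[sl, j] = _smooth_vector(pos, track.ai_index[sl, j],
                                         smoothing_param, min_anchors)
            loh_s[sl, j] = _smooth_vector(pos, track.loh_index[sl, j],
                                          smoothing_param, min_anchors)
    return replace(track, ai_smooth=ai_s, loh_smooth=loh_s)


def control_quantile(controls: list[WindowTrack], which: str = "ai",
                     q: float = 0.95, min_for_interp: int = 101) -> np.ndarray:
    """Per-anchor empirical quantile across control tracks.

    With fewer than ``min_for_interp`` controls the quantile degenerates to
    the per-anchor maximum: an interpolated 95% quantile of a moderate
    control set sits below observed controls, and because window indices are
    correlated over ~window_size anchors, the resulting ~5% per-anchor
    exceedance turns into long spurious runs on null samples.
    """
    mats = []
    for t in controls:
        m = t.ai_smooth if which == "ai" else t.loh_smooth
        if m is None:
            m = t.ai_index if which == "ai" else t.loh_index
        mats.append(m)
    stacked = np.concatenate(mats, axis=1)
    with np.errstate(invalid="ignore"):
        if stacked.shape[1] < min_for_interp:
            return np.nanmax(stacked, axis=1)
        return np.nanquantile(stacked, q, axis=1)


def _runs(exceed: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    out = []
    start = None
    for i, v in enumerate(exceed):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(exceed) - 1))
    return out


def call_regions(patient: WindowTrack, controls: list[WindowTrack],
                 min_run: int = 51, whole_chrom_frac: float = 0.9,
                 quantile: float = 0.95) -> AberrationCalls:
    """Call AI and LOH segments where the patient's smoothed track exceeds
    the per-anchor control quantile for at least ``min_run`` consecutive
    anchors.  Segments span the first-to-last exceeding anchor positions; a
    segment covering >= ``whole_chrom_frac`` of a chromosome's SNPs is
    marked whole-chromosome.  AI and LOH are called independently.
    """
    if len(patient.samples) != 1:
        raise ValidationError("patient track must hold exactly one sample")
    if len(controls) < 5:
        raise ValidationError(
            f"need >= 5 control tracks for a stable quantile, got {len(controls)}"
        )
    for t in controls:
        if not np.array_equal(t.annotation.snp_id, patient.annotation.snp_id):
            raise ValidationError("control track on a different SNP panel")
    if patient.ai_smooth is None:
        patient = smooth_track(patient)
    controls = [t if t.ai_smooth is not None else smooth_track(t) for t in controls]

    ann = patient.annotation
    segments: list[Segment] = []
    for label, pat, ctrl_q in (
        ("AI", patient.ai_smooth[:, 0], control_quantile(controls, "ai", quantile)),
        ("LOH", patient.loh_smooth[:, 0], control_quantile(controls, "loh", quantile)),
    ):
        with np.errstate(invalid="ignore"):
            exceed = np.where(np.isfinite(pat) & np.isfinite(ctrl_q),
                              pat > ctrl_q, False)
        for chrom, sl in ann.chrom_slices().items():
            n_chrom = sl.stop - sl.start
            for a, b in _runs(exceed[sl]):
                if b - a + 1 < min_run:
                    continue
                lo, hi = sl.start + a, sl.start + b
                segments.append(Segment(
                    chromosome=chrom,
                    start_pos=int(ann.position[lo]),
                    end_pos=int(ann.position[hi]),
                    label=label,
                    mean_index=float(np.nanmean(pat[lo:hi + 1])),
                    whole_chromosome=(b - a + 1) >= whole_chrom_frac * n_chrom,
                ))
    return AberrationCalls(patient.samples[0], segments).merged()


def scan_samples(patient_freqs: AlleleFreqMatrix, control_freqs: AlleleFreqMatrix,
                 control_calls: GenotypeMatrix, *, window_size: int = 51,
                 z: float = 3.0, sd_floor: float = 0.01, min_run: int = None,
                 whole_chrom_frac: float = 0.9, smoothing_param: float | None = None,
                 quantile: float = 0.95) -> tuple[list[AberrationCalls],
                                                  WindowTrack, list[WindowTrack]]:
    """Full scan pipeline: envelopes from controls, leave-one-out control
    tracks, patient tracks, smoothing, and region calls per patient sample.

    Returns (calls per patient sample, patient WindowTrack, control tracks).
    """
    if min_run is None:
        min_run = window_size
    bands = build_reference_bands(control_freqs, control_calls,
                                  z=z, sd_floor=sd_floor)
    ctrl_flags = flag_points_loo(control_freqs, control_calls,
                                 z=z, sd_floor=sd_floor)
    ctrl_track = smooth_track(window_indices(ctrl_flags, window_size),
                              smoothing_param)
    ctrl_tracks = ctrl_track.split_samples()
    pat_flags = flag_points(patient_freqs, bands)
    pat_track = smooth_track(window_indices(pat_flags, window_size),
                             smoothing_param)
    calls = [
        call_regions(pat_track.sample_track(s), ctrl_tracks, min_run=min_run,
                     whole_chrom_frac=whole_chrom_frac, quantile=quantile)
        for s in patient_freqs.samples
    ]
    return calls, pat_track, ctrl_tracks


@dataclass
class AberrationSummary:
    """Cohort-level summary of aberration calls."""

    n_samples: int
    n_with_ai: int
    n_with_loh: int
    n_whole_chrom_ai: int
    n_whole_chrom_loh: int
    per_sample: list[dict] = field(default_factory=list)

    @property
    def pct_ai(self) -> float:
        return 100.0 * self.n_with_ai / self.n_samples if self.n_samples else 0.0

    @property
    def pct_loh(self) -> float:
        return 100.0 * self.n_with_loh / self.n_samples if self.n_samples else 0.0


def aberration_report(calls: list[AberrationCalls]) -> AberrationSummary:
    """Per-sample AI/LOH presence and whole-chromosome counts, with cohort
    percentages formatted downstream to two decimals."""
    per_sample = []
    n_ai = n_loh = n_wc_ai = n_wc_loh = 0
    for c in sorted(calls, key=lambda c: c.sample):
        ai_segs = [s for s in c.segments if s.label == "AI"]
        loh_segs = [s for s in c.segments if s.label == "LOH"]
        wc_ai = sum(s.whole_chromosome for s in ai_segs)
        wc_loh = sum(s.whole_chromosome for s in loh_segs)
        per_sample.append({
            "sample": c.sample,
            "has_ai": bool(ai_segs), "has_loh": bool(loh_segs),
            "n_ai_segments": len(ai_segs), "n_loh_segments": len(loh_segs),
            "n_whole_chromosome_ai": wc_ai, "n_whole_chromosome_loh": wc_loh,
        })
        n_ai += bool(ai_segs)
        n_loh += bool(loh_segs)
        n_wc_ai += wc_ai
        n_wc_loh += wc_loh
    return AberrationSummary(
        n_samples=len(calls), n_with_ai=n_ai, n_with_loh=n_loh,
        n_whole_chrom_ai=n_wc_ai, n_whole_chrom_loh=n_wc_loh,
        per_sample=per_sample,
    )
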
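import numpy as np
import pytest

from allelekit import aberration as ab
from allelekit.allelefreq import freq_matrix
from allelekit.core_io import (
    GENO_AA,
    GENO_Aa,
    GENO_aa,
    AlleleFreqMatrix,
    GenotypeMatrix,
    ValidationError,
)
from allelekit.cpa import estimate_cpa
from allelekit.synthetic import (
    AberrationSpec,
    SimConfig,
    inject_aberration,
    simulate_cohort,
)

from .conftest import make_annotation


def _freqs(ann, values, mask=None):
    values = np.asarray(values, dtype=float)
    samples = [f"s{j}" for j in range(values.shape[1])]
    return AlleleFreqMatrix(ann, samples, values,
                            np.zeros(values.shape, bool) if mask is None else mask)


def _genos(ann, codes):
    codes = np.asarray(codes, dtype=np.int8)
    return GenotypeMatrix(ann, [f"s{j}" for j in range(codes.shape[1])], codes)


def scan_fixture(seed, n_controls=30, region=None, n_snps=2000, lam=50.0,
                 min_run=None):
    """Simulate controls + one patient (optionally aberrant) and scan."""
    cfg = SimConfig(n_snps=n_snps, n_samples=n_controls + 1, seed=seed)
    cohort = simulate_cohort(cfg)
    patient = f"sample{n_controls:03d}"
    if region is not None:
        cohort = inject_aberration(cohort, region, patient)
    cpa = estimate_cpa(cohort.intensities, cohort.genotypes)
    fm = freq_matrix(cohort.intensities, cpa)
    nc = n_controls
    ctrl_fm = AlleleFreqMatrix(fm.annotation, fm.samples[:nc],
                               fm.freq[:, :nc], fm.mask[:, :nc])
    ctrl_gm = GenotypeMatrix(cohort.annotation, cohort.genotypes.samples[:nc],
                             cohort.genotypes.calls[:, :nc])
    pat_fm = AlleleFreqMatrix(fm.annotation, [patient],
                              fm.freq[:, nc:nc + 1], fm.mask[:, nc:nc + 1])
    calls, pat_track, ctrl_tracks = ab.scan_samples(
        pat_fm, ctrl_fm, ctrl_gm, smoothing_param=lam, min_run=min_run)
    return cohort, calls[0], pat_track, ctrl_tracks


class TestReferenceBands:
    def test_hand_computed_band(self):
        # reference Aa values {0.49, 0.51}: mean 0.5, sd = 0.01414...
        ann = make_annotation(1)
        freqs = _freqs(ann, [[0.49, 0.51]])
        genos = _genos(ann, [[GENO_Aa, GENO_Aa]])
        bands = ab.build_reference_bands(freqs, genos, z=3.0, sd_floor=0.001)
        sd = np.std([0.49, 0.51], ddof=1)
        assert bands.mean[0, 1] == pytest.approx(0.5)
        assert bands.sd[0, 1] == pytest.approx(sd)
        assert bands.upper[0, 1] == pytest.approx(0.5 + 3 * sd)

    def test_sd_floor_applies_to_constant_reference(self):
        ann = make_annotation(1)
        freqs = _freqs(ann, [[0.5, 0.5, 0.5]])
        genos = _genos(ann, [[GENO_Aa] * 3])
        bands = ab.build_reference_bands(freqs, genos, z=3.0, sd_floor=0.01)
        assert bands.sd[0, 1] == 0.01

    def test_single_sample_band_missing(self):
        ann = make_annotation(1)
        freqs = _freqs(ann, [[0.5, 0.98]])
        genos = _genos(ann, [[GENO_Aa, GENO_AA]])
        bands = ab.build_reference_bands(freqs, genos)
        assert np.isnan(bands.mean[0, 1])  # one Aa sample only
        assert np.isnan(bands.mean[0, 2])

    def test_band_ordering_flag(self, small_cohort):
        cpa = estimate_cpa(small_cohort.intensities, small_cohort.genotypes)
        fm = freq_matrix(small_cohort.intensities, cpa)
        bands = ab.build_reference_bands(fm, small_cohort.genotypes)
        mis = bands.misordered()
        complete = np.isfinite(bands.mean).all(axis=1)
        assert not mis[complete].any()


class TestFlagPoints:
    def _bands(self):
        ann = make_annotation(1)
        freqs = _freqs(ann, [[0.02, 0.02, 0.50, 0.50, 0.98, 0.98]])
        genos = _genos(ann, [[GENO_aa, GENO_aa, GENO_Aa, GENO_Aa,
                              GENO_AA, GENO_AA]])
        return ab.build_reference_bands(freqs, genos, z=3.0, sd_floor=0.02)

    def test_between_bands_is_ai_and_loh(self):
        bands = self._bands()  # bands 0.02/0.50/0.98 +- 0.06
        flags = ab.flag_points(_freqs(bands.annotation, [[0.25]]), bands)
        assert flags.ai[0, 0] == 1 and flags.loh[0, 0] == 1

    def test_inside_het_band_clean(self):
        bands = self._bands()
        flags = ab.flag_points(_freqs(bands.annotation, [[0.5]]), bands)
        assert flags.ai[0, 0] == 0 and flags.loh[0, 0] == 0

    def test_homozygous_band_is_loh_not_ai(self):
        bands = self._bands()
        flags = ab.flag_points(_freqs(bands.annotation, [[0.99]]), bands)
        assert flags.ai[0, 0] == 0 and flags.loh[0, 0] == 1

    def test_no_bands_undefined(self):
        ann = make_annotation(1)
        freqs = _freqs(ann, [[0.5]])
        genos = _genos(ann, [[GENO_Aa]])  # single sample -> no bands at all
        bands = ab.build_reference_bands(freqs, genos)
        flags = ab.flag_points(_freqs(ann, [[0.25]]), bands)
        assert np.isnan(flags.ai[0, 0]) and np.isnan(flags.loh[0, 0])

    def test_masked_freq_undefined(self):
        bands = self._bands()
        flags = ab.flag_points(
            _freqs(bands.annotation, [[0.25]], mask=np.array([[True]])), bands)
        assert np.isnan(flags.ai[0, 0])

    def test_loo_matches_plain_on_excluded_sample(self):
        # LOO flags for control j equal plain flags against bands built
        # without control j (oracle equivalence)
        rng = np.random.default_rng(12)
        ann = make_annotation(40)
        n = 12
        calls = rng.choice([GENO_aa, GENO_Aa, GENO_AA], size=(40, n)).astype(np.int8)
        base = np.array([0.02, 0.5, 0.98])[calls]
        freqs = np.clip(base + rng.normal(0, 0.02, (40, n)), 0, 1)
        fm = _freqs(ann, freqs)
        gm = _genos(ann, calls)
        loo = ab.flag_points_loo(fm, gm)
        for j in (0, 5, 11):
            keep = [k for k in range(n) if k != j]
            fm_wo = _freqs(ann, freqs[:, keep])
            gm_wo = _genos(ann, calls[:, keep])
            # bands without j for j's own genotype class; other classes differ
            # only by sample j, so compare at SNPs where full == LOO setup:
            bands_wo = ab.build_reference_bands(fm_wo, gm_wo)
            plain = ab.flag_points(
                _freqs(ann, freqs[:, j:j + 1]), bands_wo)
            own = calls[:, j]
            # exact match guaranteed where the other two classes' bands are
            # unaffected by removing j, i.e. at every SNP (j only contributes
            # to its own class)
            assert np.array_equal(np.nan_to_num(loo.ai[:, j], nan=-1),
                                  np.nan_to_num(plain.ai[:, 0], nan=-1)), own
            assert np.array_equal(np.nan_to_num(loo.loh[:, j], nan=-1),
                                  np.nan_to_num(plain.loh[:, 0], nan=-1))


class TestWindowIndices:
    def test_window_arithmetic(self):
        ann = make_annotation(5)
        flags = ab.PointFlags(ann, ["s0"],
                              np.array([[1.0], [1.0], [0.0], [0.0], [0.0]]),
                              np.zeros((5, 1)))
        track = ab.window_indices(flags, 5)
        assert track.ai_index[2, 0] == pytest.approx(0.4)

    def test_bounds(self):
        ann = make_annotation(7)
        ones = np.ones((7, 1))
        track = ab.window_indices(ab.PointFlags(ann, ["s"], ones, 1 - ones), 3)
        assert np.all(track.ai_index == 1.0)
        assert np.all(track.loh_index == 0.0)

    def test_even_window_rejected(self):
        ann = make_annotation(3)
        flags = ab.PointFlags(ann, ["s"], np.zeros((3, 1)), np.zeros((3, 1)))
        with pytest.raises(ValidationError):
            ab.window_indices(flags, 4)

    def test_missing_flags_excluded_from_both_sides(self):
        ann = make_annotation(3)
        vals = np.array([[1.0], [np.nan], [0.0]])
        track = ab.window_indices(ab.PointFlags(ann, ["s"], vals, vals), 3)
        assert track.ai_index[1, 0] == pytest.approx(0.5)  # (1+0)/2

    def test_brute_force_oracle_equivalence(self):
        # independent recount: explicit loop over windows, 100 random cases
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(3, 60))
            w = int(rng.choice([1, 3, 5, 11, 21]))
            flags = rng.choice([0.0, 1.0, np.nan], size=(n, 2),
                               p=[0.45, 0.45, 0.1])
            ann = make_annotation(n)
            track = ab.window_indices(
                ab.PointFlags(ann, ["a", "b"], flags.copy(), flags.copy()), w)
            h = w // 2
            for m in range(n):
                win = flags[max(0, m - h):min(n, m + h + 1)]
                for j in range(2):
                    col = win[:, j]
                    col = col[np.isfinite(col)]
                    expect = col.mean() if len(col) else np.nan
                    got = track.ai_index[m, j]
                    assert (np.isnan(expect) and np.isnan(got)) or \
                        got == pytest.approx(expect)

    def test_windows_do_not_cross_chromosomes(self):
        ann = make_annotation(4)
        ann2 = ann.subset(np.arange(4))
        # two chromosomes, 2 SNPs each
        import numpy as np2
        from allelekit.core_io import SnpAnnotation
        ann2 = SnpAnnotation(
            np.array(["a", "b", "c", "d"], dtype=object),
            np.array(["1", "1", "2", "2"], dtype=object),
            np.array([10, 20, 10, 20]),
            np.array(["A"] * 4, dtype=object), np.array(["C"] * 4, dtype=object),
        )
        flags = np.array([[1.0], [1.0], [0.0], [0.0]])
        track = ab.window_indices(ab.PointFlags(ann2, ["s"], flags, flags), 3)
        assert track.ai_index[1, 0] == 1.0   # window stays within chr1
        assert track.ai_index[2, 0] == 0.0   # window stays within chr2


class TestSmoothTrack:
    def _track(self, values):
        values = np.asarray(values, dtype=float).reshape(-1, 1)
        ann = make_annotation(len(values))
        return ab.WindowTrack(ann, ["s"], 5, values, values.copy())

    def test_constant_reproduced(self):
        track = ab.smooth_track(self._track([0.3] * 30))
        assert np.allclose(track.ai_smooth, 0.3, atol=1e-8)

    def test_step_smoothed_within_bounds(self):
        y = np.array([0.0] * 25 + [1.0] * 25)
        track = ab.smooth_track(self._track(y), smoothing_param=10.0)
        s = track.ai_smooth[:, 0]
        assert np.all((s >= 0) & (s <= 1))
        assert s[0] < 0.2 and s[-1] > 0.8
        # transition is monotone through the step region
        mid = s[20:30]
        assert np.all(np.diff(mid) > -1e-9)

    def test_short_chromosome_falls_back_to_raw(self):
        y = [0.1, 0.9, 0.2, 0.8, 0.3, 0.7, 0.4, 0.6, 0.5]
        track = ab.smooth_track(self._track(y))
        assert np.allclose(track.ai_smooth[:, 0], y)


class TestCallRegions:
    def test_self_comparison_no_calls(self):
        _, _, pat_track, ctrl_tracks = scan_fixture(21, n_controls=6,
                                                    n_snps=400)
        calls = ab.call_regions(ctrl_tracks[0], ctrl_tracks, min_run=10)
        assert calls.segments == []

    def test_too_few_controls_rejected(self):
        _, _, pat_track, ctrl_tracks = scan_fixture(22, n_controls=6,
                                                    n_snps=400)
        with pytest.raises(ValidationError, match="control"):
            ab.call_regions(pat_track, ctrl_tracks[:4])

    def test_deletion_recovered_with_boundaries(self):
        region = AberrationSpec("1", 800, 1099, a=0, b=1, p=0.25)
        cohort, calls, _, _ = scan_fixture(1, region=region)
        spacing = 10_000
        true_start, true_end = 801 * spacing, 1100 * spacing
        ai = [s for s in calls.segments if s.label == "AI"]
        loh = [s for s in calls.segments if s.label == "LOH"]
        assert len(ai) == 1 and len(loh) >= 1
        for seg in (ai[0], loh[0]):
            assert abs(seg.start_pos - true_start) <= 51 * spacing
            assert abs(seg.end_pos - true_end) <= 51 * spacing

    def test_whole_chromosome_trisomy(self):
        region = AberrationSpec("1", 0, 1999, a=2, b=1, p=0.0)
        _, calls, _, _ = scan_fixture(2, region=region)
        ai = [s for s in calls.segments if s.label == "AI"]
        assert len(ai) == 1 and ai[0].whole_chromosome

    def test_copy_neutral_loh(self):
        # a=2, b=0: LOH called; hom-origin SNPs show no excess AI flags
        region = AberrationSpec("1", 800, 1099, a=2, b=0, p=0.0)
        cohort, calls, pat_track, ctrl_tracks = scan_fixture(3, region=region)
        loh = [s for s in calls.segments if s.label == "LOH"]
        assert len(loh) == 1
        assert abs(loh[0].start_pos - 801 * 10_000) <= 51 * 10_000
        assert abs(loh[0].end_pos - 1100 * 10_000) <= 51 * 10_000
        # AI point flags inside the region concentrate at het-origin SNPs:
        # hom-origin loci keep their germline signal distribution
        patient_j = cohort.genotypes.shape[1] - 1
        cpa = estimate_cpa(cohort.intensities, cohort.genotypes)
        fm = freq_matrix(cohort.intensities, cpa)
        nc = patient_j
        ctrl_fm = AlleleFreqMatrix(fm.annotation, fm.samples[:nc],
                                   fm.freq[:, :nc], fm.mask[:, :nc])
        ctrl_gm = GenotypeMatrix(cohort.annotation,
                                 cohort.genotypes.samples[:nc],
                                 cohort.genotypes.calls[:, :nc])
        bands = ab.build_reference_bands(ctrl_fm, ctrl_gm)
        pat_fm = AlleleFreqMatrix(fm.annotation, [fm.samples[nc]],
                                  fm.freq[:, nc:], fm.mask[:, nc:])
        flags = ab.flag_points(pat_fm, bands)
        in_region = np.zeros(2000, bool)
        in_region[800:1100] = True
        het = cohort.truth.genotypes[:, patient_j] == 1
        hom_in = np.nanmean(flags.ai[in_region & ~het, 0])
        hom_out = np.nanmean(flags.ai[~in_region & ~het, 0])
        het_in = np.nanmean(flags.ai[in_region & het, 0])
        assert hom_in <= hom_out + 0.05
        assert het_in > hom_in

    def test_null_patient_rarely_called(self):
        counts = [len(scan_fixture(300 + i)[1].segments) for i in range(5)]
        assert np.mean(counts) <= 0.5


class TestReport:
    def test_fraction_formatting(self):
        from allelekit.core_io import AberrationCalls, Segment
        calls = [
            AberrationCalls("a", [Segment("1", 1, 2, "AI", 0.5)]),
            AberrationCalls("b", []),
        ]
        summary = ab.aberration_report(calls)
        assert summary.pct_ai == pytest.approx(50.0)
        assert summary.pct_loh == 0.0

    def test_empty(self):
        summary = ab.aberration_report([])
        assert summary.pct_ai == 0.0 and summary.n_samples == 0

    def test_whole_chromosome_counted(self):
        from allelekit.core_io import AberrationCalls, Segment
        calls = [AberrationCalls("a", [
            Segment("1", 1, 2, "AI", 0.5, whole_chromosome=True),
            Segment("2", 1, 2, "LOH", 0.9),
        ])]
        summary = ab.aberration_report(calls)
        assert summary.n_whole_chrom_ai == 1
        assert summary.n_whole_chrom_loh == 0
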
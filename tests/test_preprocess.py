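"""Preprocessing chain: smoothing, baseline, TIC, noise, peaks, de-isotoping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zoomsid.preprocess import (
    ISOTOPE_SPACING_DA,
    NoiseEstimate,
    PeakList,
    PreprocessConfig,
    average_replicates,
    detect_peaks,
    estimate_noise,
    filter_replicate_quality,
    model_isotope_pattern,
    normalize_tic,
    pick_monoisotopic,
    preprocess_sample,
    remove_baseline,
    smooth,
    snip_baseline,
)
from zoomsid.spectra_io import RawSpectrum, ReplicateGroup
from zoomsid.synthetic import SynthConfig, synth_replicates

CFG = PreprocessConfig()


def make_spectrum(intensity, lo=1000.0, step=0.05, sample_id="t"):
    intensity = np.asarray(intensity, dtype=float)
    mz = lo + step * np.arange(intensity.size)
    return RawSpectrum(sample_id, 1, mz=mz, intensity=intensity)


def gaussian(mz, center, height, sigma):
    return height * np.exp(-0.5 * ((mz - center) / sigma) ** 2)


class TestSmooth:
    def test_constant_unchanged(self):
        spec = make_spectrum(np.full(200, 7.5))
        out = smooth(spec, CFG)
        np.testing.assert_allclose(out.intensity, 7.5, rtol=1e-9)

    def test_linear_ramp_preserved(self):
        spec = make_spectrum(np.linspace(1.0, 5.0, 300))
        out = smooth(spec, CFG)
        # edges use the polynomial extension; interior reproduces the ramp
        hw = CFG.sg_half_window
        np.testing.assert_allclose(out.intensity[hw:-hw], spec.intensity[hw:-hw], atol=1e-9)

    def test_matches_direct_local_least_squares(self, rng):
        """Interior output equals an explicit windowed polynomial fit."""
        x = rng.uniform(0, 10, size=120)
        spec = make_spectrum(x)
        out = smooth(spec, CFG)
        hw, order = CFG.sg_half_window, CFG.sg_poly_order
        for i in [hw, 40, 80, 119 - hw]:
            window = np.arange(i - hw, i + hw + 1)
            coeffs = np.polynomial.polynomial.polyfit(window - i, x[window], order)
            assert out.intensity[i] == pytest.approx(max(coeffs[0], 0.0), abs=1e-9)

    def test_noise_reduction_on_sine(self, rng):
        mz_len = 2000
        clean = 5.0 + 2.0 * np.sin(np.linspace(0, 6 * np.pi, mz_len))
        noisy = clean + rng.normal(0, 0.1, size=mz_len)
        out = smooth(make_spectrum(noisy), CFG)
        assert np.std(out.intensity - clean) < 0.1

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            smooth(make_spectrum(np.ones(10)), CFG)


class TestRemoveBaseline:
    def test_all_zero_stays_zero(self):
        out = remove_baseline(make_spectrum(np.zeros(500)), CFG)
        assert np.all(out.intensity == 0)

    def test_flat_offset_removed(self):
        out = remove_baseline(make_spectrum(np.full(2000, 40.0)), CFG)
        assert out.intensity.max() < 0.01 * 40.0

    def test_gaussian_peak_on_linear_baseline(self):
        mz = 1000.0 + 0.05 * np.arange(4000)
        baseline = 10.0 + 0.02 * (mz - 1000.0)
        peak = gaussian(mz, 1100.0, 50.0, 0.08)
        spec = RawSpectrum("t", 1, mz=mz, intensity=baseline + peak)
        out = remove_baseline(spec, CFG)
        apex = out.intensity[np.argmin(np.abs(mz - 1100.0))]
        assert apex == pytest.approx(50.0, rel=0.05)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e3), min_size=5, max_size=200))
    def test_never_negative(self, values):
        out = remove_baseline(make_spectrum(values), CFG)
        assert np.all(out.intensity >= 0)

    def test_decreasing_window_preserves_apex_above_clip_scale(self):
        """Baseline under a narrow peak interpolates the shoulders."""
        mz = 1000.0 + 0.05 * np.arange(1000)
        spec = RawSpectrum("t", 1, mz=mz, intensity=gaussian(mz, 1025.0, 100.0, 0.1))
        base = snip_baseline(spec.intensity, CFG.snip_iterations)
        assert base[np.argmin(np.abs(mz - 1025.0))] < 5.0


class TestNormalizeTic:
    def test_halves(self):
        out = normalize_tic(make_spectrum([2.0, 2.0]))
        np.testing.assert_allclose(out.intensity, [0.5, 0.5])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=100))
    def test_sums_to_one(self, values):
        out = normalize_tic(make_spectrum(values))
        assert out.intensity.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="TIC"):
            normalize_tic(make_spectrum(np.zeros(5)))


class TestEstimateNoise:
    def test_gaussian_noise_level(self, rng):
        sigma = 0.7
        values = 10.0 + rng.normal(0, sigma, size=5000)
        est = estimate_noise(make_spectrum(np.clip(values, 0, None)), cfg=CFG)
        # MAD-based oracle: 1.4826 * median absolute deviation ~= sigma
        assert np.median(est.noise_level) == pytest.approx(sigma, rel=0.2)

    def test_all_zero_gives_small_floor(self):
        est = estimate_noise(make_spectrum(np.zeros(100)), cfg=CFG)
        assert np.all(est.noise_level > 0)
        assert np.all(est.noise_level < 1e-6)

    def test_single_spike_barely_lifts_noise(self):
        values = np.zeros(1000)
        values[500] = 1000.0
        est = estimate_noise(make_spectrum(values), cfg=CFG)
        assert est.noise_level.max() < 0.01 * 1000.0


class TestDetectPeaks:
    def test_single_gaussian_peak(self):
        mz = 1000.0 + 0.05 * np.arange(2000)
        spec = RawSpectrum("t", 1, mz=mz, intensity=gaussian(mz, 1050.0, 100.0, 0.1))
        noise = NoiseEstimate(mz_grid=mz, noise_level=np.ones(mz.size))
        peaks = detect_peaks(spec, noise, CFG)
        assert len(peaks) == 1
        assert abs(peaks.mz[0] - 1050.0) <= 0.05

    def test_flat_spectrum_no_peaks(self):
        spec = make_spectrum(np.full(500, 3.0))
        noise = NoiseEstimate(mz_grid=spec.mz, noise_level=np.ones(500))
        assert len(detect_peaks(spec, noise, CFG)) == 0

    def test_two_close_peaks_both_found(self):
        mz = 1000.0 + 0.05 * np.arange(2000)
        inten = gaussian(mz, 1040.0, 50.0, 0.1) + gaussian(mz, 1043.0, 60.0, 0.1)
        spec = RawSpectrum("t", 1, mz=mz, intensity=inten)
        noise = NoiseEstimate(mz_grid=mz, noise_level=np.ones(mz.size))
        peaks = detect_peaks(spec, noise, CFG)
        assert len(peaks) == 2

    def test_matches_brute_force_scan(self, rng):
        """Detection equals an index-by-index local-maximum + SNR scan."""
        inten = np.clip(rng.normal(2, 1, size=600), 0, None)
        for center in rng.uniform(1002, 1028, size=6):
            inten += gaussian(1000.0 + 0.05 * np.arange(600), center, rng.uniform(20, 60), 0.1)
        spec = make_spectrum(inten)
        noise = estimate_noise(spec, cfg=CFG)
        got = detect_peaks(spec, noise, CFG)
        w = CFG.peak_half_window
        level = noise.noise_level
        expected = []
        for i in range(1, inten.size):
            window = inten[max(0, i - w) : i + w + 1]
            if inten[i] <= 0 or inten[i] < window.max():
                continue
            if inten[i] <= inten[i - 1]:
                continue
            if inten[i] / level[i] >= CFG.snr_threshold:
                expected.append(spec.mz[i])
        np.testing.assert_allclose(got.mz, expected)


class TestPickMonoisotopic:
    @staticmethod
    def _peaklist(masses, intensities):
        masses = np.asarray(masses, float)
        return PeakList("t", mz=masses, intensity=np.asarray(intensities, float), snr=np.full(masses.size, 10.0))

    def test_isolated_peak_passes_through(self):
        peaks = self._peaklist([1500.0], [10.0])
        out = pick_monoisotopic(peaks, CFG)
        assert list(out.mz) == [1500.0]

    def test_modelled_envelope_collapses_to_mono(self):
        mono = 1453.7
        masses = [mono, mono + ISOTOPE_SPACING_DA, mono + 2 * ISOTOPE_SPACING_DA]
        pattern = model_isotope_pattern(mono, 3)
        out = pick_monoisotopic(self._peaklist(masses, 100.0 * pattern), CFG)
        assert list(out.mz) == [mono]
        assert out.is_monoisotopic[0]

    def test_min_cor_threshold_is_decisive(self):
        """An envelope correlating ~0.92 with the model collapses at
        minCor 0.90 but survives at 0.95."""
        mono = 1453.7
        masses = np.array([mono + k * ISOTOPE_SPACING_DA for k in range(4)])
        model = model_isotope_pattern(mono, 4)
        # inflate the envelope tail until the pattern correlation sits
        # between the two thresholds (an ascending tail also spoils every
        # sub-envelope, so nothing collapses partially)
        observed = model + np.array([0.0, 0.0, 0.0, 0.34])
        r = np.corrcoef(observed, model)[0, 1]
        assert 0.90 < r < 0.95
        loose = PreprocessConfig(mono_min_cor=0.90)
        strict = PreprocessConfig(mono_min_cor=0.95)
        assert len(pick_monoisotopic(self._peaklist(masses, observed), loose)) == 1
        assert len(pick_monoisotopic(self._peaklist(masses, observed), strict)) == 4

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=800, max_value=3600), min_size=1, max_size=30, unique=True))
    def test_never_increases_count_and_is_subset(self, masses):
        masses = np.sort(np.asarray(masses))
        masses = masses[np.concatenate([[True], np.diff(masses) > 1e-9])]
        peaks = self._peaklist(masses, np.linspace(1, 2, masses.size))
        out = pick_monoisotopic(peaks, CFG)
        assert len(out) <= len(peaks)
        assert set(out.mz).issubset(set(peaks.mz))


class TestReplicateQuality:
    @staticmethod
    def _with_counts(counts):
        lists = []
        for count in counts:
            mz = 1000.0 + np.arange(count, dtype=float)
            lists.append(PeakList("s", mz=mz, intensity=np.ones(count), snr=np.full(count, 5.0)))
        return lists

    def test_sparse_replicate_dropped(self):
        kept = filter_replicate_quality(self._with_counts([50, 48, 2]), CFG)
        assert [len(p) for p in kept] == [50, 48]

    def test_uniform_group_kept(self):
        kept = filter_replicate_quality(self._with_counts([10, 10, 10]), CFG)
        assert len(kept) == 3

    def test_all_bad_gives_empty_group(self):
        assert filter_replicate_quality(self._with_counts([1, 2, 0]), CFG) == []


class TestAverageReplicates:
    def test_pointwise_mean(self):
        a = make_spectrum([1.0, 3.0])
        b = make_spectrum([3.0, 5.0])
        out = average_replicates([a, b])
        np.testing.assert_allclose(out.intensity, [2.0, 4.0])

    def test_single_replicate_identity(self):
        a = make_spectrum([1.0, 2.0, 3.0])
        out = average_replicates([a])
        np.testing.assert_allclose(out.intensity, a.intensity)

    def test_noise_shrinks_like_sqrt_n(self, rng):
        truth = 10.0 + 3.0 * np.sin(np.linspace(0, 4 * np.pi, 4000))
        sigma = 0.5
        reps = [make_spectrum(truth + rng.normal(0, sigma, 4000)) for _ in range(3)]
        out = average_replicates(reps)
        residual_sd = np.std(out.intensity - truth)
        assert residual_sd == pytest.approx(sigma / np.sqrt(3), rel=0.3)

    def test_interpolates_disjoint_grids(self):
        a = RawSpectrum("s", 1, mz=[1000.0, 1001.0], intensity=[2.0, 2.0])
        b = RawSpectrum("s", 2, mz=[1000.5, 1001.5], intensity=[4.0, 4.0])
        out = average_replicates([a, b])
        assert out.mz.size == 4
        assert out.intensity[np.searchsorted(out.mz, 1000.5)] == pytest.approx(3.0)


class TestPreprocessSample:
    def test_triplicate_recovers_planted_markers(self, africa_db):
        cfg = SynthConfig(species="Loxodonta africana", seed=11)
        group, truth = synth_replicates(cfg, africa_db)
        peaks = preprocess_sample(group)
        assert not peaks.failed
        for planted in truth.planted_masses:
            assert np.min(np.abs(peaks.mz - planted)) < 0.2

    def test_flat_group_fails(self):
        reps = [
            RawSpectrum("f", r, mz=1000.0 + 0.05 * np.arange(2000), intensity=np.zeros(2000))
            for r in (1, 2, 3)
        ]
        peaks = preprocess_sample(ReplicateGroup("f", reps))
        assert peaks.failed and len(peaks) == 0

    def test_high_snr_spectra_recover_planted_set_exactly(self, full_db):
        """With >=5 markers, no contaminants and peaks held to SNR >= 10,
        the planted marker set is recovered exactly (no misses, no
        spurious peaks) in >=95 of 100 seeded runs."""
        from zoomsid.refdb import fixture_reference_db

        species = full_db.species()
        cfg = PreprocessConfig(snr_threshold=10.0)
        good = 0
        for seed in range(100):
            sp = species[seed % len(species)]
            n_markers = min(6, len(full_db.markers_of(sp)))
            synth_cfg = SynthConfig(
                species=sp, seed=seed, n_markers_present=n_markers,
                n_noise_peaks=0, contaminant_names=(),
            )
            region = full_db.markers_of(sp)[0].region
            group, truth = synth_replicates(synth_cfg, fixture_reference_db(region))
            peaks = preprocess_sample(group, cfg)
            planted = np.array(truth.planted_masses)
            found_all = all(np.min(np.abs(peaks.mz - p)) < 0.2 for p in planted)
            no_extra = all(np.min(np.abs(planted - m)) < 0.3 for m in peaks.mz)
            good += found_all and no_extra
        assert good >= 95

    def test_single_clean_replicate_matches_triplicate(self, africa_db):
        base = dict(species="Loxodonta africana", seed=5, noise_sd=0.2, deamidation_prob=0.0, mass_error_sd=0.01)
        tri, truth = synth_replicates(SynthConfig(n_replicates=3, **base), africa_db)
        one, _ = synth_replicates(SynthConfig(n_replicates=1, **base), africa_db)
        peaks_tri = preprocess_sample(tri)
        peaks_one = preprocess_sample(one)
        for planted in truth.planted_masses:
            assert np.min(np.abs(peaks_tri.mz - planted)) < 0.2
            assert np.min(np.abs(peaks_one.mz - planted)) < 0.2
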
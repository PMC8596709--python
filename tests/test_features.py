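import numpy as np
import pandas as pd
import pytest

from wingbeat.features import (
    FEATURE_COLUMNS,
    FEATURE_SCHEMA,
    PAD_LENGTH,
    Spectrum,
    amplitude_energy_stats,
    bioacoustic_indices,
    extract_features,
    fundamental_frequency,
    harmonic_peaks,
    mean_spectrum,
    spectral_entropy,
    temporal_entropy,
    zero_pad,
)
from wingbeat.simulate import SpeciesTemplate, simulate_recording

SR = 10_000.0


def make_spectrum(mean_mag, bin_hz=SR / 128):
    mag = np.asarray(mean_mag, float)
    return Spectrum(freqs=np.arange(mag.size) * bin_hz, mean_mag=mag, sample_rate=SR)


class TestAmplitudeEnergyStats:
    def test_square_wave_closed_form(self):
        s = amplitude_energy_stats(np.array([-1.0, 1.0, -1.0, 1.0]))
        assert s["max_amplitude"] == 1
        assert s["amplitude_range"] == 2
        assert s["power"] == 1
        assert s["rms"] == 1
        assert s["crest_factor"] == 1

    def test_sine_closed_form(self):
        A = 0.4
        x = A * np.sin(2 * np.pi * np.arange(1000) / 100)  # 10 integer cycles
        s = amplitude_energy_stats(x)
        assert s["rms"] == pytest.approx(A / np.sqrt(2), rel=1e-3)
        assert s["crest_factor"] == pytest.approx(np.sqrt(2), rel=1e-3)

    def test_constant_degenerates(self):
        s = amplitude_energy_stats(np.full(100, 0.25))
        assert s["amplitude_range"] == 0
        assert s["crest_factor"] == 1

    def test_all_zero_crest_missing(self):
        assert np.isnan(amplitude_energy_stats(np.zeros(10))["crest_factor"])


class TestEntropies:
    def test_uniform_envelope_is_one(self):
        assert temporal_entropy(np.ones(1000)) == pytest.approx(1.0, abs=1e-12)

    def test_point_mass_is_zero(self):
        env = np.zeros(1000)
        env[0] = 1.0
        assert temporal_entropy(env) == pytest.approx(0.0, abs=1e-12)

    def test_half_support_closed_form(self):
        n = 1024
        env = np.zeros(n)
        env[: n // 2] = 1.0
        assert temporal_entropy(env) == pytest.approx(np.log(n / 2) / np.log(n), abs=1e-12)

    def test_spectral_entropy_extremes(self):
        one_bin = np.zeros(65)
        one_bin[10] = 3.0
        assert spectral_entropy(make_spectrum(one_bin)) == pytest.approx(0.0, abs=1e-12)
        assert spectral_entropy(make_spectrum(np.ones(65))) == pytest.approx(1.0, abs=1e-12)


class TestMeanSpectrum:
    def test_pure_tone_concentrates_at_its_bin(self):
        bin_hz = SR / 128
        f0 = 16 * bin_hz  # exactly on a bin
        x = np.sin(2 * np.pi * f0 * np.arange(4000) / SR)
        spec = mean_spectrum(x, SR)
        near = np.abs(spec.freqs - f0) <= bin_hz
        assert spec.mean_mag[near].sum() >= 0.8 * spec.mean_mag.sum()

    def test_zero_signal_zero_spectrum(self):
        spec = mean_spectrum(np.zeros(500), SR)
        assert not np.any(spec.mean_mag)

    def test_white_noise_roughly_flat(self, rng):
        spec = mean_spectrum(rng.normal(0, 1, 10_000), SR)
        cv = spec.mean_mag.std() / spec.mean_mag.mean()
        assert cv < 0.5

    def test_padding_only_extends_short_signals(self):
        assert zero_pad(np.ones(100)).size == PAD_LENGTH
        assert zero_pad(np.ones(9000)).size == 9000


class TestBioacousticIndices:
    def test_tone_outside_band_contributes_nothing(self):
        x = np.sin(2 * np.pi * 500 * np.arange(4000) / SR)
        idx = bioacoustic_indices(mean_spectrum(x, SR))
        assert idx["bioacoustic_index_3"] < 0.05 * idx["bioacoustic_index_2"]

    def test_superset_band_dominates(self, rng):
        idx = bioacoustic_indices(mean_spectrum(rng.normal(0, 1, 3000), SR))
        assert idx["bioacoustic_index_1"] >= idx["bioacoustic_index_2"]

    def test_flat_unit_spectrum_counts_bins(self):
        idx = bioacoustic_indices(make_spectrum(np.ones(65)))
        freqs = np.arange(65) * SR / 128
        assert idx["bioacoustic_index_1"] == np.sum((freqs >= 0) & (freqs <= 1000))
        assert idx["bioacoustic_index_4"] == np.sum((freqs >= 200) & (freqs <= 3000))


class TestHarmonicPeaks:
    def test_three_peaks_ranked_rest_missing(self):
        mag = np.zeros(65)
        mag[10], mag[20], mag[30] = 1.0, 0.5, 0.25
        hs = harmonic_peaks(make_spectrum(mag))
        bin_hz = SR / 128
        assert hs.harmonics[0] == pytest.approx(10 * bin_hz)
        assert hs.harmonics[1] == pytest.approx(20 * bin_hz)
        assert hs.harmonics[2] == pytest.approx(30 * bin_hz)
        assert all(np.isnan(h) for h in hs.harmonics[3:])
        assert hs.dominant == pytest.approx(10 * bin_hz)

    def test_tone_signal_h1_equals_dominant(self):
        x = np.sin(2 * np.pi * 120 * np.arange(5000) / SR)
        hs = harmonic_peaks(mean_spectrum(x, SR))
        assert hs.harmonics[0] == hs.dominant
        assert abs(hs.dominant - 120) <= SR / 128  # within one bin width

    def test_sub50hz_peak_tops_list_but_not_dominant(self):
        mag = np.zeros(65)
        bin_hz = SR / 128  # 78.125 Hz; put a taller "peak" below 50 Hz
        freqs = np.arange(65) * 10.0  # 10 Hz bins for this constructed case
        mag[3], mag[11] = 1.0, 0.6  # 30 Hz and 110 Hz
        hs = harmonic_peaks(Spectrum(freqs=freqs, mean_mag=mag, sample_rate=SR))
        assert hs.harmonics[0] == 30.0
        assert hs.dominant == 110.0

    def test_tie_breaks_toward_lower_frequency(self):
        mag = np.zeros(65)
        mag[10] = mag[40] = 1.0
        hs = harmonic_peaks(make_spectrum(mag))
        assert hs.harmonics[0] < hs.harmonics[1]

    def test_flat_spectrum_has_no_peaks(self):
        hs = harmonic_peaks(make_spectrum(np.ones(65)))
        assert all(np.isnan(h) for h in hs.harmonics)
        assert np.isnan(hs.dominant)


class TestFundamentalFrequency:
    def test_pure_100hz_tone_exact_lag(self):
        x = np.sin(2 * np.pi * 100 * np.arange(6000) / SR)
        est = fundamental_frequency(x, SR)
        assert est.acf_peak_lag == 100
        assert est.f0 == pytest.approx(100.0)

    def test_120hz_integer_lag_quantization(self):
        x = np.sin(2 * np.pi * 120 * np.arange(6000) / SR)
        est = fundamental_frequency(x, SR)
        assert est.acf_peak_lag in (83, 84)
        assert est.f0 in (pytest.approx(SR / 83), pytest.approx(SR / 84))

    def test_harmonic_rich_tone_keeps_full_period(self):
        t = np.arange(6000) / SR
        x = sum(0.5**k * np.sin(2 * np.pi * (k + 1) * 110 * t) for k in range(4))
        est = fundamental_frequency(np.asarray(x), SR)
        assert abs(est.f0 - 110) < 2

    def test_white_noise_rejected(self):
        rng = np.random.default_rng(11)
        assert fundamental_frequency(rng.normal(0, 1, 10_000), SR) is None

    def test_all_zero_rejected(self):
        assert fundamental_frequency(np.zeros(2000), SR) is None


class TestExtractFeatures:
    def test_schema_has_exactly_52_slots(self):
        assert len(FEATURE_COLUMNS) == 52
        raw = [f for f in FEATURE_SCHEMA if not f.detrended]
        det = [f for f in FEATURE_SCHEMA if f.detrended]
        assert len(raw) == 25 and len(det) == 27
        by_stage = {s: sum(f.stage == s for f in FEATURE_SCHEMA) for s in range(1, 8)}
        assert by_stage == {1: 6, 2: 2, 3: 17, 4: 7, 5: 2, 6: 17, 7: 1}

    def test_every_slot_present_on_synthetic_recording(self):
        tpl = SpeciesTemplate("t", f0_mean=110, trend_amplitude=0.3)
        rec, _ = simulate_recording(tpl, seed=3)
        fv = extract_features(rec)
        assert list(fv.index[-52:]) == FEATURE_COLUMNS

    def test_fundamental_recovered_within_2hz_under_trend(self):
        tpl = SpeciesTemplate("t", f0_mean=110, f0_sd=0.01, trend_amplitude=0.3,
                              temperature_coefficient=0.0)
        rec, truth = simulate_recording(tpl, seed=9)
        fv = extract_features(rec)
        assert abs(np.exp(fv["fundamental_frequency_g"]) - truth["f0"]) < 2

    def test_extraction_is_deterministic(self):
        tpl = SpeciesTemplate("t")
        rec, _ = simulate_recording(tpl, seed=21)
        a = extract_features(rec)[FEATURE_COLUMNS].astype(float)
        b = extract_features(rec)[FEATURE_COLUMNS].astype(float)
        pd.testing.assert_series_equal(a, b)

    def test_invariant_ranges(self, separable_corpus):
        features, _, _ = separable_corpus
        for col in ("temporal_entropy", "spectral_entropy", "acoustic_entropy",
                    "temporal_entropy_g", "spectral_entropy_g", "acoustic_entropy_g"):
            vals = features[col].dropna()
            assert ((vals >= 0) & (vals <= 1 + 1e-12)).all()
        for i in range(1, 5):
            assert (features[f"bioacoustic_index_{i}"].dropna() >= 0).all()
        # crest factor stored as log(max/rms); pre-log value >= 1 means log >= 0
        assert (features["crest_factor"].dropna() >= -1e-12).all()
        # acoustic entropy is the product of the other two
        ok = features[["temporal_entropy", "spectral_entropy", "acoustic_entropy"]].dropna()
        np.testing.assert_allclose(
            ok["acoustic_entropy"], ok["temporal_entropy"] * ok["spectral_entropy"], atol=1e-9
        )

    def test_detrended_stats_differ_when_trend_injected(self):
        tpl = SpeciesTemplate("t", trend_amplitude=0.3, f0_mean=110)
        rec, truth = simulate_recording(tpl, seed=4)
        assert truth["trend_range"] > 0
        fv = extract_features(rec)
        assert fv["amplitude_range"] != fv["amplitude_range_g"]
        assert fv["power"] != fv["power_g"]
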
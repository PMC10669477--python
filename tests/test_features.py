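"""Feature extraction: window geometry, band power against a brute-force
DFT oracle, and the algebra of the two normalizations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbbeeg.features import (BANDS, FEATURE_COLUMNS, WindowSpec, band_power,
                             band_powers, extract_features, normalize1,
                             normalize2, segment_windows, sum_channels)
from bbbeeg.recording import ConfigurationError, EEGRecording

BAND_BY_NAME = {b.name: b for b in BANDS}


def dft_band_power(x: np.ndarray, fs: float, low: float, high: float) -> float:
    """Independent oracle: direct DFT summation, no FFT routine."""
    n = len(x)
    t = np.arange(n)
    powers = []
    for k in range(n // 2 + 1):
        f = k * fs / n
        if low <= f < high:
            re = float(np.sum(x * np.cos(2 * np.pi * k * t / n)))
            im = float(-np.sum(x * np.sin(2 * np.pi * k * t / n)))
            powers.append(re * re + im * im)
    return float(np.mean(powers))


# ---------------------------------------------------------------------------
# window geometry


class TestSegmentation:
    def test_300s_recording_gives_25_windows(self):
        rec = EEGRecording(np.zeros((2, 300 * 250)), 250.0)
        wins = segment_windows(rec, WindowSpec(60.0, 10.0))
        assert len(wins) == 25
        assert wins[0].start_s == 0.0 and wins[-1].start_s == 240.0

    def test_exactly_one_window_at_minimum_duration(self):
        rec = EEGRecording(np.zeros((2, 60 * 250)), 250.0)
        assert len(segment_windows(rec)) == 1

    def test_training_span_of_1800s_gives_175_windows(self):
        rec = EEGRecording(np.zeros((2, 1800 * 250)), 250.0)
        assert len(segment_windows(rec)) == 175

    def test_short_recording_rejected(self):
        rec = EEGRecording(np.zeros((2, 10 * 250)), 250.0)
        with pytest.raises(ConfigurationError, match="shorter"):
            segment_windows(rec)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(duration=st.integers(2, 30), shift=st.integers(1, 12),
           extra=st.integers(0, 200))
    def test_window_count_closed_form(self, duration, shift, extra):
        """floor((T - delta)/tau) + 1 equals brute-force enumeration."""
        shift = min(shift, duration)
        total = duration + extra
        brute = sum(1 for i in range(total)
                    if i * shift + duration <= total)
        spec = WindowSpec(float(duration), float(shift))
        assert spec.count(float(total)) == brute
        rec = EEGRecording(np.zeros((2, total * 100)), 100.0)
        assert len(segment_windows(rec, spec)) == brute

    def test_windows_never_extend_past_signal_end(self, short_recording):
        wins = segment_windows(short_recording)
        assert all(w.stop_idx <= short_recording.n_samples for w in wins)


# ---------------------------------------------------------------------------
# band power


class TestBandPower:
    def test_zero_window_gives_zero_for_every_band(self):
        x = np.zeros(250 * 60)
        assert all(band_power(x, 250.0, b) == 0.0 for b in BANDS)

    def test_agrees_with_brute_force_dft_oracle(self, rng):
        """Toy 1-s windows: FFT path matches direct DFT within 1e-9."""
        x = rng.standard_normal(250)
        for b in BANDS:
            ours = band_power(x, 250.0, b)
            oracle = dft_band_power(x, 250.0, b.low_hz, b.high_hz)
            assert ours == pytest.approx(oracle, rel=1e-9)

    def test_parseval_identity_on_toy_window(self, rng):
        x = rng.standard_normal(250)
        amps2 = np.abs(np.fft.rfft(x)) ** 2
        weights = np.full(amps2.size, 2.0)
        weights[0] = weights[-1] = 1.0  # DC and Nyquist counted once
        assert np.sum(weights * amps2) == pytest.approx(
            x.size * np.sum(x**2), rel=1e-12)

    def test_pure_alpha_sinusoid_dominates_other_bands(self):
        t = np.arange(250 * 60) / 250.0
        x = np.sin(2 * np.pi * 10.0 * t)  # 10 Hz lies in alpha [8, 12)
        p = {b.name: band_power(x, 250.0, b) for b in BANDS}
        assert all(p["alpha"] > 1e3 * p[name] for name in p if name != "alpha")

    def test_quadratic_amplitude_scaling(self, rng):
        x = rng.standard_normal(250 * 60)
        for b in BANDS:
            assert band_power(2 * x, 250.0, b) == pytest.approx(
                4 * band_power(x, 250.0, b), rel=1e-12)

    def test_band_above_nyquist_rejected(self):
        from bbbeeg.features import BandDefinition
        with pytest.raises(ConfigurationError, match="Nyquist"):
            band_power(np.zeros(100), 100.0, BandDefinition("hf", 40.0, 60.0))

    def test_harmonics_partition_1_to_50_hz(self):
        """Half-open bands: every 60-s-window harmonic in [1, 50) Hz is
        counted exactly once."""
        n, fs = 60 * 250, 250.0
        freqs = np.fft.rfftfreq(n, 1 / fs)
        in_range = np.nonzero((freqs >= 1.0) & (freqs < 50.0))[0]
        claimed = np.concatenate([b.harmonic_indices(n, fs) for b in BANDS])
        assert sorted(claimed) == sorted(in_range)


# ---------------------------------------------------------------------------
# channel summation and normalizations


class TestNormalization:
    def test_sum_channels_is_elementwise_addition(self, rng):
        p = rng.uniform(1, 10, size=(2, 5))
        assert np.allclose(sum_channels(p), p[0] + p[1])
        assert np.allclose(sum_channels(np.vstack([p[0], np.zeros(5)])), p[0])

    def test_sum_channels_rejects_wrong_channel_count(self):
        with pytest.raises(ConfigurationError, match="channel"):
            sum_channels(np.ones((3, 5)))
        assert np.allclose(sum_channels(np.ones((3, 5)), expected_channels=None),
                           3 * np.ones(5))

    def test_normalize1_equal_powers_give_fifths(self):
        vec, valid = normalize1(np.full(5, 7.5))
        assert valid and np.allclose(vec, 0.2)

    def test_normalize1_known_exponentials(self):
        vec, valid = normalize1(np.exp([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert valid
        assert np.allclose(vec, np.array([1, 2, 3, 4, 5]) / 15.0, atol=1e-12)

    def test_normalize1_components_sum_to_one(self, rng):
        for _ in range(20):
            vec, valid = normalize1(rng.uniform(0.5, 1e4, size=5))
            if valid:
                assert abs(vec.sum() - 1.0) < 1e-12

    def test_normalize2_known_exponentials(self):
        vec, valid = normalize2(np.exp([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert valid and np.allclose(vec, [0, 0.25, 0.5, 0.75, 1.0], atol=1e-12)

    def test_normalize2_scale_invariant_normalize1_not(self, rng):
        """The two schemes genuinely differ under global power rescaling."""
        x = rng.uniform(1.5, 1e3, size=5)
        v2, _ = normalize2(x)
        v2c, _ = normalize2(10.0 * x)
        assert np.allclose(v2, v2c, atol=1e-12)
        v1, _ = normalize1(x)
        v1c, _ = normalize1(10.0 * x)
        assert not np.allclose(v1, v1c, atol=1e-6)

    def test_normalize2_range_contract(self, rng):
        vec, valid = normalize2(rng.uniform(0.5, 1e4, size=5))
        assert valid
        assert vec.min() == 0.0 and vec.max() == 1.0
        assert np.all((vec >= 0) & (vec <= 1))

    def test_degenerate_windows_flagged_not_dropped(self):
        vec, valid = normalize2(np.full(5, 3.0))  # zero dynamic range
        assert not valid and np.all(np.isnan(vec))
        vec, valid = normalize1(np.zeros(5))  # silent window
        assert not valid


# ---------------------------------------------------------------------------
# end-to-end extraction


class TestExtractFeatures:
    def test_300s_recording_yields_25_feature_vectors(self, short_recording):
        table = extract_features(short_recording, normalization=1)
        assert len(table) == 25
        assert list(table["label"].unique()) == ["baseline"]

    def test_norm1_rows_sum_to_one(self, short_recording):
        table = extract_features(short_recording, normalization=1)
        sums = table.loc[table["valid"], list(FEATURE_COLUMNS)].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_stationary_recording_gives_stable_features(self, short_recording):
        table = extract_features(short_recording, normalization=1)
        feats = table.loc[table["valid"], list(FEATURE_COLUMNS)]
        assert (feats.std() / feats.mean()).max() < 0.10

    def test_invalid_normalization_rejected(self, short_recording):
        with pytest.raises(ConfigurationError, match="normalization"):
            extract_features(short_recording, normalization=3)
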
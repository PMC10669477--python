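"""Synthetic-EEG generator: determinism, parameter recovery, annotations."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from bbbeeg.features import BAND_NAMES, band_powers, segment_windows
from bbbeeg.recording import ConfigurationError
from bbbeeg.synth import (StateProfile, default_profiles, generate_recording,
                          generate_training_corpus, interpolate_profiles)


def measured_band_powers(rec) -> np.ndarray:
    """Mean channel-wise band power over all shifting windows."""
    wins = segment_windows(rec)
    P = np.array([band_powers(rec.signal[:, w.start_idx:w.stop_idx], rec.fs)
                  for w in wins])
    return P.mean(axis=(0, 1))


class TestGenerateRecording:
    def test_same_seed_bit_identical(self, profiles):
        a = generate_recording([(profiles["baseline"], 120.0)], seed=7)
        b = generate_recording([(profiles["baseline"], 120.0)], seed=7)
        assert np.array_equal(a.signal, b.signal)
        assert a.epochs == b.epochs

    def test_all_zero_profile_gives_silent_signal(self):
        silent = StateProfile({n: 0.0 for n in BAND_NAMES}, noise_floor=0.0)
        rec = generate_recording([(silent, 60.0)], seed=0)
        assert np.all(rec.signal == 0.0)

    def test_delta_target_ratio_recovered(self, profiles):
        """Tripling the delta target triples the extracted delta power."""
        base = profiles["baseline"]
        boosted = replace(base, band_power_targets={
            **base.band_power_targets,
            "delta": 3 * base.band_power_targets["delta"]}, label="iso1")
        rec = generate_recording([(base, 1800.0), (boosted, 1800.0)], seed=11)
        half = rec.n_samples // 2
        first = EEG_slice(rec, 0, half)
        second = EEG_slice(rec, half, rec.n_samples)
        r = measured_band_powers(second)[-1] / measured_band_powers(first)[-1]
        assert r == pytest.approx(3.0, rel=0.15)

    def test_band_powers_match_targets_and_converge(self, profiles):
        """Recovery within a few percent; error shrinks as duration grows."""
        targets = profiles["baseline"].targets_array()

        def mean_err(duration: float) -> float:
            errs = [np.abs(measured_band_powers(
                generate_recording([(profiles["baseline"], duration)], seed=s))
                - targets) / targets for s in (0, 1, 2)]
            return float(np.mean(errs))

        err_short, err_long = mean_err(120.0), mean_err(1920.0)
        assert err_long < 0.05
        assert err_long < err_short

    def test_annotation_conservation(self, profiles):
        rec = generate_recording([(profiles["baseline"], 90.0),
                                  (profiles["iso1"], 120.0)], seed=3)
        assert sum(ep.duration_s for ep in rec.epochs) == pytest.approx(
            rec.duration_s)
        assert [ep.label for ep in rec.epochs] == ["baseline", "iso1"]

    def test_one_over_f_background_tilts_low_frequencies(self):
        flat = StateProfile({n: 0.0 for n in BAND_NAMES}, background_power=25.0,
                            background_exponent=2.0)
        rec = generate_recording([(flat, 300.0)], seed=5)
        p = measured_band_powers(rec)  # order gamma .. delta
        assert p[-1] > 10 * p[0]  # steep 1/f^2: delta far above gamma

    def test_rejects_bad_configuration(self, profiles):
        with pytest.raises(ConfigurationError, match="duration"):
            generate_recording([(profiles["baseline"], 30.0)], seed=0)
        with pytest.raises(ConfigurationError, match="fs"):
            generate_recording([(profiles["baseline"], 120.0)], fs=80.0, seed=0)
        with pytest.raises(ConfigurationError, match="decay"):
            StateProfile({"delta": 1.0}, decay_to_zero=True)


class TestTrainingCorpus:
    def test_balanced_corpus_shape(self, profiles):
        corpus = generate_training_corpus(2, seed=0, duration_s=60.0)
        assert len(corpus) == 4
        labels = [r.epochs[0].label for r in corpus]
        assert labels.count("normal_behavior") == 2
        assert labels.count("artificial_obbb") == 2

    def test_standard_corpus_yields_1430_windows(self, std_corpus, run_config):
        per_rec = [run_config.window_spec.count(r.duration_s) for r in std_corpus]
        assert sum(per_rec) == 1430
        assert all(n == 143 for n in per_rec)

    def test_missing_class_profile_rejected(self, profiles):
        with pytest.raises(ConfigurationError, match="class_profiles"):
            generate_training_corpus(
                1, {"normal_behavior": profiles["normal_behavior"]}, seed=0)

    def test_corpus_seed_reproducible(self):
        a = generate_training_corpus(1, seed=5, duration_s=60.0)
        b = generate_training_corpus(1, seed=5, duration_s=60.0)
        assert all(np.array_equal(x.signal, y.signal) for x, y in zip(a, b))


class TestInterpolation:
    def test_endpoints_and_midpoint(self, profiles):
        p0, p1 = profiles["normal_behavior"], profiles["artificial_obbb"]
        assert np.allclose(interpolate_profiles(p0, p1, 0.0).targets_array(),
                           p0.targets_array())
        assert np.allclose(interpolate_profiles(p0, p1, 1.0).targets_array(),
                           p1.targets_array())
        mid = interpolate_profiles(p0, p1, 0.5).targets_array()
        assert np.allclose(mid, np.sqrt(p0.targets_array() * p1.targets_array()))


def EEG_slice(rec, start, stop):
    """Sub-recording over a sample range (annotations dropped)."""
    from bbbeeg.recording import EEGRecording
    return EEGRecording(rec.signal[:, start:stop], rec.fs, (), id=rec.id)
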
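"""Synthetic condition-annotated two-channel EEG with controllable band power.

Each condition is described by a :class:`StateProfile` giving the target
within-band power for the five analysed bands.  Synthesis is direct: per
band, Gaussian white noise is band-pass filtered to the band's edges and
rescaled so the power the feature extractor measures matches the target;
the five band components are summed with an optional 1/f^a background and
an additive white measurement floor.  A profile may additionally decay
exponentially toward that floor, emulating the spectral collapse seen
under a lethal anesthetic dose.

Band-power targets are expressed in the same convention the feature
extractor measures: mean squared one-sided FFT harmonic amplitude in a
60-s window at the recording's sampling rate.  Targets are calibrated
against that measurement empirically, so parameter recovery is exact in
expectation.

Two channels are independent draws from the same profile mixed with an
optional shared component (default mixing 0.5), preserving per-channel
band power.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize as spo
from scipy import signal as sps

from .features import BANDS, BAND_NAMES
from .recording import ConditionEpoch, ConfigurationError, EEGRecording

__all__ = [
    "StateProfile",
    "default_profiles",
    "interpolate_profiles",
    "generate_recording",
    "generate_training_corpus",
    "generate_anesthesia_recording",
]

#: Window length (s) defining the band-power measurement convention.
CALIBRATION_WINDOW_S = 60.0


@dataclass(frozen=True)
class StateProfile:
    """Target spectral make-up of one physiological condition.

    Parameters
    ----------
    band_power_targets
        Mapping band name -> target band power (mean squared 60-s-window
        FFT amplitude, arbitrary power units).
    background_exponent, background_power
        Slope ``a`` and total variance of an optional 1/f^a broadband
        background added on top of the band components.
    noise_floor
        Variance of additive white measurement noise (always present,
        never decayed).
    decay_to_zero, decay_tau_s
        When set, the EEG components (not the floor) are multiplied by
        ``exp(-t / tau)`` within the epoch, collapsing band power toward
        the white floor with power time constant ``tau / 2``.
    label
        Condition label stamped on the generated epoch.
    """

    band_power_targets: Mapping[str, float] = field(default_factory=dict)
    background_exponent: float = 1.0
    background_power: float = 0.0
    noise_floor: float = 0.0
    decay_to_zero: bool = False
    decay_tau_s: float | None = None
    label: str = "baseline"

    def __post_init__(self) -> None:
        for name, p in self.band_power_targets.items():
            if name not in BAND_NAMES:
                raise ConfigurationError(f"unknown band {name!r} in profile")
            if p < 0:
                raise ConfigurationError(f"negative band power target for {name}")
        if self.background_power < 0 or self.noise_floor < 0:
            raise ConfigurationError("background/noise powers must be >= 0")
        if self.decay_to_zero and not (self.decay_tau_s and self.decay_tau_s > 0):
            raise ConfigurationError("decay_to_zero requires a positive decay_tau_s")

    def targets_array(self) -> np.ndarray:
        return np.array([self.band_power_targets.get(n, 0.0) for n in BAND_NAMES])


def default_profiles() -> dict[str, StateProfile]:
    """The standard study conditions.

    ``normal_behavior`` carries the resting 1/f-ordered band-power ladder.
    ``artificial_obbb`` is a broadband power elevation with extra delta /
    theta weighting — the slow-wave power rise that accompanies barrier
    opening and drainage activation.  ``iso1`` (surgical-dose anesthesia)
    has the same character but weaker; ``iso4`` (lethal dose) starts from
    the iso1 state and collapses exponentially toward the white
    measurement floor; ``death`` is the floor alone.
    """
    floor = 1.0e-4  # white-noise variance; ~1.5 power units per band at 250 Hz
    base = {"delta": 200.0, "theta": 150.0, "alpha": 110.0, "beta": 80.0, "gamma": 60.0}
    obbb = {"delta": 2000.0, "theta": 1350.0, "alpha": 880.0, "beta": 640.0, "gamma": 480.0}
    normal = StateProfile(base, noise_floor=floor, label="normal_behavior")
    opened = StateProfile(obbb, noise_floor=floor, label="artificial_obbb")
    # 1 % isoflurane shares the training class's activation signature at
    # three-quarters strength on the normal -> OBBB log-ray; the lethal
    # dose starts at full strength and collapses toward the floor.
    iso1 = replace(interpolate_profiles(normal, opened, 0.75), label="iso1")
    return {
        "normal_behavior": normal,
        "artificial_obbb": opened,
        "baseline": replace(normal, label="baseline"),
        "iso1": iso1,
        "iso4": StateProfile(obbb, noise_floor=floor, decay_to_zero=True,
                             decay_tau_s=300.0, label="iso4"),
        "death": StateProfile({n: 0.0 for n in BAND_NAMES}, noise_floor=floor,
                              label="death"),
    }


def interpolate_profiles(p0: StateProfile, p1: StateProfile, effect: float) -> StateProfile:
    """Log-linear interpolation of band targets between two profiles.

    ``effect=0`` reproduces ``p0``, ``effect=1`` reproduces ``p1``; used
    for effect-size sweeps.  Non-band fields are taken from ``p1``.
    """
    t0, t1 = p0.targets_array(), p1.targets_array()
    eps = 1e-30
    targets = np.exp((1 - effect) * np.log(t0 + eps) + effect * np.log(t1 + eps))
    return replace(
        p1, band_power_targets={n: float(v) for n, v in zip(BAND_NAMES, targets)}
    )


def _band_component(rng: np.random.Generator, n: int, fs: float, low: float,
                    high: float) -> np.ndarray:
    """Unit-scale band-limited Gaussian noise (4th-order Butterworth)."""
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, rng.standard_normal(n))


@lru_cache(maxsize=8)
def _band_coupling_matrix(fs: float) -> np.ndarray:
    """Expected measured band power per unit-variance band component.

    Zero-phase (forward-backward) filtering gives component ``k`` the
    power spectral density ``|H_k(f)|^4 / fs``; the expectation of a
    squared length-N DFT amplitude of a stationary process is
    ``N * fs * S(f)``, so component ``k`` contributes
    ``A[j, k] = N * mean(|H_k(f)|^4 over band j's harmonics)`` to the
    measured power of band ``j``.  The off-diagonal terms capture the
    Butterworth roll-off leaking past the shared band edges; solving
    ``A x = targets`` for the component variances removes that bias, so
    band-power estimates converge to their targets as duration grows.
    """
    n_win = int(round(CALIBRATION_WINDOW_S * fs))
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    A = np.empty((len(BANDS), len(BANDS)))
    for k, comp_band in enumerate(BANDS):
        sos = sps.butter(4, [comp_band.low_hz, comp_band.high_hz],
                         btype="bandpass", fs=fs, output="sos")
        for j, meas_band in enumerate(BANDS):
            f = freqs[(freqs >= meas_band.low_hz - 1e-12)
                      & (freqs < meas_band.high_hz - 1e-12)]
            _, h = sps.sosfreqz(sos, worN=f, fs=fs)
            A[j, k] = n_win * np.mean(np.abs(h) ** 4)
    return A


def _one_over_f(rng: np.random.Generator, n: int, fs: float, exponent: float,
                variance: float) -> np.ndarray:
    """1/f^a background via spectral shaping, scaled to total variance."""
    if variance <= 0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (np.sqrt(variance) / sd) if sd > 0 else x


def _component_variances(fs: float, targets: np.ndarray,
                         floor_var: float) -> np.ndarray:
    """Per-band component variances whose expected measured band powers
    (including the white floor's flat contribution) equal the targets."""
    n_win = int(round(CALIBRATION_WINDOW_S * fs))
    residual = np.maximum(targets - n_win * floor_var, 0.0)
    if not residual.any():
        return np.zeros_like(residual)
    x, _ = spo.nnls(_band_coupling_matrix(fs), residual)
    return x


def _calibrated_eeg(rng: np.random.Generator, n: int, fs: float,
                    variances: np.ndarray, bg_exp: float, bg_var: float) -> np.ndarray:
    """Sum of per-band components at given variances plus 1/f^a background."""
    x = np.zeros(n)
    for j, band in enumerate(BANDS):
        if variances[j] <= 0:
            continue
        comp = _band_component(rng, n, fs, band.low_hz, band.high_hz)
        x += comp * np.sqrt(variances[j])
    x += _one_over_f(rng, n, fs, bg_exp, bg_var)
    return x


def generate_recording(
    profile_sequence: Sequence[tuple[StateProfile, float]],
    fs: float = 250.0,
    channel_count: int = 2,
    seed: int = 0,
    shared_mixing: float = 0.5,
    recording_id: str = "synthetic",
) -> EEGRecording:
    """Generate an annotated recording from a sequence of condition profiles.

    Each ``(profile, duration_s)`` element becomes one condition epoch;
    durations must be at least one 60-s analysis window.  Identical
    arguments and seed reproduce the signal bit for bit.
    """
    if fs < 100.0:
        raise ConfigurationError(f"fs={fs} Hz below the 100 Hz bound for the gamma band")
    if not 0 <= shared_mixing <= 1:
        raise ConfigurationError("shared_mixing must lie in [0, 1]")
    if not profile_sequence:
        raise ConfigurationError("profile_sequence is empty")
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    epochs: list[ConditionEpoch] = []
    t0 = 0.0
    for profile, duration_s in profile_sequence:
        if duration_s < CALIBRATION_WINDOW_S:
            raise ConfigurationError(
                f"epoch duration {duration_s} s is below one {CALIBRATION_WINDOW_S} s window"
            )
        n = int(round(duration_s * fs))
        variances = _component_variances(fs, profile.targets_array(),
                                         profile.noise_floor)
        shared = _calibrated_eeg(rng, n, fs, variances, profile.background_exponent,
                                 profile.background_power)
        seg = np.empty((channel_count, n))
        for c in range(channel_count):
            own = _calibrated_eeg(rng, n, fs, variances, profile.background_exponent,
                                  profile.background_power)
            seg[c] = (np.sqrt(1.0 - shared_mixing) * own
                      + np.sqrt(shared_mixing) * shared)
        if profile.decay_to_zero:
            t = np.arange(n) / fs
            seg *= np.exp(-t / profile.decay_tau_s)[None, :]
        if profile.noise_floor > 0:
            seg += rng.normal(0.0, np.sqrt(profile.noise_floor), size=seg.shape)
        chunks.append(seg)
        epochs.append(ConditionEpoch(t0, t0 + n / fs, profile.label))
        t0 += n / fs
    return EEGRecording(np.concatenate(chunks, axis=1), fs, tuple(epochs), recording_id)


def generate_training_corpus(
    n_per_class: int,
    class_profiles: Mapping[str, StateProfile] | None = None,
    fs: float = 250.0,
    seed: int = 0,
    duration_s: float = 1480.0,
    channel_count: int = 2,
) -> list[EEGRecording]:
    """Balanced two-class corpus of single-epoch recordings.

    The default 1480-s duration yields 143 feature windows per recording,
    so five recordings per class give the standard 715 windows per class
    (1430 in total).  Exactly the labels ``normal_behavior`` and
    ``artificial_obbb`` are required.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    if class_profiles is None:
        prof = default_profiles()
        class_profiles = {k: prof[k] for k in ("normal_behavior", "artificial_obbb")}
    required = {"normal_behavior", "artificial_obbb"}
    if set(class_profiles) != required:
        raise ConfigurationError(
            f"class_profiles must map exactly {sorted(required)}, "
            f"got {sorted(class_profiles)}"
        )
    rng = np.random.default_rng(seed)
    corpus = []
    for label in sorted(required):
        profile = replace(copy.deepcopy(class_profiles[label]), label=label)
        for i in range(n_per_class):
            corpus.append(
                generate_recording(
                    [(profile, duration_s)], fs=fs, channel_count=channel_count,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    recording_id=f"{label}_{i:02d}",
                )
            )
    return corpus


def generate_anesthesia_recording(
    seed: int,
    fs: float = 250.0,
    epoch_durations: Mapping[str, float] | None = None,
    profiles: Mapping[str, StateProfile] | None = None,
    recording_id: str = "rat",
) -> EEGRecording:
    """One test animal: baseline, then 1 % isoflurane, then the lethal 4 % dose."""
    profiles = dict(default_profiles() if profiles is None else profiles)
    epoch_durations = dict(
        {"baseline": 1800.0, "iso1": 1800.0, "iso4": 1800.0}
        if epoch_durations is None else epoch_durations
    )
    sequence = [
        (replace(copy.deepcopy(profiles[name]), label=name), dur)
        for name, dur in epoch_durations.items()
    ]
    return generate_recording(sequence, fs=fs, seed=seed, recording_id=recording_id)
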
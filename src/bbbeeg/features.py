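"""Shifting-window band-power features and their two normalizations.

The detector's input representation: each recording is cut into 60-s
windows advanced by 10 s.  Within a window the one-sided FFT magnitude
spectrum is computed per channel, band power is the *mean* of squared
harmonic amplitudes over the harmonics falling in each of the five
classical bands

    gamma [30, 50) Hz, beta [12, 30), alpha [8, 12), theta [4, 8),
    delta [1, 4) Hz,

channel powers are summed (X_k = P_1,k + P_2,k), and the five log powers
are normalized either

* normalization 1: ``ln X_k / sum_k ln X_k``  (components sum to 1;
  sensitive to the absolute power scale), or
* normalization 2: ``(ln X_k - ln X_min) / (ln X_max - ln X_min)``
  (min 0, max 1; invariant to any global power rescaling).

Band membership uses the half-open convention [low, high) so that every
harmonic in [1, 50) Hz belongs to exactly one band.  No taper or
detrending is applied before the FFT (configurable via ``window_fn``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .recording import ConfigurationError, EEGRecording

__all__ = [
    "WindowSpec",
    "BandDefinition",
    "BANDS",
    "BAND_NAMES",
    "segment_windows",
    "band_power",
    "band_powers",
    "sum_channels",
    "normalize1",
    "normalize2",
    "extract_features",
    "feature_matrix",
    "FEATURE_COLUMNS",
]


@dataclass(frozen=True)
class WindowSpec:
    """Shifting-window geometry: duration delta and shift tau, seconds."""

    duration_s: float = 60.0
    shift_s: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.shift_s <= self.duration_s:
            raise ConfigurationError(
                f"need 0 < shift ({self.shift_s}) <= duration ({self.duration_s})"
            )

    def count(self, total_s: float) -> int:
        """Closed-form window count floor((T - delta)/tau) + 1."""
        if total_s < self.duration_s:
            return 0
        return int(np.floor((total_s - self.duration_s) / self.shift_s + 1e-9)) + 1


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ConfigurationError(f"bad band edges [{self.low_hz}, {self.high_hz})")

    def harmonic_indices(self, n_samples: int, fs: float) -> np.ndarray:
        """Indices of one-sided FFT harmonics with low <= f < high."""
        if self.high_hz > fs / 2 + 1e-9:
            raise ConfigurationError(
                f"band {self.name} upper edge {self.high_hz} Hz above Nyquist {fs / 2}"
            )
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        idx = np.nonzero((freqs >= self.low_hz - 1e-12) & (freqs < self.high_hz - 1e-12))[0]
        if idx.size == 0:
            raise ConfigurationError(
                f"band {self.name} contains no FFT harmonics at n={n_samples}, fs={fs}"
            )
        return idx


#: The five analysed bands, in the order used throughout (gamma .. delta).
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("gamma", 30.0, 50.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("delta", 1.0, 4.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)
FEATURE_COLUMNS: tuple[str, ...] = tuple(f"f_{n}" for n in BAND_NAMES)

#: Flag floor for non-positive band powers, relative to the window maximum.
POWER_FLOOR_REL = 1e-12
#: Degenerate-denominator tolerance for both normalizations (ln units).
DENOM_TOL = 1e-3


@dataclass(frozen=True)
class Window:
    """One analysis window: sample slice plus its start time."""

    start_s: float
    start_idx: int
    stop_idx: int


def segment_windows(recording: EEGRecording, spec: WindowSpec = WindowSpec()) -> list[Window]:
    """Cut the recording into shifting windows (trailing partials dropped)."""
    n_win_samples = int(round(spec.duration_s * recording.fs))
    step = int(round(spec.shift_s * recording.fs))
    if recording.n_samples < n_win_samples:
        raise ConfigurationError(
            f"recording {recording.id!r} ({recording.duration_s:.1f} s) is shorter "
            f"than one {spec.duration_s} s window"
        )
    windows = []
    start = 0
    while start + n_win_samples <= recording.n_samples:
        windows.append(Window(start / recording.fs, start, start + n_win_samples))
        start += step
    return windows


def band_power(
    samples: np.ndarray,
    fs: float,
    band: BandDefinition,
    window_fn: Callable[[int], np.ndarray] | None = None,
) -> float:
    """Mean squared FFT harmonic amplitude of one channel over one band.

    ``window_fn`` optionally supplies a taper of the window length; by
    default the plain (rectangular) FFT is taken.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1:
        raise ConfigurationError("band_power expects a single channel (1-D)")
    if window_fn is not None:
        x = x * window_fn(x.size)
    amps = np.abs(np.fft.rfft(x))
    idx = band.harmonic_indices(x.size, fs)
    return float(np.mean(amps[idx] ** 2))


def band_powers(
    window_samples: np.ndarray,
    fs: float,
    bands: Sequence[BandDefinition] = BANDS,
    window_fn: Callable[[int], np.ndarray] | None = None,
) -> np.ndarray:
    """Per-channel band powers, shape ``(n_channels, n_bands)``.

    One FFT per channel; bands share the spectrum.
    """
    x = np.atleast_2d(np.asarray(window_samples, dtype=np.float64))
    if window_fn is not None:
        x = x * window_fn(x.shape[1])[None, :]
    amps2 = np.abs(np.fft.rfft(x, axis=1)) ** 2
    out = np.empty((x.shape[0], len(bands)))
    for j, band in enumerate(bands):
        idx = band.harmonic_indices(x.shape[1], fs)
        out[:, j] = amps2[:, idx].mean(axis=1)
    return out


def sum_channels(per_channel: np.ndarray, expected_channels: int | None = 2) -> np.ndarray:
    """Channel-summed band powers ``X_k = sum_c P_c,k``.

    The method is defined for exactly two channels; pass
    ``expected_channels=None`` to allow any count.
    """
    p = np.atleast_2d(np.asarray(per_channel, dtype=np.float64))
    if expected_channels is not None and p.shape[0] != expected_channels:
        raise ConfigurationError(
            f"channel summation expects {expected_channels} channels, got {p.shape[0]}"
        )
    return p.sum(axis=0)


def _floored_log(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Logs of band powers, flooring non-positive entries; flags validity."""
    x = np.asarray(x, dtype=np.float64)
    mx = x.max() if x.size else 0.0
    if not np.isfinite(mx) or mx <= 0:
        return np.full(x.shape, np.nan), False
    floor = POWER_FLOOR_REL * mx
    return np.log(np.maximum(x, floor)), True


def normalize1(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Normalization 1: ln X_k divided by the sum of the five ln X_k.

    Returns ``(vector, valid)``; invalid windows (all-zero power, or a
    denominator within ``DENOM_TOL`` of zero) get NaN components and are
    meant to be carried with ``valid=False``, never silently dropped.
    """
    logs, ok = _floored_log(x)
    if not ok:
        return logs, False
    denom = logs.sum()
    if abs(denom) < DENOM_TOL:
        return np.full(logs.shape, np.nan), False
    return logs / denom, True


def normalize2(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Normalization 2: min-max rescaling of the five ln X_k to [0, 1]."""
    logs, ok = _floored_log(x)
    if not ok:
        return logs, False
    lo, hi = logs.min(), logs.max()
    if hi - lo < DENOM_TOL:
        return np.full(logs.shape, np.nan), False
    return (logs - lo) / (hi - lo), True


_NORMALIZERS = {1: normalize1, 2: normalize2}


def extract_features(
    recording: EEGRecording,
    spec: WindowSpec = WindowSpec(),
    normalization: int = 1,
    bands: Sequence[BandDefinition] = BANDS,
    window_fn: Callable[[int], np.ndarray] | None = None,
    expected_channels: int | None = 2,
) -> pd.DataFrame:
    """Feature table for one recording: one row per shifting window.

    Columns: ``recording_id, window_start_s, label, norm, f_gamma .. f_delta,
    valid``.  A window inherits the label of the epoch containing its start
    time.  Flagged (degenerate) windows keep their row with ``valid=False``
    and NaN features.
    """
    if normalization not in _NORMALIZERS:
        raise ConfigurationError(f"normalization must be 1 or 2, got {normalization}")
    normalizer = _NORMALIZERS[normalization]
    windows = segment_windows(recording, spec)
    rows = np.empty((len(windows), len(bands)))
    valid = np.empty(len(windows), dtype=bool)
    starts = np.empty(len(windows))
    for i, w in enumerate(windows):
        per_ch = band_powers(recording.signal[:, w.start_idx : w.stop_idx], recording.fs,
                             bands, window_fn)
        x = sum_channels(per_ch, expected_channels)
        rows[i], valid[i] = normalizer(x)
        starts[i] = w.start_s
    df = pd.DataFrame(rows, columns=[f"f_{b.name}" for b in bands])
    df.insert(0, "recording_id", recording.id)
    df.insert(1, "window_start_s", starts)
    df.insert(2, "label", [recording.label_at(t) for t in starts])
    df.insert(3, "norm", normalization)
    df["valid"] = valid
    return df


def feature_matrix(table: pd.DataFrame, valid_only: bool = True) -> np.ndarray:
    """The ``(n_windows, 5)`` feature array from a feature table."""
    df = table[table["valid"]] if valid_only else table
    return df.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
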
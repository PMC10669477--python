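"""Welch spectral-power trajectories and the normalized change index.

Slow-wave power is tracked through a recording by estimating the Welch
power spectral density (60-s Hann subwindows, 30-s offset, i.e. 50 %
overlap) inside 250-s sliding windows stepped by 50 s, and averaging the
density over a band's frequency range (delta and theta by default) and
over channels.  The per-animal effect of anesthesia is summarised by the
normalized change index

    Delta = (m1 - m0) / m0,

where ``m0`` and ``m1`` are the median trajectory values during the
baseline and anesthesia epochs.  The index is invariant to any global
rescaling of the recording's power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .features import BANDS, BandDefinition
from .recording import ConditionEpoch, ConfigurationError, EEGRecording

__all__ = ["welch_psd", "band_trajectory", "SpectralTrajectory",
           "DeltaIndex", "delta_index"]

_BAND_BY_NAME = {b.name: b for b in BANDS}


def welch_psd(segment: np.ndarray, fs: float, subwindow_s: float = 60.0,
              offset_s: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of one segment (channels x samples or 1-D).

    Hann-tapered ``subwindow_s`` segments advanced by ``offset_s`` (50 %
    overlap at the defaults), no detrending, density scaling — so the
    integral of the density over frequency recovers the signal variance
    up to taper correction.  Returns ``(freqs, psd)`` with psd shaped
    like the input's channel axis.
    """
    x = np.atleast_2d(np.asarray(segment, dtype=np.float64))
    nperseg = int(round(subwindow_s * fs))
    if x.shape[1] < nperseg:
        raise ConfigurationError(
            f"segment of {x.shape[1]} samples is shorter than one "
            f"{subwindow_s} s Welch subwindow"
        )
    noverlap = nperseg - int(round(offset_s * fs))
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=noverlap, detrend=False, axis=1)
    if np.asarray(segment).ndim == 1:
        psd = psd[0]
    return freqs, psd


@dataclass
class SpectralTrajectory:
    """Band-power time course from sliding-window Welch estimates."""

    band: str
    times: np.ndarray   # centers of the sliding windows, s
    power: np.ndarray   # mean PSD over the band and channels
    window_s: float
    step_s: float
    subwindow_s: float
    offset_s: float
    recording_id: str = "recording"

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ConfigurationError("trajectory power must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("trajectory times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"band": self.band, "time_s": self.times,
                             "power": self.power})


def band_trajectory(recording: EEGRecording, band: str | BandDefinition = "delta",
                    window_s: float = 250.0, step_s: float = 50.0,
                    subwindow_s: float = 60.0, offset_s: float = 30.0) -> SpectralTrajectory:
    """Mean in-band Welch density in sliding windows along the recording.

    Trajectory length is ``floor((T - window_s)/step_s) + 1``; the two
    channels' densities are averaged.
    """
    if isinstance(band, str):
        try:
            band = _BAND_BY_NAME[band]
        except KeyError:
            raise ConfigurationError(f"unknown band {band!r}") from None
    n_win = int(round(window_s * recording.fs))
    n_step = int(round(step_s * recording.fs))
    if recording.n_samples < n_win:
        raise ConfigurationError(
            f"recording {recording.id!r} shorter than one {window_s} s window"
        )
    times, power = [], []
    freq_mask = None
    start = 0
    while start + n_win <= recording.n_samples:
        freqs, psd = welch_psd(recording.signal[:, start : start + n_win],
                               recording.fs, subwindow_s, offset_s)
        if freq_mask is None:
            freq_mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
        power.append(psd[:, freq_mask].mean())
        times.append((start + n_win / 2) / recording.fs)
        start += n_step
    return SpectralTrajectory(band.name, np.array(times), np.array(power),
                              window_s, step_s, subwindow_s, offset_s,
                              recording.id)


@dataclass(frozen=True)
class DeltaIndex:
    """Normalized change in median band power between two states."""

    band: str
    m0: float  # median power, normal state
    m1: float  # median power, anesthesia
    delta: float

    @property
    def value(self) -> float:
        return self.delta


def delta_index(trajectory: SpectralTrajectory,
                baseline_epoch: ConditionEpoch,
                anesthesia_epoch: ConditionEpoch) -> DeltaIndex:
    """Delta = (m1 - m0)/m0 from trajectory points inside each epoch.

    A point belongs to an epoch when its sliding-window *center* falls in
    it.  Requires at least one point per epoch and a positive baseline
    median.
    """
    def points(ep: ConditionEpoch) -> np.ndarray:
        mask = (trajectory.times >= ep.start_s) & (trajectory.times < ep.end_s)
        vals = trajectory.power[mask]
        if vals.size == 0:
            raise ConfigurationError(
                f"epoch {ep.label} [{ep.start_s}, {ep.end_s}) s contains no "
                "trajectory points"
            )
        return vals

    m0 = float(np.median(points(baseline_epoch)))
    m1 = float(np.median(points(anesthesia_epoch)))
    if m0 <= 0:
        raise ConfigurationError("baseline median power m0 must be positive")
    return DeltaIndex(trajectory.band, m0, m1, (m1 - m0) / m0)
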
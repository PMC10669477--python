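"""Core containers for annotated multichannel EEG recordings.

An :class:`EEGRecording` bundles the raw signal matrix (channels x samples,
microvolts), the sampling rate, and an ordered list of condition epochs
(baseline / anesthesia stages, or the two training classes).  Every
downstream stage — feature extraction, classification, spectral
trajectories — consumes this one container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Closed vocabulary of condition labels.  ``normal_behavior`` and
#: ``artificial_obbb`` are the two training classes; the remaining labels
#: annotate the anesthesia test recordings.
CONDITION_LABELS: tuple[str, ...] = (
    "baseline",
    "iso1",
    "iso4",
    "death",
    "normal_behavior",
    "artificial_obbb",
)

#: Upper edge (Hz) of the highest analysed band (gamma); recordings must be
#: sampled at >= twice this rate.
MAX_BAND_EDGE_HZ = 50.0


class ConfigurationError(ValueError):
    """Raised when a recording, profile or config violates its contract."""


@dataclass(frozen=True)
class ConditionEpoch:
    """A labelled, contiguous stretch of a recording, in seconds from onset."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ConfigurationError(
                f"epoch start {self.start_s} must precede end {self.end_s}"
            )
        if self.label not in CONDITION_LABELS:
            raise ConfigurationError(
                f"unknown condition label {self.label!r}; "
                f"expected one of {CONDITION_LABELS}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        """Half-open membership: ``start_s <= t < end_s``."""
        return self.start_s <= t < self.end_s


@dataclass
class EEGRecording:
    """Two-channel (by default) cortical EEG with condition annotations.

    Parameters
    ----------
    signal
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz; must be at least ``2 * MAX_BAND_EDGE_HZ``.
    epochs
        Non-overlapping, sorted condition epochs covering ``[0, duration]``
        (coverage is not enforced, containment is).
    id
        Animal / recording label used in output tables.
    """

    signal: np.ndarray
    fs: float
    epochs: tuple[ConditionEpoch, ...] = field(default_factory=tuple)
    id: str = "recording"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ConfigurationError(
                f"signal must be 2-D (channels, samples); got {self.signal.ndim}-D"
            )
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if self.fs < 2 * MAX_BAND_EDGE_HZ:
            raise ConfigurationError(
                f"fs={self.fs} Hz is below the Nyquist bound "
                f"{2 * MAX_BAND_EDGE_HZ} Hz for the {MAX_BAND_EDGE_HZ} Hz gamma edge"
            )
        self.epochs = tuple(self.epochs)
        prev_end = 0.0
        for ep in self.epochs:
            if ep.start_s < prev_end - 1e-9:
                raise ConfigurationError("epochs must be sorted and non-overlapping")
            if ep.end_s > self.duration_s + 1e-9:
                raise ConfigurationError(
                    f"epoch {ep} extends past recording end {self.duration_s:.1f} s"
                )
            prev_end = ep.end_s

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def label_at(self, t: float) -> str | None:
        """Condition label of the epoch containing time ``t`` (None if gap)."""
        for ep in self.epochs:
            if ep.contains(t):
                return ep.label
        return None

    def epoch_for(self, label: str) -> ConditionEpoch:
        """First epoch carrying ``label`` (KeyError if absent)."""
        for ep in self.epochs:
            if ep.label == label:
                return ep
        raise KeyError(f"no epoch labelled {label!r} in recording {self.id!r}")
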
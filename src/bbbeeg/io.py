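"""Reading and writing recordings: EDF and a plain delimited-text dialect.

Two on-disk formats are supported:

* European Data Format (EDF): 16-bit quantized signals.  Reading goes
  through MNE; writing uses a minimal single-record EDF writer (physical
  range symmetric around zero, digital range +/-32767).
* Delimited text: a header line ``fs=<Hz>`` followed by one row per
  sample, tab-separated channels, in microvolts.

Condition epochs travel in a plain-text sidecar table
``<stem>.epochs.tsv`` with columns ``start_s  end_s  label`` next to the
signal file, for both formats.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .recording import ConditionEpoch, ConfigurationError, EEGRecording

__all__ = ["read_recording", "write_recording", "epoch_sidecar_path"]

_DIG_MAX = 32767


def epoch_sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".epochs.tsv")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("edf", "txt"):
            raise ConfigurationError(f"unknown format {format!r}; use 'edf' or 'txt'")
        return format
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".txt", ".tsv", ".csv"):
        return "txt"
    raise ConfigurationError(f"cannot infer format from suffix {suffix!r}")


def _write_epochs(path: Path, epochs: tuple[ConditionEpoch, ...]) -> None:
    if not epochs:
        return
    lines = ["start_s\tend_s\tlabel"]
    lines += [f"{ep.start_s:.3f}\t{ep.end_s:.3f}\t{ep.label}" for ep in epochs]
    epoch_sidecar_path(path).write_text("\n".join(lines) + "\n")


def _read_epochs(path: Path) -> tuple[ConditionEpoch, ...]:
    sidecar = epoch_sidecar_path(path)
    if not sidecar.exists():
        return ()
    epochs = []
    for line in sidecar.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        start, end, label = line.split("\t")
        epochs.append(ConditionEpoch(float(start), float(end), label))
    return tuple(epochs)


# ---------------------------------------------------------------------------
# delimited text


def _write_txt(recording: EEGRecording, path: Path) -> None:
    with path.open("w") as fh:
        fh.write(f"fs={recording.fs:g}\n")
        np.savetxt(fh, recording.signal.T, fmt="%.6f", delimiter="\t")


def _read_txt(path: Path) -> tuple[np.ndarray, float]:
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise ConfigurationError(
                f"{path}: first line must declare the sampling rate as 'fs=<Hz>'"
            )
        fs = float(header[3:])
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return data.T, fs


# ---------------------------------------------------------------------------
# EDF

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ConfigurationError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _phys_range_str(v: float) -> str:
    """Smallest-decimal fixed-notation string >= v that fits 7 chars, so
    both '<s>' and '-<s>' fit the 8-char physical-range header fields."""
    for dec in range(6, -1, -1):
        val = np.ceil(v * 10**dec) / 10**dec
        s = f"{val:.{dec}f}"
        if len(s) <= 7:
            return s
    raise ConfigurationError(f"physical range {v} too large for an EDF header")


def _write_edf(recording: EEGRecording, path: Path) -> None:
    """Minimal EDF: one data record spanning the whole signal, 16-bit."""
    n_ch, n_samp = recording.signal.shape
    phys_max = float(np.max(np.abs(recording.signal)))
    if phys_max == 0:
        phys_max = 1.0
    # quantize against the value actually printed in the header fields,
    # or reader and writer scales would disagree by the rounding error
    phys_str = _phys_range_str(phys_max)
    phys_max = float(phys_str)
    duration = n_samp / recording.fs
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X", 80),
            _pad(recording.id[:80], 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (n_ch + 1)), 8),
            _pad("", 44),
            _pad("1", 8),  # one data record
            _pad(f"{duration:.6g}"[:8], 8),
            _pad(str(n_ch), 4),
        ]
    )
    fields = [
        (f"EEG{c + 1}", 16) for c in range(n_ch)
    ]
    per_signal = b"".join(
        [_pad(lbl, w) for lbl, w in fields]
        + [_pad("", 80) for _ in range(n_ch)]  # transducer
        + [_pad("uV", 8) for _ in range(n_ch)]
        + [_pad("-" + phys_str, 8) for _ in range(n_ch)]
        + [_pad(phys_str, 8) for _ in range(n_ch)]
        # symmetric digital range: cal = phys_max/32767 with zero offset
        + [_pad(str(-_DIG_MAX), 8) for _ in range(n_ch)]
        + [_pad(str(_DIG_MAX), 8) for _ in range(n_ch)]
        + [_pad("", 80) for _ in range(n_ch)]  # prefiltering
        + [_pad(str(n_samp), 8) for _ in range(n_ch)]
        + [_pad("", 32) for _ in range(n_ch)]
    )
    scale = phys_max / _DIG_MAX
    digital = np.clip(
        np.round(recording.signal / scale), -_DIG_MAX, _DIG_MAX
    ).astype("<i2")
    with path.open("wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(digital.tobytes())  # channel-major within the single record


def _read_edf(path: Path) -> tuple[np.ndarray, float]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(units="uV"), float(raw.info["sfreq"])


# ---------------------------------------------------------------------------
# public API


def write_recording(recording: EEGRecording, path: str | Path,
                    format: str | None = None) -> Path:
    """Write a recording (and its epoch sidecar) to ``path``."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "edf":
        _write_edf(recording, path)
    else:
        _write_txt(recording, path)
    _write_epochs(path, recording.epochs)
    return path


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read a recording written by :func:`write_recording` (or any EDF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    signal, fs = _read_edf(path) if fmt == "edf" else _read_txt(path)
    if signal.shape[0] < 1:
        raise ConfigurationError(f"{path}: no channels found")
    return EEGRecording(signal, fs, _read_epochs(path), id=path.stem)
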
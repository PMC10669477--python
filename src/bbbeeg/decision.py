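"""From raw classifier responses to smoothed curves, binary answers and
per-condition statistics.

The raw per-window response (one value per 10-s shifting window) is noisy;
it is averaged in a 16-min (960 s) sliding window stepped along the same
10-s grid, then binarized against the mean level of the smoothed curve
over the whole recording: windows where the smoothed response lies
strictly above that level read "barrier opened / drainage activated" (1),
all others 0.  Per condition epoch the module reports box-plot statistics
of the binary-gated smoothed response and a per-animal detection flag
(any binary-1 run of at least a minimum duration inside the epoch),
aggregated to a cohort detection fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import ConditionEpoch, ConfigurationError

__all__ = [
    "smooth_response",
    "binarize",
    "ResponseTrace",
    "ConditionSummary",
    "condition_statistics",
]


def smooth_response(times: np.ndarray, raw: np.ndarray,
                    window_s: float = 960.0, step_s: float = 10.0) -> np.ndarray:
    """Sliding-mean smoothing on the response's own time grid.

    Each output sample is the arithmetic mean of the raw values whose
    window-start times fall in ``[t - window_s/2, t + window_s/2)``; NaN
    gaps (invalid windows) are excluded from the mean, and edges use the
    available points (truncated means), so the smoothed curve spans the
    whole recording.
    """
    times = np.asarray(times, dtype=np.float64)
    raw = np.asarray(raw, dtype=np.float64)
    if times.size == 0:
        raise ConfigurationError("empty response trace")
    if window_s < step_s:
        raise ConfigurationError("smoothing window must be at least one step")
    if np.any(np.diff(times) <= 0):
        raise ConfigurationError("trace times must be strictly increasing")
    half = window_s / 2.0
    valid = np.isfinite(raw)
    out = np.full(times.shape, np.nan)
    # windows are short relative to n; two-pointer pass keeps this O(n)
    lo = hi = 0
    csum = np.concatenate([[0.0], np.cumsum(np.where(valid, raw, 0.0))])
    ccnt = np.concatenate([[0], np.cumsum(valid.astype(int))])
    for i, t in enumerate(times):
        while lo < times.size and times[lo] < t - half:
            lo += 1
        if hi < lo:
            hi = lo
        while hi < times.size and times[hi] < t + half:
            hi += 1
        cnt = ccnt[hi] - ccnt[lo]
        if cnt:
            out[i] = (csum[hi] - csum[lo]) / cnt
    return out


def binarize(smoothed: np.ndarray) -> tuple[np.ndarray, float]:
    """Threshold the smoothed curve at its own mean level.

    The threshold is the mean of the smoothed response over the entire
    recording; the binary answer is 1 strictly above it, 0 otherwise
    (ties and gaps give 0).
    """
    smoothed = np.asarray(smoothed, dtype=np.float64)
    if smoothed.size == 0 or not np.isfinite(smoothed).any():
        raise ConfigurationError("cannot binarize an all-gap trace")
    threshold = float(np.nanmean(smoothed))
    binary = np.where(np.isfinite(smoothed) & (smoothed > threshold), 1, 0)
    return binary.astype(np.int8), threshold


@dataclass
class ResponseTrace:
    """Time-aligned raw / smoothed / binary classifier output for one
    recording, plus the epoch annotations needed for condition statistics."""

    recording_id: str
    normalization: int
    times: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    binary: np.ndarray
    threshold: float
    valid: np.ndarray
    epochs: tuple[ConditionEpoch, ...]

    @classmethod
    def from_response(cls, response: pd.DataFrame,
                      epochs: tuple[ConditionEpoch, ...],
                      window_s: float = 960.0) -> "ResponseTrace":
        """Smooth and binarize a raw response table (predict_response output)."""
        times = response["window_start_s"].to_numpy(dtype=np.float64)
        raw = response["response"].to_numpy(dtype=np.float64)
        step = float(np.median(np.diff(times))) if times.size > 1 else window_s
        smoothed = smooth_response(times, raw, window_s=window_s, step_s=step)
        binary, threshold = binarize(smoothed)
        return cls(
            recording_id=str(response["recording_id"].iloc[0]),
            normalization=int(response["norm"].iloc[0]),
            times=times, raw=raw, smoothed=smoothed, binary=binary,
            threshold=threshold, valid=np.isfinite(raw), epochs=tuple(epochs),
        )

    @property
    def gated(self) -> np.ndarray:
        """Smoothed response where the binary answer is 1, else 0 (NaN gaps)."""
        g = np.where(self.binary == 1, self.smoothed, 0.0)
        g[~np.isfinite(self.smoothed)] = np.nan
        return g

    def epoch_mask(self, epoch: ConditionEpoch) -> np.ndarray:
        return (self.times >= epoch.start_s) & (self.times < epoch.end_s)

    def detected(self, epoch: ConditionEpoch, min_run_s: float = 60.0,
                 step_s: float | None = None) -> bool:
        """Detection call: a binary-1 run of at least ``min_run_s`` in the epoch."""
        if step_s is None:
            step_s = float(np.median(np.diff(self.times))) if self.times.size > 1 else 1.0
        need = max(int(np.ceil(min_run_s / step_s)), 1)
        b = self.binary[self.epoch_mask(epoch)]
        run = best = 0
        for v in b:
            run = run + 1 if v == 1 else 0
            best = max(best, run)
        return best >= need

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_start_s": self.times,
            "raw": self.raw,
            "smoothed": self.smoothed,
            "binary": self.binary,
            "threshold": self.threshold,
            "valid": self.valid,
        })


@dataclass
class ConditionSummary:
    """Cohort statistics: per-condition box summaries and detection calls."""

    per_condition: pd.DataFrame  # one row per (normalization, label)
    per_animal: pd.DataFrame     # one row per (normalization, recording, label)

    def detection_fraction(self, label: str, normalization: int | None = None) -> float:
        df = self.per_animal[self.per_animal["label"] == label]
        if normalization is not None:
            df = df[df["normalization"] == normalization]
        if df.empty:
            raise KeyError(f"condition {label!r} absent from all recordings")
        return float(df["detected"].mean())

    def median_response(self, label: str, normalization: int | None = None) -> float:
        df = self.per_condition[self.per_condition["label"] == label]
        if normalization is not None:
            df = df[df["normalization"] == normalization]
        if df.empty:
            raise KeyError(f"condition {label!r} absent from summary")
        return float(df["q50"].iloc[0])

    def mean_response(self, label: str, normalization: int | None = None) -> float:
        df = self.per_condition[self.per_condition["label"] == label]
        if normalization is not None:
            df = df[df["normalization"] == normalization]
        if df.empty:
            raise KeyError(f"condition {label!r} absent from summary")
        return float(df["mean"].iloc[0])


def condition_statistics(traces: list[ResponseTrace],
                         min_run_s: float = 60.0) -> ConditionSummary:
    """Box-plot five-number summaries of the gated response per condition,
    per-animal detection flags, and cohort detection fractions.

    The pooled statistic per condition is the binary-gated smoothed
    response (zero where the answer is 0) over every valid window of
    every animal's matching epochs; ``n_nonzero`` and ``mean_nonzero``
    additionally describe only the windows that fired.
    """
    if not traces:
        raise ConfigurationError("no traces supplied")
    rows_animal = []
    pooled: dict[tuple[int, str], list[np.ndarray]] = {}
    for trace in traces:
        if not trace.epochs:
            raise ConfigurationError(
                f"trace {trace.recording_id!r} carries no epoch annotations"
            )
        for ep in trace.epochs:
            mask = trace.epoch_mask(ep)
            gated = trace.gated[mask]
            gated = gated[np.isfinite(gated)]
            pooled.setdefault((trace.normalization, ep.label), []).append(gated)
            rows_animal.append({
                "normalization": trace.normalization,
                "recording_id": trace.recording_id,
                "label": ep.label,
                "n_windows": int(mask.sum()),
                "n_fired": int((trace.binary[mask] == 1).sum()),
                "detected": trace.detected(ep, min_run_s=min_run_s),
            })
    rows_cond = []
    for (norm, label), chunks in sorted(pooled.items()):
        values = np.concatenate(chunks) if chunks else np.array([])
        nonzero = values[values > 0]
        q = (np.percentile(values, [0, 25, 50, 75, 100])
             if values.size else np.full(5, np.nan))
        rows_cond.append({
            "normalization": norm,
            "label": label,
            "n_windows": int(values.size),
            "mean": float(values.mean()) if values.size else np.nan,
            "q0": q[0], "q25": q[1], "q50": q[2], "q75": q[3], "q100": q[4],
            "n_nonzero": int(nonzero.size),
            "mean_nonzero": float(nonzero.mean()) if nonzero.size else np.nan,
            "all_zero": bool(values.size and nonzero.size == 0),
        })
    per_animal = pd.DataFrame(rows_animal)
    per_condition = rows = pd.DataFrame(rows_cond)
    det = (per_animal.groupby(["normalization", "label"])["detected"]
           .mean().rename("detection_fraction"))
    per_condition = rows.merge(det.reset_index(), on=["normalization", "label"])
    return ConditionSummary(per_condition, per_animal)
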
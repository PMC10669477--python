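"""End-to-end study orchestration: corpus -> training -> application ->
spectral reports.

The stages mirror the experimental workflow: generate (or load) a
two-class training corpus and an anesthesia cohort; train the band-power
classifier on normalization-1 features; apply it to every cohort animal
under either normalization, producing response traces and condition
summaries; compute delta/theta Welch trajectories and the normalized
change indices.  :func:`run_study` performs everything in memory; the
``cmd_*`` functions are the disk-backed counterparts behind the CLI.

Every emitted table carries a header comment with the config hash and
seed, so any number in any output can be traced to the exact run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as rec_io
from .classifier import (BandPowerClassifier, ClassifierResults, ClassifierSpec,
                         TrainConfig, split_dataset)
from .decision import ConditionSummary, ResponseTrace, condition_statistics
from .features import WindowSpec, extract_features, feature_matrix
from .recording import ConfigurationError, EEGRecording
from .spectral import DeltaIndex, band_trajectory, delta_index
from .synth import (StateProfile, default_profiles, generate_anesthesia_recording,
                    generate_training_corpus)

__all__ = ["RunConfig", "run_study", "train_on_corpus", "analyze_recording",
           "apply_to_cohort", "cohort_spectra",
           "cmd_generate", "cmd_train", "cmd_apply", "cmd_spectra", "cmd_report"]

CLASS_TO_INDEX = {"normal_behavior": 0, "artificial_obbb": 1}


@dataclass
class RunConfig:
    """Declarative description of one full study surrogate."""

    seed: int = 0
    fs: float = 250.0
    out_dir: str = "runs/study"
    # corpus
    n_per_class: int = 5
    corpus_duration_s: float = 1480.0
    # cohort
    n_animals: int = 6
    cohort_epochs: Sequence[tuple[str, float]] = (
        ("baseline", 1800.0), ("iso1", 1800.0), ("iso4", 1800.0))
    # analysis
    window_duration_s: float = 60.0
    window_shift_s: float = 10.0
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    hidden_size: int = 150
    l2: float = 1e-4
    train_fraction: float = 0.70
    smooth_window_s: float = 960.0
    min_run_s: float = 60.0
    spectral_window_s: float = 250.0
    spectral_step_s: float = 50.0
    welch_subwindow_s: float = 60.0
    welch_offset_s: float = 30.0
    # optional per-profile band-target overrides, e.g. {"iso1": {"delta": 900}}
    profile_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "cohort_epochs" in payload:
            payload["cohort_epochs"] = [tuple(e) for e in payload["cohort_epochs"]]
        return cls(**payload)

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window_duration_s, self.window_shift_s)

    @property
    def classifier_spec(self) -> ClassifierSpec:
        return ClassifierSpec(hidden_size=self.hidden_size, l2=self.l2)

    def train_config(self, seed: int | None = None) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           learning_rate=self.learning_rate,
                           seed=self.seed if seed is None else seed,
                           train_fraction=self.train_fraction)

    def profiles(self) -> dict[str, StateProfile]:
        profs = default_profiles()
        for name, targets in self.profile_overrides.items():
            if name not in profs:
                raise ConfigurationError(f"unknown profile {name!r} in overrides")
            merged = dict(profs[name].band_power_targets) | {
                k: float(v) for k, v in targets.items()}
            profs[name] = dataclasses.replace(profs[name], band_power_targets=merged)
        return profs

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _table_header(cfg: RunConfig) -> str:
    return f"# seed={cfg.seed} config={cfg.config_hash()}\n"


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(_table_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# in-memory stages


def corpus_feature_table(corpus: Sequence[EEGRecording],
                         spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Normalization-1 feature table pooled over a training corpus."""
    return pd.concat(
        [extract_features(r, spec, normalization=1) for r in corpus],
        ignore_index=True,
    )


def train_on_corpus(
    corpus: Sequence[EEGRecording],
    window_spec: WindowSpec = WindowSpec(),
    classifier_spec: ClassifierSpec | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[ClassifierResults, dict[int, tuple[int, int]]]:
    """Features -> 70/30 split -> fit; returns results and split counts."""
    cfg = train_config or TrainConfig()
    table = corpus_feature_table(corpus, window_spec)
    valid = table[table["valid"]]
    y = valid["label"].map(CLASS_TO_INDEX)
    if y.isna().any():
        raise ConfigurationError("corpus contains non-training labels")
    X = feature_matrix(table)
    Xtr, ytr, Xte, yte, counts = split_dataset(
        X, y.to_numpy(dtype=np.int64), cfg.train_fraction, cfg.seed)
    model = BandPowerClassifier(Xtr, ytr, classifier_spec)
    results = model.fit(cfg, eval_set=(Xte, yte))
    return results, counts


def analyze_recording(results: ClassifierResults, recording: EEGRecording,
                      normalization: int, window_spec: WindowSpec = WindowSpec(),
                      smooth_window_s: float = 960.0) -> ResponseTrace:
    """Features under the chosen normalization -> raw response -> trace."""
    table = extract_features(recording, window_spec, normalization=normalization)
    response = results.predict_response(table)
    return ResponseTrace.from_response(response, recording.epochs,
                                       window_s=smooth_window_s)


def apply_to_cohort(results: ClassifierResults, cohort: Sequence[EEGRecording],
                    normalization: int, window_spec: WindowSpec = WindowSpec(),
                    smooth_window_s: float = 960.0,
                    min_run_s: float = 60.0) -> tuple[list[ResponseTrace], ConditionSummary]:
    if not cohort:
        raise ConfigurationError("empty cohort")
    traces = [analyze_recording(results, rec, normalization, window_spec,
                                smooth_window_s) for rec in cohort]
    return traces, condition_statistics(traces, min_run_s=min_run_s)


def cohort_spectra(cohort: Sequence[EEGRecording], cfg: RunConfig,
                   bands: Sequence[str] = ("delta", "theta"),
                   baseline_label: str = "baseline",
                   anesthesia_label: str = "iso1") -> pd.DataFrame:
    """Per-animal trajectories reduced to Delta indices, one row per
    (animal, band), plus the cohort mean +/- SEM per band."""
    rows = []
    for rec in cohort:
        for band in bands:
            traj = band_trajectory(rec, band, cfg.spectral_window_s,
                                   cfg.spectral_step_s, cfg.welch_subwindow_s,
                                   cfg.welch_offset_s)
            idx = delta_index(traj, rec.epoch_for(baseline_label),
                              rec.epoch_for(anesthesia_label))
            rows.append({"recording_id": rec.id, "band": band,
                         "m0": idx.m0, "m1": idx.m1, "delta": idx.delta})
    df = pd.DataFrame(rows)
    summary = (df.groupby("band")["delta"]
               .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
               .reset_index())
    return df.merge(summary, on="band", suffixes=("", "_cohort"))


def make_cohort(cfg: RunConfig) -> list[EEGRecording]:
    profs = cfg.profiles()
    rng = np.random.default_rng(cfg.seed + 1)
    return [
        generate_anesthesia_recording(
            seed=int(rng.integers(0, 2**31 - 1)), fs=cfg.fs,
            epoch_durations=dict(cfg.cohort_epochs), profiles=profs,
            recording_id=f"rat_{i:02d}")
        for i in range(cfg.n_animals)
    ]


def make_corpus(cfg: RunConfig) -> list[EEGRecording]:
    profs = cfg.profiles()
    return generate_training_corpus(
        cfg.n_per_class,
        {k: profs[k] for k in ("normal_behavior", "artificial_obbb")},
        fs=cfg.fs, seed=cfg.seed, duration_s=cfg.corpus_duration_s)


def run_study(cfg: RunConfig) -> dict:
    """The whole surrogate in memory; returns every intermediate product."""
    corpus = make_corpus(cfg)
    results, counts = train_on_corpus(corpus, cfg.window_spec,
                                      cfg.classifier_spec, cfg.train_config())
    cohort = make_cohort(cfg)
    out: dict = {"corpus": corpus, "cohort": cohort, "results": results,
                 "split_counts": counts}
    for norm in (1, 2):
        traces, summary = apply_to_cohort(results, cohort, norm, cfg.window_spec,
                                          cfg.smooth_window_s, cfg.min_run_s)
        out[f"traces_norm{norm}"] = traces
        out[f"summary_norm{norm}"] = summary
    out["spectra"] = cohort_spectra(cohort, cfg)
    return out


# ---------------------------------------------------------------------------
# disk-backed stages (CLI)


def _corpus_dir(cfg: RunConfig) -> Path:
    return Path(cfg.out_dir) / "corpus"


def _cohort_dir(cfg: RunConfig) -> Path:
    return Path(cfg.out_dir) / "cohort"


def _load_dir(path: Path) -> list[EEGRecording]:
    files = sorted(path.glob("*.txt"))
    if not files:
        raise ConfigurationError(f"no recordings found under {path}")
    return [rec_io.read_recording(f) for f in files]


def cmd_generate(cfg: RunConfig) -> dict[str, list[Path]]:
    """Write the training corpus and anesthesia cohort as delimited text."""
    written: dict[str, list[Path]] = {"corpus": [], "cohort": []}
    for rec in make_corpus(cfg):
        written["corpus"].append(
            rec_io.write_recording(rec, _corpus_dir(cfg) / f"{rec.id}.txt"))
    for rec in make_cohort(cfg):
        written["cohort"].append(
            rec_io.write_recording(rec, _cohort_dir(cfg) / f"{rec.id}.txt"))
    print(f"[generate] corpus: {len(written['corpus'])} recordings, "
          f"{cfg.window_spec.count(cfg.corpus_duration_s) * len(written['corpus'])} "
          f"feature windows; cohort: {len(written['cohort'])} animals")
    return written


def cmd_train(cfg: RunConfig) -> ClassifierResults:
    """Train on the on-disk corpus; write model JSON and the training log."""
    corpus = _load_dir(_corpus_dir(cfg))
    results, counts = train_on_corpus(corpus, cfg.window_spec,
                                      cfg.classifier_spec, cfg.train_config())
    out = Path(cfg.out_dir)
    results.save(out / "model.json")
    _write_table(results.curves_frame(), out / "training_log.tsv", cfg)
    for cls, (ntr, nte) in counts.items():
        print(f"[train] class {cls}: {ntr} training / {nte} testing examples")
    print(f"[train] final accuracy train={results.final_train_accuracy:.3f} "
          f"test={results.final_test_accuracy:.3f}")
    return results


def cmd_apply(cfg: RunConfig, normalization: int) -> ConditionSummary:
    """Apply the trained model to the cohort under one normalization."""
    if normalization not in (1, 2):
        raise ConfigurationError(f"normalization must be 1 or 2, got {normalization}")
    results = ClassifierResults.load(Path(cfg.out_dir) / "model.json")
    cohort = _load_dir(_cohort_dir(cfg))
    traces, summary = apply_to_cohort(results, cohort, normalization,
                                      cfg.window_spec, cfg.smooth_window_s,
                                      cfg.min_run_s)
    out = Path(cfg.out_dir) / f"norm{normalization}"
    for trace in traces:
        _write_table(trace.to_frame(), out / f"trace_{trace.recording_id}.tsv", cfg)
    _write_table(summary.per_condition, out / "condition_summary.tsv", cfg)
    _write_table(summary.per_animal, out / "per_animal.tsv", cfg)
    print(f"[apply] normalization {normalization}: {len(traces)} animals, "
          f"{len(summary.per_condition)} condition rows")
    return summary


def cmd_spectra(cfg: RunConfig) -> pd.DataFrame:
    """Delta/theta trajectories and Delta-index tables for the cohort."""
    cohort = _load_dir(_cohort_dir(cfg))
    out = Path(cfg.out_dir) / "spectra"
    for rec in cohort:
        for band in ("delta", "theta"):
            traj = band_trajectory(rec, band, cfg.spectral_window_s,
                                   cfg.spectral_step_s, cfg.welch_subwindow_s,
                                   cfg.welch_offset_s)
            _write_table(traj.to_frame(), out / f"traj_{rec.id}_{band}.tsv", cfg)
    table = cohort_spectra(cohort, cfg)
    _write_table(table, out / "delta_index.tsv", cfg)
    print(f"[spectra] {len(cohort)} animals x 2 bands; Delta-index table written")
    return table


def cmd_report(cfg: RunConfig) -> list[Path]:
    """Simple figures: response traces per normalization and trajectories."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(cfg.out_dir) / "report"
    out.mkdir(parents=True, exist_ok=True)
    figures = []
    for norm in (1, 2):
        norm_dir = Path(cfg.out_dir) / f"norm{norm}"
        files = sorted(norm_dir.glob("trace_*.tsv"))
        if not files:
            continue
        fig, axes = plt.subplots(len(files), 1, figsize=(8, 2 * len(files)),
                                 squeeze=False, sharex=True)
        for ax, f in zip(axes[:, 0], files):
            df = pd.read_csv(f, sep="\t", comment="#")
            ax.plot(df["window_start_s"], df["raw"], color="orange", lw=0.5,
                    label="raw")
            ax.plot(df["window_start_s"], df["smoothed"], color="black",
                    label="smoothed")
            ax.plot(df["window_start_s"], df["binary"], ls="--",
                    color="tab:blue" if norm == 1 else "tab:red", label="binary")
            ax.axhline(df["threshold"].iloc[0], ls="-.", color="gray")
            ax.set_ylabel(f.stem.removeprefix("trace_"))
        axes[-1, 0].set_xlabel("time (s)")
        axes[0, 0].legend(loc="upper left", fontsize=7)
        fig.suptitle(f"classifier response, normalization {norm}")
        path = out / f"responses_norm{norm}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        figures.append(path)
    spectra_dir = Path(cfg.out_dir) / "spectra"
    traj_files = sorted(spectra_dir.glob("traj_*_delta.tsv"))
    if traj_files:
        fig, ax = plt.subplots(figsize=(8, 4))
        for f in traj_files:
            df = pd.read_csv(f, sep="\t", comment="#")
            ax.plot(df["time_s"], df["power"], lw=0.8,
                    label=f.stem.removeprefix("traj_").removesuffix("_delta"))
        ax.set_xlabel("time (s)")
        ax.set_ylabel("delta-band Welch power")
        ax.legend(fontsize=7)
        path = out / "delta_trajectories.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        figures.append(path)
    print(f"[report] wrote {len(figures)} figures under {out}")
    return figures
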
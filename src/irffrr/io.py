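"""Dataset and result persistence, experiment configuration, logging.

The canonical on-disk container is HDF5 (one group per session, one group
per trial, datasets ``emg`` / ``force`` / ``stimulus``), since trials have
ragged lengths; a directory of per-trial CSV files (columns ``time,
ch1..chC, f1..f5, stim1..stim5``) is supported as a plain-text interchange
format.  Every artifact embeds the generator/experiment configuration and
seed for provenance.  Forces and stimuli are stored as fractions of MVC,
sEMG in arbitrary non-negative units.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .dataset import Trial, TrialDataset
from .evaluation import (
    EvaluationReport,
    HyperGrid,
    LearnerSpec,
    grid_search_cv,
    run_batch_setting,
    run_incremental_setting,
    run_realistic_setting,
)
from .simulate import StimulusProfile, SyntheticConfig, generate_dataset

__all__ = [
    "DATASET_FORMAT_VERSION",
    "SchemaError",
    "ExperimentConfig",
    "PRESETS",
    "save_dataset_hdf5",
    "load_dataset_hdf5",
    "save_dataset_csv",
    "load_dataset_csv",
    "load_dataset",
    "save_report",
    "config_from_file",
    "make_synthetic_config",
    "run_experiment",
    "json_logger",
]

DATASET_FORMAT_VERSION = 1


class SchemaError(ValueError):
    """A file does not match the documented dataset schema."""


# ---------------------------------------------------------------------------
# Structured logging
# ---------------------------------------------------------------------------


class _JsonLineFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        entry = {
            "t": round(time.time(), 3),
            "level": record.levelname,
            "stage": record.name.rsplit(".", 1)[-1],
            "msg": record.getMessage(),
        }
        extra = getattr(record, "data", None)
        if extra:
            entry.update(extra)
        return json.dumps(entry)


def json_logger(name: str = "irffrr", level: int = logging.INFO) -> logging.Logger:
    """Logger emitting one JSON object per line to stderr."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(_JsonLineFormatter())
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------


def save_dataset_hdf5(ds: TrialDataset, path: str | Path) -> None:
    """Write a (raw, un-featurized) dataset to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = DATASET_FORMAT_VERSION
        if ds.seed is not None:
            f.attrs["seed"] = int(ds.seed)
        if ds.config is not None:
            f.attrs["config_json"] = json.dumps(ds.config)
        for session in ds.sessions:
            for t in session:
                grp = f.create_group(
                    f"sessions/{t.session_index:02d}/trials/{t.trial_index:02d}"
                )
                grp.attrs["session_index"] = t.session_index
                grp.attrs["trial_index"] = t.trial_index
                grp.attrs["day_index"] = t.day_index
                grp.attrs["sample_rate"] = t.sample_rate
                grp.create_dataset("emg", data=t.emg)
                grp.create_dataset("force", data=t.force)
                grp.create_dataset("stimulus", data=t.stimulus)


def load_dataset_hdf5(path: str | Path) -> TrialDataset:
    """Read a dataset written by :func:`save_dataset_hdf5`.

    Trials are restored in chronological order from their (session, trial)
    index attributes regardless of on-file group order; arrays round-trip
    bit-exactly.
    """
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != DATASET_FORMAT_VERSION:
            raise SchemaError(
                f"unsupported dataset format version {version!r} in {path}"
            )
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        config = (
            json.loads(f.attrs["config_json"])
            if "config_json" in f.attrs
            else None
        )
        if "sessions" not in f:
            raise SchemaError(f"missing top-level 'sessions' group in {path}")
        trials: list[Trial] = []
        for skey in f["sessions"]:
            sgrp = f["sessions"][skey]
            if "trials" not in sgrp:
                raise SchemaError(f"session group {skey!r} has no 'trials'")
            for tkey in sgrp["trials"]:
                grp = sgrp["trials"][tkey]
                for name in ("emg", "force", "stimulus"):
                    if name not in grp:
                        raise SchemaError(
                            f"trial group {skey}/{tkey} missing dataset {name!r}"
                        )
                trials.append(
                    Trial(
                        emg=grp["emg"][()],
                        force=grp["force"][()],
                        stimulus=grp["stimulus"][()],
                        trial_index=int(grp.attrs["trial_index"]),
                        session_index=int(grp.attrs["session_index"]),
                        day_index=int(grp.attrs["day_index"]),
                        sample_rate=float(grp.attrs["sample_rate"]),
                    )
                )
    return _assemble(trials, seed, config)


def _assemble(
    trials: list[Trial], seed: int | None, config: dict | None
) -> TrialDataset:
    trials.sort(key=lambda t: (t.session_index, t.trial_index))
    sessions: dict[int, list[Trial]] = {}
    for t in trials:
        sessions.setdefault(t.session_index, []).append(t)
    ds = TrialDataset(
        sessions=[sessions[k] for k in sorted(sessions)], seed=seed, config=config
    )
    ds.validate_chronology()
    return ds


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def _csv_columns(n_channels: int, n_dofs: int) -> list[str]:
    return (
        ["time"]
        + [f"ch{i}" for i in range(1, n_channels + 1)]
        + [f"f{i}" for i in range(1, n_dofs + 1)]
        + [f"stim{i}" for i in range(1, n_dofs + 1)]
    )


def save_dataset_csv(ds: TrialDataset, directory: str | Path) -> None:
    """Write one CSV per trial (``s<SS>_t<TT>.csv``) plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": DATASET_FORMAT_VERSION,
        "seed": ds.seed,
        "config": ds.config,
        "trials": [],
    }
    for t in ds.trials():
        C, p = t.emg.shape[1], t.force.shape[1]
        name = f"s{t.session_index:02d}_t{t.trial_index:02d}.csv"
        times = np.arange(t.emg.shape[0]) / t.sample_rate
        df = pd.DataFrame(
            np.column_stack([times, t.emg, t.force, t.stimulus]),
            columns=_csv_columns(C, p),
        )
        df.to_csv(directory / name, index=False, float_format="%.6g")
        manifest["trials"].append(
            {
                "file": name,
                "session_index": t.session_index,
                "trial_index": t.trial_index,
                "day_index": t.day_index,
                "sample_rate": t.sample_rate,
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset_csv(directory: str | Path) -> TrialDataset:
    """Read a per-trial CSV directory written by :func:`save_dataset_csv`.

    Column names are validated; a missing column is reported by name rather
    than silently coerced.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"missing manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    trials: list[Trial] = []
    for entry in manifest["trials"]:
        df = pd.read_csv(directory / entry["file"])
        n_channels = sum(c.startswith("ch") for c in df.columns)
        n_dofs = sum(
            c.startswith("f") and c[1:].isdigit() for c in df.columns
        )
        expected = _csv_columns(n_channels, n_dofs)
        missing = [c for c in expected if c not in df.columns]
        if missing or n_channels == 0 or n_dofs == 0:
            raise SchemaError(
                f"{entry['file']}: missing required column(s) "
                f"{missing or ['ch*/f*/stim*']}"
            )
        emg = df[[f"ch{i}" for i in range(1, n_channels + 1)]].to_numpy()
        force = df[[f"f{i}" for i in range(1, n_dofs + 1)]].to_numpy()
        stim = df[[f"stim{i}" for i in range(1, n_dofs + 1)]].to_numpy()
        trials.append(
            Trial(
                emg=emg,
                force=force,
                stimulus=stim,
                trial_index=int(entry["trial_index"]),
                session_index=int(entry["session_index"]),
                day_index=int(entry["day_index"]),
                sample_rate=float(entry["sample_rate"]),
            )
        )
    return _assemble(trials, manifest.get("seed"), manifest.get("config"))


def load_dataset(path: str | Path, fmt: str | None = None) -> TrialDataset:
    """Load a dataset, inferring HDF5 vs CSV-directory from the path."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.is_dir() else "hdf5"
    if fmt == "hdf5":
        return load_dataset_hdf5(path)
    if fmt == "csv":
        return load_dataset_csv(path)
    raise ValueError(f"unknown dataset format {fmt!r}")


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Resolved configuration for one evaluation run.

    ``regularizer`` / ``bandwidth`` may be the string ``"cv"`` to request
    the leave-one-trial-out grid search on the initial training trials.
    Presets: ``evaluation`` (D=1000, 200 ms windows, 25 runs, CV over the
    default grid) matches the offline finger-force protocol; ``demonstration``
    (D=300, lambda=1.0, gamma=2.47, no windowing) matches the low-latency
    teleoperation configuration.
    """

    learner: str = "irffrr"
    rff_dim: int = 1000
    regularizer: float | str = 1.0
    bandwidth: float | str = 2.47
    grid: HyperGrid = field(default_factory=HyperGrid)
    setting: str = "incremental"
    runs: int = 1
    seed: int = 0
    window_length: int = 20
    increment: int = 1
    subsample_factor: int = 4
    cv_runs: int = 1

    def apply_preset(self, preset: str) -> "ExperimentConfig":
        if preset not in PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
            )
        for k, v in PRESETS[preset].items():
            setattr(self, k, v)
        return self


PRESETS: dict[str, dict] = {
    "evaluation": {
        "learner": "irffrr",
        "rff_dim": 1000,
        "window_length": 20,
        "runs": 25,
        "regularizer": "cv",
        "bandwidth": "cv",
    },
    "demonstration": {
        "learner": "irffrr",
        "rff_dim": 300,
        "regularizer": 1.0,
        "bandwidth": 2.47,
        "window_length": 1,
    },
}

_SETTINGS = ("batch", "batch-per-session", "incremental", "realistic1", "realistic2")


def config_from_file(path: str | Path, **overrides) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML or JSON file.

    Any keyword overrides (e.g. from CLI flags) take precedence over file
    values; unknown keys are errors.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    preset = raw.pop("preset", None)
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    if "grid" in raw and isinstance(raw["grid"], dict):
        raw["grid"] = HyperGrid(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw["grid"].items()
        })
    cfg = ExperimentConfig(**raw)
    if preset:
        cfg.apply_preset(preset)
    return cfg


def make_synthetic_config(params: dict | None = None, seed: int = 0) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a plain dict (e.g. YAML)."""
    params = dict(params or {})
    params.setdefault("seed", seed)
    profile = params.pop("profile", None)
    if isinstance(profile, dict):
        profile = StimulusProfile(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in profile.items()
        })
        params["profile"] = profile
    for key in ("force_inconsistency_range", "warmup_sessions"):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    if "mixing" in params and params["mixing"] is not None:
        params["mixing"] = np.asarray(params["mixing"], dtype=float)
    return SyntheticConfig(**params)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def save_report(report: EvaluationReport, out_dir: str | Path) -> dict:
    """Write a report as tidy CSV plus a JSON summary; returns the summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{report.setting}_{report.learner}"
    report.to_frame().to_csv(out_dir / f"{stem}.csv", index=False)
    summary = {
        "setting": report.setting,
        "learner": report.learner,
        "runs": report.runs,
        "n_training_trials": report.n_training_trials,
        "n_scored_trials": report.n_scored_trials,
        "overall_nmse": report.overall("nmse"),
        "overall_corr": report.overall("corr"),
        "per_session_nmse": {
            int(s): report.overall("nmse", sessions=[int(s)])
            for s in np.unique(report.session_index)
        },
        "hyperparameters": report.hyperparameters,
    }
    (out_dir / f"{stem}_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_experiment(
    cfg: ExperimentConfig,
    dataset: TrialDataset | str | Path,
    out_dir: str | Path | None = None,
) -> EvaluationReport:
    """Featurize, (optionally) tune, train and evaluate per ``cfg``.

    ``dataset`` may be a loaded raw :class:`TrialDataset` or a path to one.
    Writes tidy CSV and JSON summary artifacts when ``out_dir`` is given.
    """
    log = json_logger()
    if not isinstance(dataset, TrialDataset):
        dataset = load_dataset(dataset)
    if cfg.setting not in _SETTINGS:
        raise ValueError(
            f"unknown setting {cfg.setting!r}; choose from {_SETTINGS}"
        )
    log.info(
        "featurize", extra={"data": {"window_length": cfg.window_length,
                                     "increment": cfg.increment}}
    )
    ds = dataset.featurized(cfg.window_length, cfg.increment)

    lam, gam = cfg.regularizer, cfg.bandwidth
    spec = LearnerSpec(
        kind=cfg.learner,
        rff_dim=cfg.rff_dim,
        regularizer=lam if isinstance(lam, (int, float)) else 1.0,
        bandwidth=gam if isinstance(gam, (int, float)) else 1.0,
    )
    if lam == "cv" or gam == "cv":
        train_trials = ds.sessions[0][:3]
        lam, gam = grid_search_cv(
            train_trials,
            cfg.grid,
            spec,
            subsample_factor=cfg.subsample_factor,
            runs=cfg.cv_runs,
            seed=cfg.seed,
        )
        log.info(
            "grid-search", extra={"data": {"lambda": lam, "gamma": gam}}
        )
        spec = LearnerSpec(
            kind=cfg.learner, rff_dim=cfg.rff_dim, regularizer=lam, bandwidth=gam
        )

    log.info("evaluate", extra={"data": {"setting": cfg.setting,
                                         "learner": spec.label(),
                                         "runs": cfg.runs}})
    if cfg.setting in ("batch", "batch-per-session"):
        report = run_batch_setting(
            ds, spec, retrain_each_session=cfg.setting == "batch-per-session",
            runs=cfg.runs, seed=cfg.seed,
        )
    elif cfg.setting == "incremental":
        report = run_incremental_setting(ds, spec, runs=cfg.runs, seed=cfg.seed)
    else:
        variant = (
            "graded_stimulus" if cfg.setting == "realistic1" else "binary_stimulus"
        )
        report = run_realistic_setting(
            ds, variant, spec, runs=cfg.runs, seed=cfg.seed
        )
    if out_dir is not None:
        summary = save_report(report, out_dir)
        log.info("report", extra={"data": summary})
    return report
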
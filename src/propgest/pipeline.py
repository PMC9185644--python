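"""End-to-end pipeline runner: simulate -> train -> recognize -> evaluate.

A run is driven by one :class:`RunConfig` (YAML-loadable, validated
before any stage executes) and a single root seed from which every
stage's randomness is derived.  Outputs land in a run directory with a
manifest (config hash, seeds, package version) so deterministic stages
are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__ as _version
from .features import FilterSpec
from .fusion import recognize, score_timing
from .io import write_trial
from .schema import MODES
from .synthetic import SimulatorConfig, make_choreography, make_corpus, synthesize_trial
from .training import ALGORITHMS, TrainingConfig, save_model, train_side
from .windowing import WindowParams, build_dataset

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "events_to_json", "report_to_json"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


#: Per-side default algorithm families (the deployed configuration).
DEFAULT_SIDE_ALGOS = {"left": ("svm",), "right": ("random_forest",)}


@dataclass
class RunConfig:
    mode: str = "two-sensor"
    w: int = 30
    s: int = 5
    seed: int = 0
    n_subjects: int = 8
    n_trials: int = 10
    n_eval_trials: int = 3
    noise_sd: float = 0.35
    filter_order: int = 2
    filter_cutoff_hz: float = 4.0
    fs_hz: float = 30.0
    side_algos: dict = field(default_factory=lambda: dict(DEFAULT_SIDE_ALGOS))
    n_folds: int = 10
    nf_max: int = 30

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 1 <= self.s <= self.w:
            raise ConfigError(f"need 1 <= s <= w, got w={self.w}, s={self.s}")
        if self.n_subjects < 1 or self.n_trials < 1 or self.n_eval_trials < 1:
            raise ConfigError("n_subjects, n_trials and n_eval_trials must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not self.filter_cutoff_hz < self.fs_hz / 2:
            raise ConfigError("filter_cutoff_hz must be below Nyquist")
        for side, algos in self.side_algos.items():
            if side not in ("left", "right"):
                raise ConfigError(f"unknown side {side!r} in side_algos")
            bad = [a for a in algos if a not in ALGORITHMS]
            if bad:
                raise ConfigError(f"unknown algorithms {bad}; expected subset of {ALGORITHMS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def events_to_json(events) -> list[dict]:
    return [
        {
            "gesture_id": e.gesture_id,
            "gesture_name": e.gesture_name,
            "onset_ms": e.onset_ms,
            "duration_ms": e.duration_ms,
        }
        for e in events
    ]


def report_to_json(report) -> dict:
    return {
        "n_events": report.n_events,
        "n_reference": report.n_reference,
        "n_matched": report.n_matched,
        "onset_errors_ms": report.onset_errors_ms,
        "mae_ms": report.mae_ms,
        "duration_errors_pct": report.duration_errors_pct,
        "mean_duration_error_pct": report.mean_duration_error_pct,
        "unmatched_events": report.unmatched_events,
        "unmatched_references": report.unmatched_references,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages under *out_dir*; returns the run directory.

    Stages: corpus simulation, per-side training, recognition of fresh
    evaluation trials (unseen choreography seeds), and timing evaluation
    against the simulator's ground truth.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_cfg = SimulatorConfig(fs_hz=config.fs_hz, noise_sd=config.noise_sd)
    params = WindowParams(config.w, config.s)
    train_cfg = TrainingConfig(
        n_folds=config.n_folds, nf_max=config.nf_max, seed=config.seed
    )
    filt = FilterSpec(
        order=config.filter_order, cutoff_hz=config.filter_cutoff_hz, fs_hz=config.fs_hz
    )

    stage = "simulate"
    try:
        corpus = make_corpus(
            config.seed, n_subjects=config.n_subjects, n_trials=config.n_trials,
            config=sim_cfg,
        )
        corpus_dir = out / "corpus"
        corpus_dir.mkdir(exist_ok=True)
        for i, rec in enumerate(corpus):
            write_trial(rec, corpus_dir / f"trial_{i:03d}.csv")

        stage = "train"
        models = {}
        training_summary = {}
        for side in ("left", "right"):
            ds = build_dataset(corpus, side, config.mode, params, seed=config.seed, filt=filt)
            model = train_side(ds, train_cfg, algos=tuple(config.side_algos[side]))
            save_model(model, out / f"{side}.model.joblib")
            models[side] = model
            training_summary[side] = {
                "algorithm": model.algorithm,
                "params": model.params,
                "cv_accuracy": model.cv_accuracy,
                "cv_accuracy_pooled": model.cv_accuracy_pooled,
                "class_counts": ds.counts,
            }

        stage = "recognize"
        eval_dir = out / "eval"
        eval_dir.mkdir(exist_ok=True)
        reports = []
        for i in range(config.n_eval_trials):
            plan = make_choreography(config.seed + 9000 + i, config=sim_cfg)
            rec = synthesize_trial(plan, sim_cfg)
            write_trial(rec, eval_dir / f"eval_{i:02d}.csv")
            events = recognize(rec, models["left"], models["right"])
            with open(eval_dir / f"eval_{i:02d}.events.json", "w") as fh:
                json.dump(events_to_json(events), fh, indent=1)

            stage = "evaluate"
            report = score_timing(events, rec.annotations)
            reports.append(report_to_json(report))
            stage = "recognize"

        stage = "manifest"
        manifest = {
            "package_version": _version,
            "config": asdict(config),
            "config_sha256": config.digest(),
            "seed": config.seed,
            "training": training_summary,
            "evaluation": reports,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    except Exception as err:  # annotate which stage failed, then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed under {out}") from err
    return out
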
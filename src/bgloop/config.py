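"""Run configuration, artifact serialization and fixture curves.

A :class:`RunConfig` is the single document describing a sweep: parameter
overrides, lesion levels, replicate count, epochs and the base seed. It
round-trips through YAML, and its canonical hash is embedded in every
artifact so that outputs can be traced to the exact configuration.

Artifacts written per sweep:

* ``curves.csv`` — condition, epoch, mean_error, sd (fractions);
* ``trials.csv`` — condition, network, epoch, trial, stimulus, response,
  correct, response_time_ms (fractions/ms);
* ``summary.json`` — phase segmentation, learning times, window errors
  (percentages) and the paired-test table.

``summary.json`` can be regenerated from ``trials.csv`` alone
(:func:`summary_from_trials`), so analyses are reproducible without
re-simulation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiment import (
    ConditionSummary, LearningCurve, compare_conditions, response_time_summary,
    segment_phases, _network_learning_time,
)
from .lesion import LesionSpec, stage_of
from .params import (
    BackgroundDrive, DASchedule, LearningParams, NeuronParams, TaskParams,
)

SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """Declarative description of one experiment sweep."""

    epochs: int = 300
    n_networks: int = 30
    base_seed: int = 0
    lesions: list[float] = field(default_factory=lambda: [0.0])
    output_dir: str = "results"
    log_level: str = "INFO"
    task: TaskParams = field(default_factory=TaskParams)
    learning: LearningParams = field(default_factory=LearningParams)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    background: BackgroundDrive = field(default_factory=BackgroundDrive)
    da: DASchedule = field(default_factory=DASchedule)

    def validate(self) -> None:
        errors = []
        if self.epochs < 1:
            errors.append("epochs: must be >= 1")
        if self.n_networks < 1:
            errors.append("n_networks: must be >= 1")
        if self.base_seed < 0 or self.base_seed >= 2**31:
            errors.append("base_seed: must lie in [0, 2^31)")
        for f in self.lesions:
            if not 0.0 <= f <= 1.0:
                errors.append(f"lesions: value {f} outside [0, 1]")
        if errors:
            raise ConfigError(errors)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "epochs": self.epochs,
            "n_networks": self.n_networks,
            "base_seed": self.base_seed,
            "lesions": list(self.lesions),
            "output_dir": self.output_dir,
            "log_level": self.log_level,
            "task": dataclasses.asdict(self.task),
            "learning": dataclasses.asdict(self.learning),
            "neuron": dataclasses.asdict(self.neuron),
            "background": dataclasses.asdict(self.background),
            "da": dataclasses.asdict(self.da),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("schema_version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError([f"{k}: unknown key" for k in sorted(unknown)])
        sub = {}
        for key, typ in (("task", TaskParams), ("learning", LearningParams),
                         ("neuron", NeuronParams),
                         ("background", BackgroundDrive), ("da", DASchedule)):
            if key in d:
                try:
                    sub[key] = typ(**d.pop(key))
                except (TypeError, ValueError) as exc:
                    raise ConfigError([f"{key}: {exc}"]) from exc
        cfg = cls(**d, **sub)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(["config document must be a mapping"])
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Hash of the scientific content (output location and logging
        verbosity do not affect results and are excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class ConfigError(ValueError):
    """Invalid configuration; carries the list of offending keys."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid config: " + "; ".join(problems))


# --------------------------------------------------------------------------
# Artifact writing
# --------------------------------------------------------------------------

def _summary_payload(
    conditions: list[ConditionSummary], config_hash: str, base_seed: int
) -> dict:
    healthy = [c for c in conditions if c.lesion.lesion_fraction == 0.0]
    lesioned = [c for c in conditions if c.lesion.lesion_fraction > 0.0]
    payload: dict = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config_hash,
        "base_seed": base_seed,
        "conditions": [],
        "tests": [],
    }
    for c in conditions:
        seg = c.segmentation
        _, rt_mean = c.response_times, float(np.mean(c.response_times))
        payload["conditions"].append({
            "lesion": c.lesion.lesion_fraction,
            "stage": stage_of(c.lesion.lesion_fraction),
            "n_networks": c.n_networks,
            "n_epochs": c.n_epochs,
            "early_end": seg.early_end,
            "progressing_end": seg.progressing_end,
            "complete": seg.complete,
            "mean_learning_time": float(np.mean(c.learning_times)),
            "frac_completed": float(np.mean(c.learning_completed)),
            "mean_response_time_ms": rt_mean,
            "window_errors_pct": {
                str(k): v for k, v in c.window_errors().items()
            },
        })
    if healthy and lesioned:
        table = compare_conditions(healthy[0], lesioned)
        payload["tests"] = json.loads(
            table.to_json(orient="records", double_precision=15)
        )
    return payload


def write_artifacts(
    conditions: list[ConditionSummary], config: RunConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write curves.csv, trials.csv and summary.json for a finished sweep."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    curve_rows = []
    trial_frames = []
    for c in conditions:
        mean, sd = c.curve.mean_error, c.curve.sd_error
        for e in range(c.n_epochs):
            curve_rows.append((c.lesion.lesion_fraction, e + 1,
                               mean[e], sd[e]))
        t = c.trials.copy()
        t.insert(0, "condition", c.lesion.lesion_fraction)
        t = t.rename(columns={"response_time": "response_time_ms"})
        trial_frames.append(t)

    curves = pd.DataFrame(
        curve_rows, columns=["condition", "epoch", "mean_error", "sd"]
    )
    trials = pd.concat(trial_frames, ignore_index=True)

    paths = {
        "curves": out / "curves.csv",
        "trials": out / "trials.csv",
        "summary": out / "summary.json",
    }
    header = f"# config_hash={chash} base_seed={config.base_seed}\n"
    for name, df in (("curves", curves), ("trials", trials)):
        with open(paths[name], "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    payload = _summary_payload(conditions, chash, config.base_seed)
    paths["summary"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths


def read_artifact_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def summary_from_trials(
    trials: pd.DataFrame, base_seed: int, config_hash: str = "unknown"
) -> dict:
    """Rebuild the summary payload from a trials table alone."""
    if trials.empty:
        raise ValueError("trials table is empty; nothing to analyze")
    conditions = []
    for lesion_value, sub in trials.groupby("condition"):
        n_epochs = int(sub["epoch"].max())
        networks = sorted(sub["network"].unique())
        errors = np.zeros((len(networks), n_epochs))
        for i, netid in enumerate(networks):
            pern = sub[sub["network"] == netid]
            err = 1.0 - pern.groupby("epoch")["correct"].mean()
            errors[i] = err.sort_index().to_numpy()
        curve = LearningCurve(errors)
        lt = np.zeros(len(networks))
        comp = np.zeros(len(networks), dtype=bool)
        for i in range(len(networks)):
            lt[i], comp[i] = _network_learning_time(errors[i])
        t = sub.rename(columns={"response_time_ms": "response_time"})
        rt_per_net, _ = response_time_summary(t)
        conditions.append(ConditionSummary(
            lesion=LesionSpec(lesion_fraction=float(lesion_value)),
            curve=curve,
            segmentation=segment_phases(curve),
            learning_times=lt,
            learning_completed=comp,
            response_times=rt_per_net,
            trials=t.drop(columns=["condition"]),
            base_seed=base_seed,
            n_epochs=n_epochs,
        ))
    conditions.sort(key=lambda c: c.lesion.lesion_fraction)
    return _summary_payload(conditions, config_hash, base_seed)


# --------------------------------------------------------------------------
# Fixture curves
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureCurve:
    """Synthetic per-epoch error series with a configured phase structure."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, float))


def make_fixture_curve(
    plateaus: tuple[float, ...],
    changepoints: tuple[int, ...],
    n_epochs: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FixtureCurve:
    """Piecewise-constant error series with optional Gaussian noise.

    ``plateaus`` holds one level per segment; ``changepoints`` the last
    epoch (1-based) of each segment but the final one, strictly increasing.
    Values are clipped to [0, 1] after adding noise.
    """
    if len(plateaus) != len(changepoints) + 1:
        raise ValueError("need exactly one more plateau than changepoints")
    if list(changepoints) != sorted(set(changepoints)):
        raise ValueError("changepoints must be strictly increasing")
    series = np.empty(n_epochs)
    bounds = [0, *changepoints, n_epochs]
    for level, a, b in zip(plateaus, bounds[:-1], bounds[1:]):
        series[a:b] = level
    if noise_sd > 0:
        series = series + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=n_epochs
        )
    return FixtureCurve(values=np.clip(series, 0.0, 1.0))


__all__ = [
    "RunConfig", "ConfigError", "FixtureCurve", "make_fixture_curve",
    "write_artifacts", "read_artifact_csv", "summary_from_trials",
    "SCHEMA_VERSION",
]
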
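"""Configuration, the end-to-end trial pipeline, and the run manifest.

``run_pipeline`` drives one synthetic landing trial through every stage —
simulate (or load a trial directory), register, joint kinematics, event
detection, outcome variables — writing each stage's outputs and a manifest
that records seeds, configuration and per-stage status.  Cohort-level
statistics (summary tables) are driven separately by
:func:`run_cohort_analysis` since they consume many trials.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError
from .events import make_trial_events
from .experiments import PERTURB_DEG, PERTURB_MM
from .io import (write_angle_series, write_events, write_poses,
                 write_trial_dir)
from .kinematics import series_from_poses
from .registration import RegistrationOptions, RegistrationResult, track_sequence
from .stats import build_summary_tables, trial_variables
from .synthetic import (CohortSpec, condition_script, make_cohort,
                        make_phantom, make_trial)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline",
           "run_cohort_analysis"]


@dataclass
class PipelineConfig:
    """Validated options for one pipeline run (units: mm, ms, deg, N)."""

    seed: int = 0
    condition: str = "barefoot"
    # simulate stage
    image_noise: float = 0.02
    grf_noise_n: float = 3.0
    n_before: int = 0
    n_after: int = 14
    # registration stage
    bones: tuple = ("tibia", "talus", "calcaneus")
    n_starts: int = 3
    max_evals: int = 300
    start_sigma_mm: float = 1.0
    start_sigma_deg: float = 1.0
    init_perturb_mm: float = PERTURB_MM
    init_perturb_deg: float = PERTURB_DEG
    # events stage
    toe_threshold_n: float = 10.0
    hold_ms: float = 20.0
    heel_height_mm: float = 5.0
    # stats
    decimals: int = 1
    average_trials: bool = True
    # input (optional pre-existing trial directory; otherwise simulate)
    trial_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.condition not in ("barefoot", "shod"):
            raise ConfigError(f"condition must be barefoot|shod")
        if self.n_starts < 1 or self.max_evals < 10:
            raise ConfigError("registration options out of range")
        if not (0 <= self.image_noise < 0.5):
            raise ConfigError("image_noise out of range [0, 0.5)")
        if self.toe_threshold_n <= 0 or self.heel_height_mm < 0:
            raise ConfigError("event thresholds out of range")
        if self.trial_dir is not None and not Path(self.trial_dir).exists():
            raise ConfigError(f"trial_dir does not exist: {self.trial_dir}")

    def registration_options(self) -> RegistrationOptions:
        return RegistrationOptions(n_starts=self.n_starts,
                                   max_evals=self.max_evals,
                                   start_sigma_mm=self.start_sigma_mm,
                                   start_sigma_deg=self.start_sigma_deg,
                                   seed=self.seed)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: Dict[str, str] = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def record(self, stage: str, status: str) -> None:
        self.stages[stage] = status

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute simulate → register → kinematics → events → variables.

    Every stage's result is written under ``out_dir``; a stage failure is
    recorded in the manifest and downstream stages are skipped.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.digest(), seed=config.seed)
    state: dict = {}

    def stage(name, fn):
        if manifest.warnings and manifest.warnings[-1] == "__abort__":
            manifest.record(name, "skipped")
            return
        t0 = time.time()
        try:
            fn()
            manifest.record(name, f"ok ({time.time() - t0:.1f} s)")
        except Exception as exc:                  # noqa: BLE001
            manifest.record(name, f"failed: {exc}")
            manifest.warnings.append(traceback.format_exc(limit=2))
            manifest.warnings.append("__abort__")

    def _simulate():
        phantom = make_phantom()
        script = condition_script(config.condition)
        trial = make_trial(phantom, script, seed=config.seed,
                           image_noise=config.image_noise,
                           grf_noise_n=config.grf_noise_n,
                           n_before=config.n_before, n_after=config.n_after)
        write_trial_dir(trial, out / "trial")
        manifest.add_output(out / "trial")
        state["trial"], state["phantom"] = trial, phantom

    def _register():
        trial, phantom = state["trial"], state["phantom"]
        rng = np.random.default_rng(config.seed + 5)
        meshes = {b: phantom.meshes[b] for b in config.bones}
        init = {b: trial.truth_poses[b][0].perturbed(
                    rng, config.init_perturb_deg, config.init_perturb_mm)
                for b in meshes}
        result = track_sequence(trial.camera, meshes, trial.sequence, init,
                                config.registration_options())
        write_poses(result, out / "poses.csv")
        manifest.add_output(out / "poses.csv")
        state["registration"] = result

    def _kinematics():
        trial, phantom = state["trial"], state["phantom"]
        result: RegistrationResult = state["registration"]
        poses = result.masked_poses()
        for bone in phantom.meshes:
            if bone not in poses:           # not registered: use truth
                poses[bone] = trial.truth_poses[bone]
        series = series_from_poses(poses, phantom.frames,
                                   trial.frame_times_ms)
        write_angle_series(series, out / "angles.csv")
        manifest.add_output(out / "angles.csv")
        state["series"] = series

    def _events():
        trial, phantom = state["trial"], state["phantom"]
        poses = state["registration"].masked_poses()
        calc_poses = poses.get("calcaneus", trial.truth_poses["calcaneus"])
        ev = make_trial_events(trial.grf, calc_poses,
                               phantom.meshes["calcaneus"],
                               trial.frame_times_ms,
                               toe_threshold_n=config.toe_threshold_n,
                               hold_ms=config.hold_ms,
                               height_threshold_mm=config.heel_height_mm)
        write_events(ev, out / "events.json")
        manifest.add_output(out / "events.json")
        state["events"] = ev

    def _variables():
        from .events import TrialRecord
        trial = state["trial"]
        record = TrialRecord(subject="synthetic", condition=trial.condition,
                             trial_index=0, angles=state["series"],
                             grf=trial.grf, events=state["events"])
        vars_ = trial_variables(record)
        (out / "variables.json").write_text(json.dumps(vars_, indent=1))
        manifest.add_output(out / "variables.json")

    stage("simulate", _simulate)
    stage("register", _register)
    stage("kinematics", _kinematics)
    stage("events", _events)
    stage("variables", _variables)
    manifest.warnings = [w for w in manifest.warnings if w != "__abort__"]
    manifest.write(out / "manifest.json")
    return manifest


def run_cohort_analysis(spec: CohortSpec, out_dir) -> RunManifest:
    """Generate a synthetic cohort and emit the condition summary tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=hashlib.sha256(
        json.dumps(asdict(spec)).encode()).hexdigest()[:16], seed=spec.seed)
    trials, effects = make_cohort(spec)
    table1, table2, comparisons = build_summary_tables(trials)
    table1.to_csv(out / "table1_toe_contact_angles.csv", index=False)
    table2.to_csv(out / "table2_period_changes.csv", index=False)
    effects.to_csv(out / "ground_truth_effects.csv", index=False)
    (out / "comparisons.json").write_text(json.dumps(
        {k: c.__dict__ for k, c in comparisons.items()}, indent=1))
    for p in ("table1_toe_contact_angles.csv", "table2_period_changes.csv",
              "ground_truth_effects.csv", "comparisons.json"):
        manifest.add_output(out / p)
    manifest.record("cohort", "ok")
    manifest.write(out / "manifest.json")
    return manifest
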
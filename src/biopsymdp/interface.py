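"""Pipeline orchestration: configuration, staged execution, and reporting.

A run executes simulate (optional) -> estimate-transitions -> solve ->
sweep -> report, writing every artifact plus a machine-readable manifest
(config hash, seed, per-stage status and files) so runs are reproducible
and auditable.  All randomness flows from the single top-level seed;
per-stage seeds are derived deterministically from it.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import Horizon, config_hash
from .rewards import BASE_CASE, RewardSpec
from .sensitivity import (
    SWEEP_PARAMETERS,
    SweepSpec,
    default_base_rewards,
    one_way_sweep,
    solve_threshold,
    write_sweep,
)
from .solver import (
    ThresholdCurve,
    backward_induction,
    extract_threshold,
    write_policy,
    write_threshold_curve,
    write_value,
)
from .synthetic_data import CohortConfig, generate_cohort, load_base_kernel
from .transitions import estimate_kernel, read_kernel, read_trajectories, write_kernel, write_trajectories

#: default one-way sweep grids (table low/base/high, plus the constant-
#: disutility factor 1 the sensitivity analysis singles out)
DEFAULT_SWEEPS = {
    "d40": [0.0, 2.0, 3.0],
    "disutility_factor": [0.5, 1.0, 2.0, 4.0],
    "pct_invasive": [0.65, 0.75, 0.85],
    "tau": [1.2, 1.6, 2.0],
}

#: age bands used in the report, matching the headline result's grouping
REPORT_BANDS = ((None, 41), (42, 75), (76, None))


class ConfigError(ValueError):
    """A configuration field is missing, inconsistent, or points nowhere."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolvable from YAML or keywords."""

    out_dir: str
    seed: int = 0
    horizon: Horizon = field(default_factory=Horizon)
    simulate: bool = True
    n_patients: int = 10_000
    kernel_path: str | None = None  # used when simulate is False
    base_case: dict = field(default_factory=lambda: dict(BASE_CASE))
    sweeps: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SWEEPS.items()})
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.simulate:
            if not self.kernel_path:
                raise ConfigError("kernel_path is required when simulate is disabled")
            if not Path(self.kernel_path).exists():
                raise ConfigError(f"kernel_path does not exist: {self.kernel_path}")
        for name in self.sweeps:
            canon = "disutility_factor" if name == "factor" else name
            if canon not in SWEEP_PARAMETERS:
                raise ConfigError(f"unknown sweep parameter {name!r}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        horizon_cfg = raw.pop("horizon", None)
        cfg = cls(**raw)
        if horizon_cfg:
            cfg.horizon = Horizon(**horizon_cfg)
        return cfg

    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        d["horizon"] = {
            "start_age": self.horizon.start_age,
            "last_decision_age": self.horizon.last_decision_age,
            "terminal_age": self.horizon.terminal_age,
        }
        return d


def _derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    import hashlib

    stage_id = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([int(master), stage_id % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk).

    Any stage failure aborts with a :class:`StageError` naming the stage;
    the manifest on disk marks the run incomplete.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_map = config.to_mapping()
    manifest: dict = {
        "config_hash": config_hash(cfg_map),
        "seed": config.seed,
        "complete": False,
        "stages": {},
        "files": [],
    }
    manifest_path = out / "manifest.json"

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {"status": "ok", "files": [f.name for f in files]}
        manifest["files"].extend(f.name for f in files)
        manifest_path.write_text(json.dumps(manifest, indent=2))

    def fail(stage: str, exc: Exception) -> "StageError":
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return StageError(f"stage {stage!r} failed: {exc}")

    (out / "config.yaml").write_text(yaml.safe_dump(cfg_map, sort_keys=True))
    manifest["files"].append("config.yaml")

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            cohort_cfg = CohortConfig(
                n_patients=config.n_patients,
                seed=_derive_seed(config.seed, stage),
                age_range=(float(config.horizon.start_age), float(config.horizon.last_decision_age)),
            )
            cohort = generate_cohort(cohort_cfg)
            traj_path = out / "trajectories.csv"
            write_trajectories(cohort.trajectories, traj_path)
            outcomes_path = out / "outcomes.csv"
            cohort.outcomes.to_csv(outcomes_path, index=False)
            truth_path = out / "true_kernel.csv"
            write_kernel(cohort_cfg.true_kernel, truth_path)
            record(stage, [traj_path, outcomes_path, truth_path])
            trajectories = cohort.trajectories
        else:
            manifest["stages"][stage] = {"status": "skipped"}
            trajectories = None
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise fail(stage, exc) from exc

    # --- estimate-transitions -----------------------------------------
    stage = "estimate-transitions"
    try:
        if trajectories is not None:
            kernel = estimate_kernel(trajectories)
        else:
            kernel = read_kernel(config.kernel_path)
        kernel_path = out / "kernel.csv"
        support_path = out / "kernel_support.csv"
        write_kernel(kernel, kernel_path, support_path)
        record(stage, [kernel_path, support_path])
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc) from exc

    # --- solve ---------------------------------------------------------
    stage = "solve"
    try:
        base = default_base_rewards()
        for name, value in config.base_case.items():
            base = base.with_parameter(name, value)
        from .model_core import build_instance

        mdp = build_instance(kernel, base, config.horizon)
        vf, policy = backward_induction(mdp)
        curve = extract_threshold(policy)
        policy_path = out / "policy.csv"
        value_path = out / "value.csv"
        curve_path = out / "threshold_curve.csv"
        write_policy(policy, policy_path)
        write_value(vf, value_path)
        write_threshold_curve(curve, curve_path)
        record(stage, [policy_path, value_path, curve_path])
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc) from exc

    # --- sweep ---------------------------------------------------------
    stage = "sweep"
    try:
        sweep_files: list[Path] = []
        for name, values in config.sweeps.items():
            spec = SweepSpec(parameter=name, values=list(values), base=base)
            result = one_way_sweep(spec, kernel, config.horizon)
            sweep_files.extend(write_sweep(result, out / "sweeps"))
        record(stage, sweep_files)
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc) from exc

    # --- report --------------------------------------------------------
    stage = "report"
    try:
        report_path = out / "report.md"
        report_path.write_text(render_report(curve, manifest["config_hash"], config.seed))
        record(stage, [report_path])
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc) from exc

    manifest["complete"] = True
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def render_report(curve: ThresholdCurve, cfg_hash: str, seed: int) -> str:
    """Markdown summary of biopsy thresholds by age band (<42, 42-75, >75)."""
    lines = [
        "# Optimal biopsy threshold report",
        "",
        f"config hash: `{cfg_hash}`  seed: {seed}",
        "",
        "| age band | min threshold (%) | max threshold (%) |",
        "|---|---|---|",
    ]
    for lo, hi in REPORT_BANDS:
        lo_a = int(curve.ages[0]) if lo is None else lo
        hi_a = int(curve.ages[-1]) if hi is None else hi
        mask = (curve.ages >= lo_a) & (curve.ages <= hi_a)
        label = f"{'<' + str(hi + 1) if lo is None else ''}"
        if lo is not None and hi is not None:
            label = f"{lo}-{hi}"
        elif lo is not None:
            label = f">{lo - 1}"
        if not mask.any():
            lines.append(f"| {label} | - | - |")
            continue
        t = curve.threshold[mask]
        lines.append(f"| {label} | {int(t.min())} | {int(t.max())} |")
    non_cl = curve.non_control_ages
    lines += [
        "",
        f"ages without control-limit structure: {non_cl if non_cl else 'none'}",
        "(threshold 101 denotes ages where biopsy is never optimal)",
        "",
    ]
    return "\n".join(lines)
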
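"""Base-case solve and one-way sensitivity sweeps over the headline parameters.

The four swept variables and their admissible ranges mirror the model's
sensitivity-analysis table: biopsy disutility at age 40 (0-3 weeks, base 2),
the disutility multiplication factor at age 100 (0.5-4, base 2), the
invasive fraction of detected cancers (0.65-0.85, base 0.75), and the
treatment effectiveness factor (1.2-2, base 1.6).  Sweeps vary exactly one
parameter while the others stay at base case; each setting is solved to a
threshold curve.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import Horizon, build_instance
from .rewards import BASE_CASE, SENSITIVITY_RANGES, RewardSpec
from .solver import ThresholdCurve, backward_induction, extract_threshold, write_threshold_curve
from .transitions import TransitionKernel

#: canonical sweep parameter names (aliases accepted by RewardSpec.with_parameter)
SWEEP_PARAMETERS = ("d40", "disutility_factor", "pct_invasive", "tau")


@dataclass
class SweepSpec:
    """One-way sweep over a single parameter, anchored at a base RewardSpec."""

    parameter: str
    values: list[float]
    base: RewardSpec

    def __post_init__(self) -> None:
        name = "disutility_factor" if self.parameter == "factor" else self.parameter
        if name not in SWEEP_PARAMETERS:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")
        self.parameter = name
        if not self.values:
            raise ValueError("sweep values must be nonempty")
        lo, hi = SENSITIVITY_RANGES[name]
        for v in self.values:
            if not math.isfinite(v):
                raise ValueError(f"non-finite sweep value {v!r}")
            if v < 0 and name in ("d40", "pct_invasive"):
                raise ValueError(f"{name} cannot be negative (got {v})")
            if name == "pct_invasive" and v > 1:
                raise ValueError("pct_invasive cannot exceed 1")
            if name == "tau" and v <= 0:
                raise ValueError("tau must be positive")
            if not lo <= v <= hi:
                warnings.warn(
                    f"sweep value {v} for {name} is outside the declared "
                    f"range [{lo}, {hi}]; proceeding",
                    stacklevel=2,
                )


@dataclass
class SweepResult:
    """Threshold curves per sweep setting; the base case is always included."""

    parameter: str
    values: list[float]
    curves: list[ThresholdCurve]
    base_value: float
    base_curve: ThresholdCurve

    def curve_for(self, value: float) -> ThresholdCurve:
        for v, c in zip(self.values, self.curves):
            if v == value:
                return c
        raise KeyError(f"no curve for {self.parameter}={value}")


def solve_threshold(
    kernel: TransitionKernel, rewards: RewardSpec, horizon: Horizon | None = None
) -> ThresholdCurve:
    """Build, solve, and reduce one instance to its threshold curve."""
    mdp = build_instance(kernel, rewards, horizon)
    _, policy = backward_induction(mdp)
    return extract_threshold(policy)


def run_base_case(
    kernel: TransitionKernel,
    base: RewardSpec | None = None,
    horizon: Horizon | None = None,
) -> ThresholdCurve:
    """Solve the base case (d40=2 weeks, factor=2, pct_invasive=0.75, tau=1.6).

    If ``base`` is omitted the shipped synthetic fixture tables are used
    with the base-case parameters.
    """
    if base is None:
        base = default_base_rewards()
    for name in SWEEP_PARAMETERS:
        base = base.with_parameter(name, BASE_CASE[name])
    return solve_threshold(kernel, base, horizon)


def default_base_rewards() -> RewardSpec:
    """Base-case RewardSpec on the shipped synthetic fixture tables."""
    from .rewards import DisutilitySchedule, TreatmentEffect
    from .synthetic_data import load_fixture_tables

    mortality, lump, terminal = load_fixture_tables()
    lump.pct_invasive = BASE_CASE["pct_invasive"]
    return RewardSpec(
        disutility=DisutilitySchedule(BASE_CASE["d40"], BASE_CASE["disutility_factor"]),
        mortality=mortality,
        effect=TreatmentEffect(BASE_CASE["tau"]),
        lump=lump,
        terminal_reward=terminal,
    )


def one_way_sweep(
    spec: SweepSpec,
    kernel: TransitionKernel,
    horizon: Horizon | None = None,
) -> SweepResult:
    """Solve once per sweep value, all other parameters held at the anchor.

    Curves are returned in the order of ``spec.values``; the base-case
    curve (the anchor RewardSpec's own value of the swept parameter) is
    computed alongside for reference.
    """
    curves = [
        solve_threshold(kernel, spec.base.with_parameter(spec.parameter, v), horizon)
        for v in spec.values
    ]
    base_value = spec.base.scalar_parameters()[spec.parameter]
    base_curve = solve_threshold(kernel, spec.base, horizon)
    return SweepResult(spec.parameter, list(spec.values), curves, base_value, base_curve)


def write_sweep(result: SweepResult, out_dir: str | os.PathLike) -> list[Path]:
    """Write one ``threshold_curve_<param>_<value>.csv`` per setting plus a
    combined long-format table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    long_rows = []
    for v, curve in zip(result.values, result.curves):
        path = out_dir / f"threshold_curve_{result.parameter}_{v:g}.csv"
        write_threshold_curve(curve, path)
        written.append(path)
        long_rows.append(
            pd.DataFrame(
                {
                    "parameter": result.parameter,
                    "value": v,
                    "age": curve.ages,
                    "threshold": curve.threshold,
                    "control_limit_flag": curve.control_limit.astype(int),
                }
            )
        )
    combined = out_dir / f"sweep_{result.parameter}.csv"
    pd.concat(long_rows, ignore_index=True).to_csv(combined, index=False)
    written.append(combined)
    return written
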
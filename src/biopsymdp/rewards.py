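"""QALY rewards: annual survival rewards, biopsy disutility, and lump sums.

Rewards are measured in quality-adjusted life years.  A year in a
risk-score state is worth 1 QALY if the patient survives it and 1/2 QALY if
she dies during it (half-cycle correction).  Biopsy carries a time penalty
(disutility) in weeks that grows linearly with age.  A malignant biopsy
grants a lump sum equal to the expected post-treatment remaining life,
mixing invasive and in-situ (DCIS) prognoses.  Only the biopsy disutility
is modelled; disease-, treatment- and age-related quality weights are
deliberately excluded so the trade-off between biopsy harm and life-year
gain is isolated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model_core import Horizon

WEEKS_PER_YEAR = 52.0

#: Table of base-case values and one-way sensitivity ranges
BASE_CASE = {"d40": 2.0, "disutility_factor": 2.0, "pct_invasive": 0.75, "tau": 1.6}
SENSITIVITY_RANGES = {
    "d40": (0.0, 3.0),
    "disutility_factor": (0.5, 4.0),
    "pct_invasive": (0.65, 0.85),
    "tau": (1.2, 2.0),
}


@dataclass(frozen=True)
class DisutilitySchedule:
    """Biopsy time penalty: ``d40`` weeks at age 40, rising (or falling)
    linearly to ``factor * d40`` weeks at age 100."""

    d40: float = BASE_CASE["d40"]
    factor: float = BASE_CASE["disutility_factor"]

    def __post_init__(self) -> None:
        if self.d40 < 0:
            raise ValueError("d40 must be nonnegative")
        if not self.factor > 0:
            raise ValueError("disutility factor must be positive")


def disutility_at(age: int, sched: DisutilitySchedule) -> float:
    """Biopsy disutility at ``age``, in years.

    Linear in age between the anchors (d40 weeks at 40, factor*d40 weeks at
    100); converted to years at 52 weeks/year.
    """
    if not 40 <= age <= 100:
        raise ValueError(f"disutility schedule defined on ages 40..100, got {age}")
    weeks = sched.d40 + (sched.factor * sched.d40 - sched.d40) * (age - 40) / 60.0
    return weeks / WEEKS_PER_YEAR


class AgeTable:
    """An ``age -> value`` lookup backed by a dense array; strict on coverage."""

    def __init__(self, ages: np.ndarray, values: np.ndarray, name: str = "table"):
        ages = np.asarray(ages, dtype=int)
        values = np.asarray(values, dtype=float)
        if ages.ndim != 1 or ages.shape != values.shape:
            raise ValueError(f"{name}: ages and values must be 1-d and equal length")
        order = np.argsort(ages)
        ages, values = ages[order], values[order]
        if np.any(np.diff(ages) != 1):
            raise ValueError(f"{name}: ages must be consecutive integers")
        self.name = name
        self.min_age = int(ages[0])
        self.max_age = int(ages[-1])
        self._values = values

    def __call__(self, age: int) -> float:
        if not self.min_age <= age <= self.max_age:
            raise KeyError(f"{self.name}: age {age} outside {self.min_age}..{self.max_age}")
        return float(self._values[int(age) - self.min_age])

    def array(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=int)
        if ages.min() < self.min_age or ages.max() > self.max_age:
            raise KeyError(f"{self.name}: requested ages outside coverage")
        return self._values[ages - self.min_age]

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.min_age, self.max_age + 1)

    @property
    def values(self) -> np.ndarray:
        return self._values.copy()


@dataclass
class MortalityTables:
    """Annual death probabilities: all-(other-)cause, and breast-cancer under
    treatment."""

    other_cause: AgeTable
    treated_bc: AgeTable

    def __post_init__(self) -> None:
        for t in (self.other_cause, self.treated_bc):
            if np.any((t.values < 0) | (t.values > 1)):
                raise ValueError(f"{t.name}: probabilities outside [0, 1]")


@dataclass(frozen=True)
class TreatmentEffect:
    """Ratio of untreated to treated annual breast-cancer mortality.

    tau > 1 means treatment lowers mortality; base case 1.6.
    """

    tau: float = BASE_CASE["tau"]

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("treatment effect factor must be positive")


@dataclass
class LumpSumTables:
    """Expected post-treatment remaining life (years) by age at diagnosis,
    separately for invasive disease and DCIS, mixed by ``pct_invasive``."""

    invasive_expected_life: AgeTable
    dcis_expected_life: AgeTable
    pct_invasive: float = BASE_CASE["pct_invasive"]

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_invasive <= 1.0:
            raise ValueError("pct_invasive must be in [0, 1]")
        for t in (self.invasive_expected_life, self.dcis_expected_life):
            if np.any(t.values < 0):
                raise ValueError(f"{t.name}: expected life must be nonnegative")
            if np.any(np.diff(t.values) > 1e-9):
                raise ValueError(f"{t.name}: expected life must be non-increasing in age")


@dataclass
class RewardSpec:
    """All reward inputs for one solve."""

    disutility: DisutilitySchedule
    mortality: MortalityTables
    effect: TreatmentEffect
    lump: LumpSumTables
    terminal_reward: float
    #: whether the biopsy time penalty is also charged on the malignant branch
    disutility_on_malignant: bool = True

    def __post_init__(self) -> None:
        if self.terminal_reward < 0:
            raise ValueError("terminal reward must be nonnegative")

    def check_age_coverage(self, horizon: Horizon) -> None:
        ages = np.arange(horizon.start_age, horizon.last_decision_age + 1)
        for t in (
            self.mortality.other_cause,
            self.mortality.treated_bc,
            self.lump.invasive_expected_life,
            self.lump.dcis_expected_life,
        ):
            if t.min_age > ages[0] or t.max_age < ages[-1]:
                raise ValueError(
                    f"table {t.name} covers {t.min_age}..{t.max_age}, "
                    f"horizon needs {ages[0]}..{ages[-1]}"
                )

    def scalar_parameters(self) -> dict:
        return {
            "d40": float(self.disutility.d40),
            "disutility_factor": float(self.disutility.factor),
            "pct_invasive": float(self.lump.pct_invasive),
            "tau": float(self.effect.tau),
            "terminal_reward": float(self.terminal_reward),
            "disutility_on_malignant": bool(self.disutility_on_malignant),
        }

    def with_parameter(self, name: str, value: float) -> "RewardSpec":
        """A copy with one of the four headline parameters replaced."""
        if name == "d40":
            return replace(self, disutility=DisutilitySchedule(value, self.disutility.factor))
        if name in ("factor", "disutility_factor"):
            return replace(self, disutility=DisutilitySchedule(self.disutility.d40, value))
        if name == "pct_invasive":
            return replace(self, lump=replace(self.lump, pct_invasive=value))
        if name == "tau":
            return replace(self, effect=TreatmentEffect(value))
        raise KeyError(f"unknown sweep parameter {name!r}")


def untreated_bc_mortality(age: int, tables: MortalityTables, effect: TreatmentEffect) -> float:
    """Annual breast-cancer death probability without treatment: tau times the
    treated probability, capped at 1."""
    return min(1.0, effect.tau * tables.treated_bc(age))


def annual_death_prob(
    age: int,
    risk_score: int,
    tables: MortalityTables,
    effect: TreatmentEffect,
    lethal_fraction: float = 1.0,
) -> float:
    """Annual death probability in a risk-score state under annual mammography.

    The breast-cancer hazard is the risk-weighted untreated mortality
    (risk_score/100 × tau × treated mortality); it combines with other-cause
    mortality as independent competing risks:

        p = 1 − (1 − p_other) (1 − f · (s/100) · min(1, tau · p_treated))

    ``lethal_fraction`` f is the share of prospective cancers lethal while
    undetected.  The solver passes the invasive fraction here: in-situ
    disease does not threaten life within the year it goes undiagnosed, so
    only the invasive share of the risk carries untreated mortality.
    """
    if not 0 <= risk_score <= 100:
        raise ValueError(f"risk score {risk_score} outside 0..100")
    if not 0.0 <= lethal_fraction <= 1.0:
        raise ValueError(f"lethal_fraction {lethal_fraction!r} outside [0, 1]")
    p_o = tables.other_cause(age)
    m_u = untreated_bc_mortality(age, tables, effect)
    return 1.0 - (1.0 - p_o) * (1.0 - lethal_fraction * (risk_score / 100.0) * m_u)


def intermediate_reward(p_death: float) -> float:
    """One-year QALY reward with half-cycle correction: a full year if the
    patient survives, half a year if she dies during it."""
    if not 0.0 <= p_death <= 1.0:
        raise ValueError(f"death probability {p_death!r} outside [0, 1]")
    return (1.0 - p_death) * 1.0 + p_death * 0.5


def benign_biopsy_reward(age: int, other_cause_p: float, sched: DisutilitySchedule) -> float:
    """QALY reward for the year following a benign biopsy.

    Biopsy is assumed perfect, so the patient is cancer-free that year and
    faces only other-cause mortality; the biopsy time penalty is subtracted.
    """
    if not 40 <= age <= 99:
        raise ValueError(f"benign biopsy reward defined for decision ages 40..99, got {age}")
    return intermediate_reward(other_cause_p) - disutility_at(age, sched)


def lump_sum(age: int, lump: LumpSumTables) -> float:
    """Expected post-treatment remaining life on a malignant biopsy at ``age``:
    a pct_invasive mix of the invasive and DCIS prognoses."""
    return (
        lump.pct_invasive * lump.invasive_expected_life(age)
        + (1.0 - lump.pct_invasive) * lump.dcis_expected_life(age)
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O for the age tables
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "other_cause": "other_cause_mortality.csv",
    "treated_bc": "treated_bc_mortality.csv",
    "invasive": "invasive_expected_life.csv",
    "dcis": "dcis_expected_life.csv",
}


def read_age_table(path: str | os.PathLike, name: str | None = None) -> AgeTable:
    """Read an ``age,value`` delimited table."""
    df = pd.read_csv(path)
    if not {"age", "value"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns age,value")
    return AgeTable(df["age"].to_numpy(), df["value"].to_numpy(), name or Path(path).stem)


def write_age_table(table: AgeTable, path: str | os.PathLike) -> None:
    pd.DataFrame({"age": table.ages, "value": table.values}).to_csv(
        path, index=False, float_format="%.12g"
    )


def write_reward_tables(spec: RewardSpec, directory: str | os.PathLike) -> dict[str, Path]:
    directory = Path(directory)
    tables = {
        "other_cause": spec.mortality.other_cause,
        "treated_bc": spec.mortality.treated_bc,
        "invasive": spec.lump.invasive_expected_life,
        "dcis": spec.lump.dcis_expected_life,
    }
    paths = {}
    for key, table in tables.items():
        p = directory / _TABLE_FILES[key]
        write_age_table(table, p)
        paths[key] = p
    return paths


def read_reward_spec(table_paths: Mapping[str, os.PathLike], params: Mapping) -> RewardSpec:
    """Assemble a RewardSpec from table files and a scalar-parameter mapping."""
    mortality = MortalityTables(
        other_cause=read_age_table(table_paths["other_cause"], "other_cause"),
        treated_bc=read_age_table(table_paths["treated_bc"], "treated_bc"),
    )
    lump = LumpSumTables(
        invasive_expected_life=read_age_table(table_paths["invasive"], "invasive"),
        dcis_expected_life=read_age_table(table_paths["dcis"], "dcis"),
        pct_invasive=float(params.get("pct_invasive", BASE_CASE["pct_invasive"])),
    )
    return RewardSpec(
        disutility=DisutilitySchedule(
            d40=float(params.get("d40", BASE_CASE["d40"])),
            factor=float(params.get("disutility_factor", BASE_CASE["disutility_factor"])),
        ),
        mortality=mortality,
        effect=TreatmentEffect(float(params.get("tau", BASE_CASE["tau"]))),
        lump=lump,
        terminal_reward=float(params["terminal_reward"]),
        disutility_on_malignant=bool(params.get("disutility_on_malignant", True)),
    )
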
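"""Synthetic mammography cohort and parameter-table fixtures.

The clinical dataset behind the model (tens of thousands of exams with
registry-matched outcomes) is not publicly available, so this module
generates cohorts with the same statistical shape: entry ages roughly
Normal(56.5, 12.7) clipped to the model horizon, mostly-low risk scores
evolving by a known ground-truth annual kernel, exam gaps of 2-3 years to
exercise interpolation, single-exam patients to exercise the exclusion
rule, and per-exam cancer outcomes calibrated to about 9.7 per 1000 exams.
Because the generating kernel is known, kernel estimation can be tested
for parameter recovery end to end.

Also provides synthetic stand-ins, shaped like US life tables and
SEER-style post-diagnosis survival, for the mortality and lump-sum tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model_core import N_RISK_STATES, Horizon
from .rewards import AgeTable, LumpSumTables, MortalityTables
from .transitions import TransitionKernel, Trajectory, read_kernel

# ---------------------------------------------------------------------------
# Ground-truth kernel
# ---------------------------------------------------------------------------

#: local drift weights: offset -> probability mass before normalization
_DRIFT_OFFSETS = {-2: 0.04, -1: 0.12, 0: 0.52, 1: 0.18, 2: 0.08, 3: 0.03}


def default_true_kernel() -> TransitionKernel:
    """The versioned ground-truth annual kernel used by the shipped fixtures.

    Each score mostly persists or drifts up a little; an upward jump of ten
    points has probability growing with the current score, giving higher
    scores a heavier upward tail.  Mass falling off the 0..100 grid
    accumulates at the boundary.
    """
    n = N_RISK_STATES
    matrix = np.zeros((n, n))
    for s in range(n):
        row = np.zeros(n)
        for off, w in _DRIFT_OFFSETS.items():
            row[min(max(s + off, 0), n - 1)] += w
        jump = 0.02 + 0.0008 * s
        row[min(s + 10, n - 1)] += jump
        matrix[s] = row / row.sum()
    return TransitionKernel(matrix=matrix, support_counts=None)


def default_baseline_score_distribution() -> np.ndarray:
    """Baseline risk-score weights: geometric decay, heavily below 5."""
    w = np.zeros(N_RISK_STATES)
    s = np.arange(31)
    w[:31] = 0.45 ** s * 0.55
    return w / w.sum()


#: observed exams per patient; mass at 1 exercises the exclusion rule,
#: mean about 2.7 exams/patient as in a mixed screening/diagnostic practice
DEFAULT_EXAMS_PER_PATIENT = {1: 0.25, 2: 0.25, 3: 0.20, 4: 0.15, 5: 0.08, 6: 0.05, 7: 0.02}


@dataclass
class CohortConfig:
    """Generation parameters; defaults emulate the reference clinical cohort
    (mean entry age 56.5, SD 12.7, cancer detection near 9.7/1000 exams)."""

    n_patients: int = 10_000
    seed: int = 0
    entry_age_mean: float = 56.5
    entry_age_sd: float = 12.7
    age_range: tuple[float, float] = (40.0, 99.0)
    baseline_score_distribution: np.ndarray = field(
        default_factory=default_baseline_score_distribution
    )
    true_kernel: TransitionKernel = field(default_factory=default_true_kernel)
    exams_per_patient_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_EXAMS_PER_PATIENT)
    )
    gap_probability: float = 0.25
    cancer_rate_per_exam: float = 0.0097

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        w = np.asarray(self.baseline_score_distribution, dtype=float)
        if w.shape != (N_RISK_STATES,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("baseline_score_distribution must be a distribution over 0..100")
        counts = np.array(list(self.exams_per_patient_distribution.keys()))
        probs = np.array(list(self.exams_per_patient_distribution.values()))
        if np.any(counts < 1) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("exams_per_patient_distribution must be a distribution over counts >= 1")
        if not 0.0 <= self.gap_probability <= 1.0:
            raise ValueError("gap_probability must be in [0, 1]")
        if not 0.0 <= self.cancer_rate_per_exam <= 1.0:
            raise ValueError("cancer_rate_per_exam must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """Generated trajectories, per-exam outcomes, and the generating truth."""

    trajectories: list[Trajectory]
    outcomes: pd.DataFrame  # finding_id, age, risk_score, cancer
    ground_truth: CohortConfig


def _calibrate_outcome_scale(scores: np.ndarray, target: float) -> float:
    """Solve mean(min(c * s/100, 1)) = target for c by bisection.

    Cancer probability is proportional to the current risk score (capped at
    1), so the marginal detection rate can be matched exactly.
    """
    if target == 0:
        return 0.0
    frac = scores / 100.0
    achievable = float(np.mean(frac > 0))
    if target > achievable:
        raise ValueError(
            f"target cancer rate {target} exceeds achievable maximum {achievable:.4f} "
            "given the realized score distribution"
        )
    lo, hi = 0.0, 1.0
    while np.mean(np.minimum(hi * frac, 1.0)) < target:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - guarded by the achievable check
            raise ValueError("cancer-rate calibration failed to bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(np.minimum(mid * frac, 1.0)) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort.

    Per patient: entry age from the clipped normal; baseline score from the
    baseline distribution; annual score evolution by the ground-truth
    kernel; exams thinned to 2-3 year gaps with probability
    ``gap_probability``; per-exam cancer outcomes with probability
    proportional to the current score, scaled so the marginal rate matches
    ``cancer_rate_per_exam``.  Identical configs and seeds give identical
    cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    lo, hi = config.age_range

    entry = np.clip(rng.normal(config.entry_age_mean, config.entry_age_sd, n), lo, hi)
    counts = np.array(sorted(config.exams_per_patient_distribution))
    probs = np.array([config.exams_per_patient_distribution[c] for c in counts])
    n_exams = rng.choice(counts, size=n, p=probs)

    max_gaps = int(n_exams.max()) - 1
    # interval between consecutive exams: 1 year, or 2-3 with gap_probability
    if max_gaps > 0:
        gapped = rng.random((n, max_gaps)) < config.gap_probability
        width = rng.integers(2, 4, size=(n, max_gaps))
        intervals = np.where(gapped, width, 1)
    else:
        intervals = np.zeros((n, 0), dtype=int)

    # annual latent score paths, long enough for the widest exam schedule
    max_years = int(intervals.sum(axis=1).max(initial=0))
    paths = np.empty((n, max_years + 1), dtype=np.int64)
    paths[:, 0] = rng.choice(N_RISK_STATES, size=n, p=config.baseline_score_distribution)
    cum = np.cumsum(config.true_kernel.matrix, axis=1)
    for year in range(max_years):
        cur = paths[:, year]
        u = rng.random(n)
        nxt = np.empty(n, dtype=np.int64)
        for s in np.unique(cur):
            mask = cur == s
            nxt[mask] = np.searchsorted(cum[s], u[mask], side="right")
        paths[:, year + 1] = np.minimum(nxt, N_RISK_STATES - 1)

    trajectories: list[Trajectory] = []
    all_scores: list[np.ndarray] = []
    rows_fid: list[str] = []
    rows_age: list[float] = []
    for i in range(n):
        offsets = np.concatenate([[0], np.cumsum(intervals[i, : n_exams[i] - 1])])
        ages = entry[i] + offsets
        keep = ages <= hi
        keep[0] = True  # entry exam always observed
        offsets, ages = offsets[keep], ages[keep]
        scores = paths[i, offsets]
        fid = f"F{i:06d}"
        trajectories.append(Trajectory(fid, ages, scores))
        all_scores.append(scores)
        rows_fid.extend([fid] * len(ages))
        rows_age.extend(ages.tolist())

    exam_scores = np.concatenate(all_scores)
    scale = _calibrate_outcome_scale(exam_scores, config.cancer_rate_per_exam)
    p_cancer = np.minimum(scale * exam_scores / 100.0, 1.0)
    cancer = (rng.random(len(exam_scores)) < p_cancer).astype(int)
    outcomes = pd.DataFrame(
        {
            "finding_id": rows_fid,
            "age": rows_age,
            "risk_score": exam_scores,
            "cancer": cancer,
        }
    )
    return SyntheticCohort(trajectories=trajectories, outcomes=outcomes, ground_truth=config)


# ---------------------------------------------------------------------------
# Fixture parameter tables (synthetic stand-ins for US life tables and
# SEER-style survival)
# ---------------------------------------------------------------------------

_MAX_AGE = 120  # hazard extended beyond the horizon for life expectancies
_GOMPERTZ_A = 6.366e-5  # other-cause hazard level: ~0.002 at 40
_GOMPERTZ_B = 0.0861  # doubling every ~8 years; ~0.35 at 100


def _other_cause_hazard(ages: np.ndarray) -> np.ndarray:
    return np.minimum(_GOMPERTZ_A * np.exp(_GOMPERTZ_B * ages), 1.0)


def _treated_bc_hazard(ages: np.ndarray) -> np.ndarray:
    # annual breast-cancer mortality under treatment around diagnosis, rising
    # mildly with age; scaled up by tau it gives the hazard of leaving an
    # invasive cancer undetected for a year
    return 0.12 + 0.001 * (ages - 40.0)


# post-treatment excess annual hazards behind the lump-sum life expectancies:
# treated invasive survivors retain a small excess; DCIS prognosis is close
# to the cancer-free life table
_EXCESS_INVASIVE = 0.01
_EXCESS_DCIS = 0.001


def _life_expectancy(q: np.ndarray) -> float:
    """Discrete remaining life expectancy from a vector of annual death
    probabilities, with a half-year credit for the year of death."""
    surv = np.cumprod(1.0 - q)
    return 0.5 + float(surv[:-1].sum()) + 0.5 * float(surv[-1])


def make_fixture_tables(horizon: Horizon) -> tuple[MortalityTables, LumpSumTables, float]:
    """Build synthetic, smooth, monotone parameter tables for the horizon.

    Returns mortality tables, lump-sum tables (DCIS prognosis dominating
    invasive at every age, both non-increasing), and the terminal reward —
    the all-cause expected remaining life at the terminal age.
    """
    ages = np.arange(horizon.start_age, horizon.terminal_age + 1)
    q_other = _other_cause_hazard(ages)
    q_treated = _treated_bc_hazard(ages)

    def remaining_life(age: int, excess: float) -> float:
        future = np.arange(age, _MAX_AGE)
        q = 1.0 - (1.0 - _other_cause_hazard(future)) * (1.0 - excess)
        return _life_expectancy(np.minimum(q, 1.0))

    invasive = np.array([remaining_life(a, _EXCESS_INVASIVE) for a in ages])
    dcis = np.array([remaining_life(a, _EXCESS_DCIS) for a in ages])

    mortality = MortalityTables(
        other_cause=AgeTable(ages, q_other, "other_cause"),
        treated_bc=AgeTable(ages, q_treated, "treated_bc"),
    )
    lump = LumpSumTables(
        invasive_expected_life=AgeTable(ages, invasive, "invasive"),
        dcis_expected_life=AgeTable(ages, dcis, "dcis"),
    )
    terminal_reward = remaining_life(horizon.terminal_age, 0.0)
    return mortality, lump, terminal_reward


# ---------------------------------------------------------------------------
# Shipped fixture files
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("biopsymdp") / "data" / name


def load_base_kernel() -> TransitionKernel:
    """The shipped (versioned) ground-truth kernel fixture."""
    return read_kernel(_data_path("base_kernel.csv"))


def load_fixture_tables() -> tuple[MortalityTables, LumpSumTables, float]:
    """Shipped synthetic parameter tables (written by scripts/make_fixtures.py)."""
    from .rewards import read_age_table

    mortality = MortalityTables(
        other_cause=read_age_table(_data_path("other_cause_mortality.csv"), "other_cause"),
        treated_bc=read_age_table(_data_path("treated_bc_mortality.csv"), "treated_bc"),
    )
    lump = LumpSumTables(
        invasive_expected_life=read_age_table(_data_path("invasive_expected_life.csv"), "invasive"),
        dcis_expected_life=read_age_table(_data_path("dcis_expected_life.csv"), "dcis"),
    )
    terminal = float(
        pd.read_csv(_data_path("terminal_reward.csv"))["value"].iloc[0]
    )
    return mortality, lump, terminal
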
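"""Backward-induction solution of the finite-horizon biopsy decision process.

For each decision age a (from the last decision age down to the start age)
and each risk-score state s, the Bellman recursion compares

    V_AM(a, s) = r(p) + (1 - p) * sum_s' K(s'|s) V(a+1, s')
    V_BX(a, s) = (s/100) (L(a) - d_M(a))
               + (1 - s/100) [ r_B(a) + (1 - p_o(a)) * sum_s' K(s'|s) V(a+1, s') ]

where p is the annual death probability under mammography (other-cause plus
risk-weighted untreated breast-cancer mortality), r the half-cycle-corrected
one-year reward, L the post-diagnosis lump sum, d_M the biopsy disutility
charged on the malignant branch (switchable), r_B the benign-biopsy-year
reward, and p_o the other-cause death probability (a benign biopsy leaves
the patient cancer-free for the year).  Death preempts the risk-score
transition, so the continuation is weighted by the survival probability.
Ties go to mammography, making the reported threshold the smallest risk at
which biopsy is strictly better.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import Action, MdpInstance
from .rewards import (
    annual_death_prob,
    benign_biopsy_reward,
    disutility_at,
    intermediate_reward,
    lump_sum,
)

#: value gap below which the two actions are considered tied (AM wins ties)
TIE_TOL = 1e-12

#: threshold sentinel when biopsy is never optimal at an age
NO_BIOPSY = 101


@dataclass
class ValueFunction:
    """Expected QALYs-to-go, indexed by age and risk score.

    ``values[i, s]`` is the value at ``ages[i]`` in risk-score state ``s``;
    the last row is the terminal age, where every alive state receives the
    terminal reward.  The death state has value 0 at every age.
    """

    ages: np.ndarray  # start_age .. terminal_age inclusive
    values: np.ndarray  # (n_ages, n_scores)

    def value(self, age: int, state: int | str) -> float:
        if isinstance(state, str):
            if state == "Death":
                return 0.0
            raise KeyError(f"no per-age value stored for state {state!r}")
        i = int(age) - int(self.ages[0])
        if not 0 <= i < len(self.ages):
            raise KeyError(f"age {age} outside {self.ages[0]}..{self.ages[-1]}")
        return float(self.values[i, state])


@dataclass
class PolicyTable:
    """Optimal (or candidate) action per (decision age, risk score)."""

    ages: np.ndarray  # decision ages only
    is_biopsy: np.ndarray  # (n_decision_ages, n_scores) boolean

    def action(self, age: int, risk_score: int) -> Action:
        i = int(age) - int(self.ages[0])
        if not 0 <= i < len(self.ages):
            raise KeyError(f"age {age} is not a decision age")
        return Action.BX if self.is_biopsy[i, risk_score] else Action.AM


@dataclass
class ThresholdCurve:
    """Smallest risk score at which biopsy is optimal, per decision age.

    ``threshold[i] == NO_BIOPSY`` (101) flags ages where mammography is
    optimal everywhere.  ``control_limit[i]`` is True when the policy at
    that age recommends biopsy for *every* score at or above the threshold;
    ages violating that structure are listed in ``non_control_ages`` for
    diagnosis, never silently repaired.
    """

    ages: np.ndarray
    threshold: np.ndarray  # int, 0..101
    control_limit: np.ndarray  # bool

    @property
    def non_control_ages(self) -> list[int]:
        return [int(a) for a in self.ages[~self.control_limit]]

    def at(self, age: int) -> int:
        i = int(age) - int(self.ages[0])
        if not 0 <= i < len(self.ages):
            raise KeyError(f"age {age} outside curve")
        return int(self.threshold[i])


def solve_decision_problem(
    kernel: np.ndarray,
    r_am: np.ndarray,
    p_death: np.ndarray,
    lump_net: np.ndarray,
    r_benign: np.ndarray,
    p_other: np.ndarray,
    malignant_prob: np.ndarray,
    terminal: np.ndarray | float,
    discount: float = 1.0,
    policy: np.ndarray | None = None,
    tie_tol: float = TIE_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Generic finite-horizon core shared by the optimizer and the evaluator.

    Shapes: ``kernel`` (n, n) row-stochastic; ``r_am`` and ``p_death``
    (T, n); ``lump_net``, ``r_benign``, ``p_other`` (T,);
    ``malignant_prob`` (n,); ``terminal`` scalar or (n,).  ``policy``
    (T, n) boolean fixes the action at every epoch (no maximization) —
    used for policy evaluation and, in tests, for exhaustive enumeration.

    Returns ``(values, is_biopsy)`` of shapes (T+1, n) and (T, n).
    """
    kernel = np.asarray(kernel, dtype=float)
    r_am = np.atleast_2d(np.asarray(r_am, dtype=float))
    p_death = np.atleast_2d(np.asarray(p_death, dtype=float))
    T, n = r_am.shape
    lump_net = np.broadcast_to(np.asarray(lump_net, dtype=float), (T,))
    r_benign = np.broadcast_to(np.asarray(r_benign, dtype=float), (T,))
    p_other = np.broadcast_to(np.asarray(p_other, dtype=float), (T,))
    malignant_prob = np.asarray(malignant_prob, dtype=float)

    values = np.empty((T + 1, n))
    values[T] = terminal
    is_biopsy = np.zeros((T, n), dtype=bool)
    for e in range(T - 1, -1, -1):
        cont = kernel @ values[e + 1]  # E[V(a+1) | s], (n,)
        v_am = r_am[e] + discount * (1.0 - p_death[e]) * cont
        v_bx = malignant_prob * lump_net[e] + (1.0 - malignant_prob) * (
            r_benign[e] + discount * (1.0 - p_other[e]) * cont
        )
        if not (np.all(np.isfinite(v_am)) and np.all(np.isfinite(v_bx))):
            raise FloatingPointError(f"non-finite action values at epoch {e}")
        if policy is None:
            bx = v_bx > v_am + tie_tol  # ties go to AM
        else:
            bx = np.asarray(policy[e], dtype=bool)
        is_biopsy[e] = bx
        values[e] = np.where(bx, v_bx, v_am)
    return values, is_biopsy


def _instance_arrays(mdp: MdpInstance):
    """Evaluate the reward model on the instance's age/score grid."""
    h = mdp.horizon
    rw = mdp.rewards
    ages = np.array(h.decision_ages)
    n = len(mdp.state_space.risk_states)
    scores = np.arange(n)

    # only the invasive share of a prospective cancer is lethal while it
    # goes undiagnosed, so the mammography-year hazard is weighted by it
    p_death = np.array(
        [
            [
                annual_death_prob(
                    a, s, rw.mortality, rw.effect, lethal_fraction=rw.lump.pct_invasive
                )
                for s in scores
            ]
            for a in ages
        ]
    )
    r_am = (1.0 - p_death) + p_death * 0.5  # vectorized half-cycle reward
    p_other = np.array([rw.mortality.other_cause(a) for a in ages])
    d = np.array([disutility_at(a, rw.disutility) for a in ages])
    lump = np.array([lump_sum(a, rw.lump) for a in ages])
    lump_net = lump - d if rw.disutility_on_malignant else lump
    r_benign = np.array(
        [benign_biopsy_reward(a, p, rw.disutility) for a, p in zip(ages, p_other)]
    )
    malignant_prob = scores / 100.0
    return ages, r_am, p_death, lump_net, r_benign, p_other, malignant_prob


def backward_induction(
    mdp: MdpInstance, discount: float = 1.0
) -> tuple[ValueFunction, PolicyTable]:
    """Solve the instance for the QALY-maximizing policy.

    QALYs are summed undiscounted by default; ``discount`` (per-year factor
    on the continuation value) is exposed for exploration only.
    """
    ages, r_am, p_death, lump_net, r_benign, p_other, mal = _instance_arrays(mdp)
    values, is_biopsy = solve_decision_problem(
        mdp.kernel.matrix,
        r_am,
        p_death,
        lump_net,
        r_benign,
        p_other,
        mal,
        terminal=mdp.rewards.terminal_reward,
        discount=discount,
    )
    all_ages = np.append(ages, mdp.horizon.terminal_age)
    return ValueFunction(all_ages, values), PolicyTable(ages, is_biopsy)


def evaluate_policy(
    mdp: MdpInstance, policy: PolicyTable, discount: float = 1.0
) -> ValueFunction:
    """Expected QALYs-to-go under a fixed policy (no maximization)."""
    ages, r_am, p_death, lump_net, r_benign, p_other, mal = _instance_arrays(mdp)
    if policy.is_biopsy.shape != r_am.shape or int(policy.ages[0]) != int(ages[0]):
        raise ValueError("policy does not cover every (decision age, risk score)")
    values, _ = solve_decision_problem(
        mdp.kernel.matrix,
        r_am,
        p_death,
        lump_net,
        r_benign,
        p_other,
        mal,
        terminal=mdp.rewards.terminal_reward,
        discount=discount,
        policy=policy.is_biopsy,
    )
    all_ages = np.append(ages, mdp.horizon.terminal_age)
    return ValueFunction(all_ages, values)


def extract_threshold(policy: PolicyTable) -> ThresholdCurve:
    """Per-age smallest risk score with a biopsy recommendation.

    Also checks, per age, whether the policy has control-limit structure
    (biopsy for every score at or above the threshold); violations are
    reported, not repaired.
    """
    n_ages, n_scores = policy.is_biopsy.shape
    threshold = np.full(n_ages, NO_BIOPSY, dtype=int)
    control = np.ones(n_ages, dtype=bool)
    for i in range(n_ages):
        bx = policy.is_biopsy[i]
        idx = np.flatnonzero(bx)
        if idx.size:
            threshold[i] = idx[0]
            control[i] = bool(np.all(bx[idx[0]:]))
    return ThresholdCurve(policy.ages.copy(), threshold, control)


# ---------------------------------------------------------------------------
# Delimited-text outputs
# ---------------------------------------------------------------------------


def write_policy(policy: PolicyTable, path: str | os.PathLike) -> None:
    ages = np.repeat(policy.ages, policy.is_biopsy.shape[1])
    scores = np.tile(np.arange(policy.is_biopsy.shape[1]), len(policy.ages))
    actions = np.where(policy.is_biopsy.ravel(), Action.BX.value, Action.AM.value)
    pd.DataFrame({"age": ages, "risk_score": scores, "action": actions}).to_csv(
        path, index=False
    )


def write_value(vf: ValueFunction, path: str | os.PathLike) -> None:
    ages = np.repeat(vf.ages, vf.values.shape[1])
    scores = np.tile(np.arange(vf.values.shape[1]), len(vf.ages))
    pd.DataFrame({"age": ages, "state": scores, "qalys": vf.values.ravel()}).to_csv(
        path, index=False, float_format="%.12g"
    )


def write_threshold_curve(curve: ThresholdCurve, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "age": curve.ages,
            "threshold": curve.threshold,
            "control_limit_flag": curve.control_limit.astype(int),
        }
    ).to_csv(path, index=False)


def read_threshold_curve(path: str | os.PathLike) -> ThresholdCurve:
    df = pd.read_csv(path)
    return ThresholdCurve(
        df["age"].to_numpy(),
        df["threshold"].to_numpy(dtype=int),
        df["control_limit_flag"].to_numpy(dtype=bool),
    )
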
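"""Annual risk-score transition kernel estimated from longitudinal trajectories.

Each mammographic finding contributes a time-ordered sequence of
(age, risk score) observations.  Findings seen at more than one time point
are annualized — gaps longer than a year are filled by linear interpolation
of the score, assuming risk changes linearly with time — and every
consecutive annual pair (s_t, s_{t+1}) contributes one count to the
empirical transition matrix.  Findings with a single observation carry no
transition information and are excluded.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .model_core import N_RISK_STATES, ROW_SUM_TOL, round_half_up


@dataclass
class Trajectory:
    """One finding's time-ordered (age, risk score) observations."""

    finding_id: str
    ages: np.ndarray  # decimal years, strictly increasing
    scores: np.ndarray  # integers 0..100

    def __init__(self, finding_id, ages: Sequence[float], scores: Sequence[int]):
        self.finding_id = str(finding_id)
        self.ages = np.asarray(ages, dtype=float)
        self.scores = np.asarray(scores, dtype=int)
        if self.ages.ndim != 1 or self.ages.shape != self.scores.shape:
            raise ValueError("ages and scores must be 1-d and equal length")
        if len(self.ages) < 1:
            raise ValueError("trajectory needs at least one observation")
        diffs = np.diff(self.ages)
        if np.any(diffs == 0):
            raise ValueError(f"duplicate ages in trajectory {self.finding_id}")
        if np.any(diffs < 0):
            raise ValueError(f"ages not strictly increasing in trajectory {self.finding_id}")
        if np.any((self.scores < 0) | (self.scores > 100)):
            raise ValueError(f"risk scores outside 0..100 in trajectory {self.finding_id}")

    def __len__(self) -> int:
        return len(self.ages)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Trajectory)
            and self.finding_id == other.finding_id
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.scores, other.scores)
        )


@dataclass
class TransitionKernel:
    """Row-stochastic annual transition matrix over the 0..100 score grid.

    ``support_counts[s]`` is the number of observed (or imputed-by-
    interpolation) annual transitions out of score ``s``; rows with zero
    support were never observed and are flagged in :attr:`imputed_rows`.
    """

    matrix: np.ndarray
    support_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("kernel matrix must be square")
        if self.support_counts is not None:
            self.support_counts = np.asarray(self.support_counts, dtype=int)
            if self.support_counts.shape != (n,):
                raise ValueError("support_counts length must match matrix rows")
        self.validate()

    @property
    def n_scores(self) -> int:
        return self.matrix.shape[0]

    @property
    def imputed_rows(self) -> np.ndarray | None:
        """Boolean mask of rows imputed for lack of observed transitions."""
        if self.support_counts is None:
            return None
        return self.support_counts == 0

    def validate(self) -> None:
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"kernel row {bad} sums to {sums[bad]!r}, not 1")
        if np.any(self.matrix < -1e-15) or np.any(self.matrix > 1 + 1e-15):
            raise ValueError("kernel entries outside [0, 1]")


def annualize_trajectory(traj: Trajectory) -> Trajectory:
    """Resample a trajectory onto consecutive integer-year spacing.

    Gaps wider than one year are filled by linear interpolation of the risk
    score (risk is assumed to change linearly with time), rounded half-up to
    the integer grid.  The interpolation grid is anchored at the first
    observation, so observed points at whole-year offsets are preserved
    exactly.  Already-annual trajectories are returned unchanged.
    """
    if len(traj) < 2:
        return traj
    diffs = np.diff(traj.ages)
    if np.allclose(diffs, 1.0):
        return traj
    first = traj.ages[0]
    n_years = int(np.floor(traj.ages[-1] - first + 1e-9))
    grid = first + np.arange(n_years + 1)
    interp = np.interp(grid, traj.ages, traj.scores.astype(float))
    scores = np.array([round_half_up(v) for v in interp], dtype=int)
    # snap observed whole-year-offset points onto the grid exactly
    offsets = np.round(traj.ages - first).astype(int)
    on_grid = np.abs(traj.ages - first - offsets) < 1e-9
    scores[offsets[on_grid]] = traj.scores[on_grid]
    return Trajectory(traj.finding_id, grid, scores)


def estimate_kernel(
    trajectories: Iterable[Trajectory],
    mode: Literal["empirical", "mean-drift"] = "empirical",
) -> TransitionKernel:
    """Estimate the annual transition kernel from a trajectory corpus.

    Single-observation trajectories are excluded.  The rest are annualized;
    each consecutive annual pair adds one count to cell (from, to).  In
    ``empirical`` mode (default) each row is the observed next-score
    distribution; ``mean-drift`` mode instead puts all row mass on the
    rounded mean next score, collapsing the stochastic structure to the
    average one-year change.  Rows with no observed transitions are imputed
    as self-transitions and flagged via ``support_counts == 0``.

    Raises
    ------
    ValueError
        If no trajectory has more than one observation.
    """
    if mode not in ("empirical", "mean-drift"):
        raise ValueError(f"unknown estimation mode {mode!r}")
    froms: list[np.ndarray] = []
    tos: list[np.ndarray] = []
    n_multi = 0
    for traj in trajectories:
        if len(traj) < 2:
            continue  # single observations carry no transition information
        n_multi += 1
        ann = annualize_trajectory(traj)
        froms.append(ann.scores[:-1])
        tos.append(ann.scores[1:])
    if n_multi == 0:
        raise ValueError("no trajectory has more than one observation; kernel not estimable")
    f = np.concatenate(froms)
    t = np.concatenate(tos)
    counts = np.zeros((N_RISK_STATES, N_RISK_STATES), dtype=float)
    np.add.at(counts, (f, t), 1.0)
    support = counts.sum(axis=1)
    matrix = np.zeros_like(counts)
    observed = support > 0
    matrix[observed] = counts[observed] / support[observed, None]
    if mode == "mean-drift":
        drift = np.zeros_like(matrix)
        mean_next = (matrix[observed] * np.arange(N_RISK_STATES)).sum(axis=1)
        rows = np.where(observed)[0]
        cols = np.array([round_half_up(m) for m in mean_next], dtype=int)
        drift[rows, cols] = 1.0
        matrix = drift
    # zero-support rows: impute score persistence, flagged by support 0
    for s in np.where(~observed)[0]:
        matrix[s, s] = 1.0
    return TransitionKernel(matrix=matrix, support_counts=support.astype(int))


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def read_trajectories(path: str | os.PathLike) -> list[Trajectory]:
    """Read trajectories from delimited text ``finding_id,age,risk_score``."""
    df = pd.read_csv(path)
    required = {"finding_id", "age", "risk_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory file must have columns {sorted(required)}")
    out = []
    for fid, grp in df.groupby("finding_id", sort=False):
        grp = grp.sort_values("age")
        out.append(Trajectory(fid, grp["age"].to_numpy(), grp["risk_score"].to_numpy()))
    return out


def write_trajectories(trajectories: Iterable[Trajectory], path: str | os.PathLike) -> None:
    rows = [
        {"finding_id": tr.finding_id, "age": a, "risk_score": s}
        for tr in trajectories
        for a, s in zip(tr.ages, tr.scores)
    ]
    pd.DataFrame(rows, columns=["finding_id", "age", "risk_score"]).to_csv(path, index=False)


def write_kernel(
    kernel: TransitionKernel,
    path: str | os.PathLike,
    support_path: str | os.PathLike | None = None,
) -> None:
    """Write a kernel as ``from_score,to_score,probability`` (nonzero cells only)
    plus an optional ``from_score,count`` support sidecar."""
    f, t = np.nonzero(kernel.matrix)
    pd.DataFrame(
        {"from_score": f, "to_score": t, "probability": kernel.matrix[f, t]}
    ).to_csv(path, index=False, float_format="%.12g")
    if support_path is not None:
        counts = (
            kernel.support_counts
            if kernel.support_counts is not None
            else np.zeros(kernel.n_scores, dtype=int)
        )
        pd.DataFrame(
            {"from_score": np.arange(kernel.n_scores), "count": counts}
        ).to_csv(support_path, index=False)


def read_kernel(
    path: str | os.PathLike,
    support_path: str | os.PathLike | None = None,
) -> TransitionKernel:
    """Read a kernel written by :func:`write_kernel`."""
    df = pd.read_csv(path)
    n = int(max(df["from_score"].max(), df["to_score"].max())) + 1
    n = max(n, N_RISK_STATES)
    matrix = np.zeros((n, n))
    matrix[df["from_score"].to_numpy(), df["to_score"].to_numpy()] = df[
        "probability"
    ].to_numpy()
    support = None
    if support_path is not None and Path(support_path).exists():
        sdf = pd.read_csv(support_path)
        support = np.zeros(n, dtype=int)
        support[sdf["from_score"].to_numpy()] = sdf["count"].to_numpy()
    return TransitionKernel(matrix=matrix, support_counts=support)
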
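"""State space, actions, horizon and the assembled decision-process instance.

The model tracks a patient annually through 104 states: 101 integer
risk-score states (0..100, the percent probability of breast cancer
assigned by an upstream risk model), a benign-biopsy state, a
malignant-biopsy state, and death.  Malignant biopsy and death are
absorbing; no decision is made there.  In every risk-score state the
radiologist chooses between annual mammography (AM) and biopsy (BX).
"""

from __future__ import annotations

import enum
import hashlib
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import yaml

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints
    from .rewards import RewardSpec
    from .transitions import TransitionKernel

#: number of integer risk-score states
N_RISK_STATES = 101
#: risk-score states plus Biopsy-B, Biopsy-M, Death
N_STATES = N_RISK_STATES + 3

#: numerical tolerance for kernel row sums
ROW_SUM_TOL = 1e-9


class Action(enum.Enum):
    """The two decisions available in every risk-score state."""

    AM = "AM"  # annual mammography
    BX = "BX"  # image-guided core biopsy

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf.

    Used wherever a continuous risk probability or interpolated score is
    mapped onto the integer 0..100 grid.
    """
    return int(math.floor(x + 0.5))


def risk_score_from_probability(p: float) -> int:
    """Map a cancer probability in [0, 1] to its integer risk-score state.

    A probability of 0.122 lands in state 12.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p!r} outside [0, 1]")
    return round_half_up(100.0 * p)


@dataclass(frozen=True)
class StateSpace:
    """The 104 model states: risk scores 0..100 plus the three special states."""

    risk_states: tuple[int, ...] = tuple(range(N_RISK_STATES))
    biopsy_benign: str = "Biopsy-B"
    biopsy_malignant: str = "Biopsy-M"
    death: str = "Death"

    def __post_init__(self) -> None:
        if tuple(self.risk_states) != tuple(range(N_RISK_STATES)):
            raise ValueError("risk states must be exactly the integers 0..100")

    @property
    def n_states(self) -> int:
        return len(self.risk_states) + 3

    @property
    def absorbing(self) -> tuple[str, str]:
        return (self.biopsy_malignant, self.death)


@dataclass(frozen=True)
class Horizon:
    """Decision epochs: annual decisions from ``start_age`` through
    ``last_decision_age``; a terminal reward is granted at ``terminal_age``.
    """

    start_age: int = 40
    last_decision_age: int = 99
    terminal_age: int = 100

    def __post_init__(self) -> None:
        if not (self.start_age < self.last_decision_age < self.terminal_age):
            raise ValueError(
                "horizon requires start_age < last_decision_age < terminal_age, "
                f"got {self.start_age}, {self.last_decision_age}, {self.terminal_age}"
            )
        if self.terminal_age != self.last_decision_age + 1:
            raise ValueError("terminal_age must be last_decision_age + 1")

    @property
    def decision_ages(self) -> range:
        """All ages at which a decision is made (inclusive of the last)."""
        return range(self.start_age, self.last_decision_age + 1)

    @property
    def n_epochs(self) -> int:
        return self.last_decision_age - self.start_age + 1


def biopsy_branch(risk_score: int) -> tuple[float, float]:
    """Split a biopsy decision into its malignant / benign outcome probabilities.

    Biopsy is assumed perfectly sensitive and specific and the risk score is
    taken to fully describe current cancer risk, so a patient in state ``s``
    moves to the malignant-biopsy state with probability ``s/100`` and to the
    benign-biopsy state otherwise.

    Returns
    -------
    (p_malignant, p_benign), summing exactly to 1.
    """
    if not isinstance(risk_score, (int, np.integer)) or isinstance(risk_score, bool):
        raise TypeError(f"risk_score must be an integer, got {risk_score!r}")
    if not 0 <= risk_score <= 100:
        raise ValueError(f"risk score {risk_score} outside 0..100")
    p_mal = risk_score / 100.0
    return p_mal, 1.0 - p_mal


@dataclass
class MdpInstance:
    """A fully validated decision-process instance ready for the solver."""

    state_space: StateSpace
    horizon: Horizon
    kernel: "TransitionKernel"
    rewards: "RewardSpec"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Reject (never repair) structural problems.

        Checks kernel shape and row-stochasticity and that every reward
        table covers every decision age.
        """
        k = self.kernel.matrix
        n = len(self.state_space.risk_states)
        if k.shape != (n, n):
            raise ValueError(f"kernel shape {k.shape} does not match {n} risk states")
        row_sums = k.sum(axis=1)
        bad = np.where(np.abs(row_sums - 1.0) > ROW_SUM_TOL)[0]
        if bad.size:
            raise ValueError(
                f"kernel rows {bad.tolist()[:5]} do not sum to 1 "
                f"(first bad sum {row_sums[bad[0]]:.6g})"
            )
        if np.any(k < -1e-15) or np.any(k > 1 + 1e-15):
            raise ValueError("kernel entries outside [0, 1]")
        self.rewards.check_age_coverage(self.horizon)


def build_instance(
    kernel: "TransitionKernel",
    rewards: "RewardSpec",
    horizon: Horizon | None = None,
) -> MdpInstance:
    """Assemble and validate an :class:`MdpInstance`.

    Raises on any coverage or stochasticity failure; nothing is repaired.
    """
    return MdpInstance(
        state_space=StateSpace(),
        horizon=horizon if horizon is not None else Horizon(),
        kernel=kernel,
        rewards=rewards,
    )


# ---------------------------------------------------------------------------
# Serialization: a plain-text key: value config naming the horizon and the
# file paths of the kernel and reward tables.
# ---------------------------------------------------------------------------


def write_instance(mdp: MdpInstance, directory: str | os.PathLike) -> Path:
    """Write an instance to ``directory`` as a config plus delimited tables.

    Returns the path of the config file.  Probabilities survive the
    round-trip to within 1e-12; integer fields exactly.
    """
    from .rewards import write_reward_tables
    from .transitions import write_kernel

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    kernel_path = directory / "kernel.csv"
    support_path = directory / "kernel_support.csv"
    write_kernel(mdp.kernel, kernel_path, support_path)
    table_paths = write_reward_tables(mdp.rewards, directory)

    cfg = {
        "horizon": {
            "start_age": mdp.horizon.start_age,
            "last_decision_age": mdp.horizon.last_decision_age,
            "terminal_age": mdp.horizon.terminal_age,
        },
        "kernel": kernel_path.name,
        "kernel_support": support_path.name,
        "tables": {k: p.name for k, p in table_paths.items()},
        "parameters": mdp.rewards.scalar_parameters(),
    }
    config_path = directory / "instance.yaml"
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return config_path


def read_instance(config_path: str | os.PathLike) -> MdpInstance:
    """Read an instance previously written by :func:`write_instance`."""
    from .rewards import read_reward_spec
    from .transitions import read_kernel

    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    base = config_path.parent
    horizon = Horizon(**cfg["horizon"])
    kernel = read_kernel(base / cfg["kernel"], base / cfg["kernel_support"])
    rewards = read_reward_spec(
        {k: base / v for k, v in cfg["tables"].items()}, cfg["parameters"]
    )
    return build_instance(kernel, rewards, horizon)


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping, for run manifests."""
    canon = yaml.safe_dump(obj, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:16]
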
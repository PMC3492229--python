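import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from biopsymdp.model_core import Horizon
from biopsymdp.rewards import (
    AgeTable,
    DisutilitySchedule,
    LumpSumTables,
    MortalityTables,
    RewardSpec,
    TreatmentEffect,
)
from biopsymdp.sensitivity import default_base_rewards
from biopsymdp.synthetic_data import default_true_kernel, load_base_kernel

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def horizon() -> Horizon:
    return Horizon()


@pytest.fixture(scope="session")
def base_kernel():
    return load_base_kernel()


@pytest.fixture(scope="session")
def true_kernel():
    return default_true_kernel()


@pytest.fixture(scope="session")
def base_rewards() -> RewardSpec:
    return default_base_rewards()


def constant_reward_spec(
    horizon: Horizon = Horizon(),
    other: float = 0.01,
    treated: float = 0.10,
    tau: float = 1.6,
    invasive_life: float = 10.0,
    dcis_life: float = 14.0,
    pct_invasive: float = 0.75,
    d40: float = 2.0,
    factor: float = 2.0,
    terminal: float = 2.0,
) -> RewardSpec:
    """A reward spec with age-constant tables, for hand-computable cases."""
    ages = np.arange(horizon.start_age, horizon.terminal_age + 1)
    const = lambda v, name: AgeTable(ages, np.full(len(ages), v), name)
    return RewardSpec(
        disutility=DisutilitySchedule(d40, factor),
        mortality=MortalityTables(const(other, "other_cause"), const(treated, "treated_bc")),
        effect=TreatmentEffect(tau),
        lump=LumpSumTables(const(invasive_life, "invasive"), const(dcis_life, "dcis"), pct_invasive),
        terminal_reward=terminal,
    )


@pytest.fixture
def const_rewards() -> RewardSpec:
    return constant_reward_spec()


# ---------------------------------------------------------------------------
# Independent exhaustive-enumeration oracle for small decision problems.
# Evaluates every deterministic Markov policy by its own forward recursion
# and maximizes over them; shares no code path with the solver.
# ---------------------------------------------------------------------------


def enumeration_oracle(kernel, r_am, p_death, lump_net, r_benign, p_other, mal, terminal,
                       discount=1.0):
    """Return (optimal value at every (epoch, state), per-policy values)."""
    kernel = np.asarray(kernel, float)
    r_am = np.asarray(r_am, float)
    T, n = r_am.shape
    lump_net = np.broadcast_to(np.asarray(lump_net, float), (T,))
    r_benign = np.broadcast_to(np.asarray(r_benign, float), (T,))
    p_other = np.broadcast_to(np.asarray(p_other, float), (T,))
    mal = np.asarray(mal, float)
    terminal = np.broadcast_to(np.asarray(terminal, float), (n,))

    n_bits = T * n
    policies = ((np.arange(2**n_bits)[:, None] >> np.arange(n_bits)) & 1).astype(bool)
    policies = policies.reshape(-1, T, n)  # (P, T, n): True = biopsy

    V = np.broadcast_to(terminal, (policies.shape[0], n)).copy()
    values = np.empty((policies.shape[0], T + 1, n))
    values[:, T] = V
    for e in range(T - 1, -1, -1):
        cont = V @ kernel.T
        v_am = r_am[e] + discount * (1.0 - p_death[e]) * cont
        v_bx = mal * lump_net[e] + (1.0 - mal) * (
            r_benign[e] + discount * (1.0 - p_other[e]) * cont
        )
        V = np.where(policies[:, e], v_bx, v_am)
        values[:, e] = V
    # the optimum at every (epoch, state) is the max over all fixed policies
    return values.max(axis=0), values


def random_small_problem(rng, n, T):
    """A random decision problem with n risk states and T epochs."""
    kernel = rng.random((n, n)) + 0.05
    kernel /= kernel.sum(axis=1, keepdims=True)
    return dict(
        kernel=kernel,
        r_am=rng.uniform(0.3, 1.0, (T, n)),
        p_death=rng.uniform(0.0, 0.6, (T, n)),
        lump_net=rng.uniform(0.0, 8.0, T),
        r_benign=rng.uniform(0.2, 1.0, T),
        p_other=rng.uniform(0.0, 0.3, T),
        mal=np.sort(rng.uniform(0.0, 1.0, n)),
        terminal=rng.uniform(0.0, 4.0, n),
    )
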
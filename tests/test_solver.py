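import dataclasses

import numpy as np
import pytest

from biopsymdp.model_core import Action, Horizon, build_instance
from biopsymdp.solver import (
    NO_BIOPSY,
    PolicyTable,
    ThresholdCurve,
    backward_induction,
    evaluate_policy,
    extract_threshold,
    read_threshold_curve,
    solve_decision_problem,
    write_policy,
    write_threshold_curve,
    write_value,
)

from .conftest import constant_reward_spec, enumeration_oracle, random_small_problem


class TestGenericCore:
    def test_zero_rewards_give_zero_values_and_all_am(self):
        n, T = 4, 3
        kernel = np.full((n, n), 1.0 / n)
        V, bx = solve_decision_problem(
            kernel,
            r_am=np.zeros((T, n)),
            p_death=np.zeros((T, n)),
            lump_net=np.zeros(T),
            r_benign=np.zeros(T),
            p_other=np.zeros(T),
            malignant_prob=np.linspace(0, 1, n),
            terminal=0.0,
        )
        assert np.all(V == 0.0)
        assert not bx.any()  # ties resolve to mammography

    def test_two_state_single_epoch_matches_hand_enumeration(self):
        # hand-set numbers; optimum of the 4 candidate policies computed by hand
        kernel = np.eye(2)
        V, bx = solve_decision_problem(
            kernel,
            r_am=np.array([[0.9, 0.8]]),
            p_death=np.array([[0.1, 0.2]]),
            lump_net=np.array([5.0]),
            r_benign=np.array([0.85]),
            p_other=np.array([0.05]),
            malignant_prob=np.array([0.0, 0.5]),
            terminal=np.array([2.0, 1.0]),
        )
        # state 0: AM = 0.9 + 0.9*2 = 2.70, BX = 0.85 + 0.95*2 = 2.75 -> BX
        # state 1: AM = 0.8 + 0.8*1 = 1.60, BX = 2.5 + 0.5*(0.85+0.95) = 3.40 -> BX
        np.testing.assert_allclose(V[0], [2.75, 3.40], atol=1e-12)
        assert bx[0].tolist() == [True, True]

    @pytest.mark.parametrize("n,T", [(2, 1), (3, 2), (3, 3), (4, 2)])
    def test_matches_exhaustive_policy_enumeration(self, n, T):
        rng = np.random.default_rng(1000 + 10 * n + T)
        for _ in range(10):
            prob = random_small_problem(rng, n, T)
            V, _ = solve_decision_problem(
                prob["kernel"], prob["r_am"], prob["p_death"], prob["lump_net"],
                prob["r_benign"], prob["p_other"], prob["mal"], prob["terminal"],
            )
            V_star, _ = enumeration_oracle(**prob)
            np.testing.assert_allclose(V, V_star, atol=1e-9)

    def test_non_finite_rewards_rejected(self):
        with pytest.raises(FloatingPointError):
            solve_decision_problem(
                np.eye(2),
                r_am=np.array([[np.nan, 0.0]]),
                p_death=np.zeros((1, 2)),
                lump_net=np.zeros(1),
                r_benign=np.zeros(1),
                p_other=np.zeros(1),
                malignant_prob=np.array([0.0, 1.0]),
                terminal=0.0,
            )


class TestBackwardInduction:
    def test_value_at_terminal_age_is_terminal_reward(self, true_kernel):
        mdp = build_instance(true_kernel, constant_reward_spec(terminal=2.5))
        vf, _ = backward_induction(mdp)
        assert vf.value(100, 0) == 2.5 and vf.value(100, 100) == 2.5
        assert vf.value(70, "Death") == 0.0

    def test_value_bounded_by_terminal_plus_horizon(self, base_kernel, base_rewards):
        mdp = build_instance(base_kernel, base_rewards)
        vf, _ = backward_induction(mdp)
        bound = base_rewards.terminal_reward + mdp.horizon.n_epochs
        assert np.all(vf.values <= bound + 1e-9)
        assert np.all(np.isfinite(vf.values)) and np.all(vf.values >= 0)

    def test_raising_lump_sums_never_lowers_values(self, base_kernel, base_rewards):
        mdp = build_instance(base_kernel, base_rewards)
        vf, _ = backward_induction(mdp)
        lifted = dataclasses.replace(
            base_rewards,
            lump=dataclasses.replace(
                base_rewards.lump,
                invasive_expected_life=_scaled(base_rewards.lump.invasive_expected_life, 1.2),
            ),
        )
        vf2, _ = backward_induction(build_instance(base_kernel, lifted))
        assert np.all(vf2.values >= vf.values - 1e-12)

    def test_discounting_reduces_values(self, base_kernel, base_rewards):
        mdp = build_instance(base_kernel, base_rewards)
        vf, _ = backward_induction(mdp)
        vf_d, _ = backward_induction(mdp, discount=0.97)
        # terminal rows coincide; earlier epochs are discounted except where
        # the optimum is an immediate lump sum with no continuation (score 100)
        assert np.all(vf_d.values <= vf.values + 1e-12)
        assert np.all(vf_d.values[:-1, :100] < vf.values[:-1, :100])


def _scaled(table, factor):
    from biopsymdp.rewards import AgeTable

    return AgeTable(table.ages, table.values * factor, table.name)


class TestEvaluatePolicy:
    def test_optimal_policy_reproduces_optimal_value(self, base_kernel, base_rewards):
        mdp = build_instance(base_kernel, base_rewards)
        vf, policy = backward_induction(mdp)
        vf_eval = evaluate_policy(mdp, policy)
        np.testing.assert_allclose(vf_eval.values, vf.values, atol=1e-12)

    def test_fixed_policies_never_beat_the_optimum(self, base_kernel, base_rewards):
        mdp = build_instance(base_kernel, base_rewards)
        vf, _ = backward_induction(mdp)
        ages = np.array(mdp.horizon.decision_ages)
        for fill in (False, True):  # all-AM and all-BX
            fixed = PolicyTable(ages, np.full((len(ages), 101), fill))
            vals = evaluate_policy(mdp, fixed).values
            assert np.all(vals <= vf.values + 1e-9)

    def test_partial_policy_rejected(self, base_kernel, base_rewards):
        mdp = build_instance(base_kernel, base_rewards)
        short = PolicyTable(np.arange(40, 50), np.zeros((10, 101), dtype=bool))
        with pytest.raises(ValueError, match="cover"):
            evaluate_policy(mdp, short)

    def test_single_epoch_all_biopsy_matches_closed_form(self):
        # one epoch, fixed BX: V = m*lump + (1-m)*(r_b + (1-p_o)*terminal)
        n = 3
        mal = np.array([0.0, 0.5, 1.0])
        V, _ = solve_decision_problem(
            np.full((n, n), 1 / n),
            r_am=np.zeros((1, n)),
            p_death=np.zeros((1, n)),
            lump_net=np.array([6.0]),
            r_benign=np.array([0.9]),
            p_other=np.array([0.1]),
            malignant_prob=mal,
            terminal=2.0,
            policy=np.ones((1, n), dtype=bool),
        )
        expected = mal * 6.0 + (1 - mal) * (0.9 + 0.9 * 2.0)
        np.testing.assert_allclose(V[0], expected, atol=1e-12)


class TestThresholdExtraction:
    def _policy(self, bx_rule):
        ages = np.arange(40, 100)
        is_bx = np.array([[bx_rule(a, s) for s in range(101)] for a in ages])
        return PolicyTable(ages, is_bx)

    def test_constant_control_limit_policy(self):
        curve = extract_threshold(self._policy(lambda a, s: s >= 2))
        assert np.all(curve.threshold == 2)
        assert curve.control_limit.all()
        assert curve.non_control_ages == []

    def test_all_mammography_policy_yields_sentinels(self):
        curve = extract_threshold(self._policy(lambda a, s: False))
        assert np.all(curve.threshold == NO_BIOPSY)
        assert curve.control_limit.all()

    def test_non_control_limit_age_is_flagged_not_repaired(self):
        # biopsy at scores 5..9 only: a band, not a control limit
        curve = extract_threshold(self._policy(lambda a, s: (5 <= s < 10) if a == 50 else s >= 5))
        assert curve.at(50) == 5
        assert curve.non_control_ages == [50]

    def test_policy_table_action_accessor(self):
        policy = self._policy(lambda a, s: s >= 3)
        assert policy.action(40, 3) is Action.BX
        assert policy.action(40, 2) is Action.AM
        with pytest.raises(KeyError):
            policy.action(100, 0)


class TestSolverOutputs:
    def test_output_files_round_trip(self, tmp_path, base_kernel, base_rewards):
        mdp = build_instance(base_kernel, base_rewards)
        vf, policy = backward_induction(mdp)
        curve = extract_threshold(policy)
        write_policy(policy, tmp_path / "policy.csv")
        write_value(vf, tmp_path / "value.csv")
        write_threshold_curve(curve, tmp_path / "curve.csv")
        back = read_threshold_curve(tmp_path / "curve.csv")
        np.testing.assert_array_equal(back.threshold, curve.threshold)
        np.testing.assert_array_equal(back.ages, curve.ages)
        import pandas as pd

        pol = pd.read_csv(tmp_path / "policy.csv")
        assert len(pol) == 60 * 101
        assert set(pol["action"].unique()) <= {"AM", "BX"}
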
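import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from biopsymdp.transitions import (
    Trajectory,
    TransitionKernel,
    annualize_trajectory,
    estimate_kernel,
    read_kernel,
    read_trajectories,
    write_kernel,
    write_trajectories,
)


def traj(fid, pairs):
    ages, scores = zip(*pairs)
    return Trajectory(fid, ages, scores)


class TestTrajectory:
    def test_duplicate_ages_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            traj("a", [(40, 1), (40, 2)])

    def test_decreasing_ages_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            traj("a", [(42, 1), (40, 2)])

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError, match="0..100"):
            traj("a", [(40, 101)])


class TestAnnualize:
    @pytest.mark.parametrize(
        "observed,expected",
        [
            # a two-year gap: risk assumed to rise linearly, midpoint imputed
            ([(40, 1), (42, 5)], [(40, 1), (41, 3), (42, 5)]),
            ([(50, 4), (51, 7)], [(50, 4), (51, 7)]),  # already annual
            ([(60, 2), (63, 8)], [(60, 2), (61, 4), (62, 6), (63, 8)]),
            ([(45, 9)], [(45, 9)]),  # single observation passes through
        ],
    )
    def test_linear_interpolation_on_integer_grid(self, observed, expected):
        out = annualize_trajectory(traj("a", observed))
        exp = traj("a", expected)
        np.testing.assert_allclose(out.ages, exp.ages)
        np.testing.assert_array_equal(out.scores, exp.scores)

    def test_interpolated_scores_round_half_up(self):
        # (40,0) -> (43,5): exact values 5/3 and 10/3 round to 2 and 3
        out = annualize_trajectory(traj("a", [(40, 0), (43, 5)]))
        np.testing.assert_array_equal(out.scores, [0, 2, 3, 5])

    def test_decimal_entry_ages_keep_annual_spacing(self):
        out = annualize_trajectory(traj("a", [(56.3, 2), (59.3, 8)]))
        np.testing.assert_allclose(out.ages, [56.3, 57.3, 58.3, 59.3])
        np.testing.assert_array_equal(out.scores, [2, 4, 6, 8])

    @given(
        start=st.integers(40, 90),
        gap=st.integers(1, 8),
        s0=st.integers(0, 100),
        s1=st.integers(0, 100),
    )
    def test_observed_endpoints_preserved_and_spacing_annual(self, start, gap, s0, s1):
        out = annualize_trajectory(traj("a", [(start, s0), (start + gap, s1)]))
        assert out.scores[0] == s0 and out.scores[-1] == s1
        np.testing.assert_allclose(np.diff(out.ages), 1.0)
        lo, hi = min(s0, s1), max(s0, s1)
        assert np.all((out.scores >= lo) & (out.scores <= hi))


class TestEstimateKernel:
    def test_self_transitions_give_identity_rows(self):
        trajs = [traj(i, [(40, s), (41, s), (42, s)]) for i, s in enumerate([0, 5, 80])]
        k = estimate_kernel(trajs)
        for s in (0, 5, 80):
            assert k.matrix[s, s] == 1.0
            assert k.support_counts[s] == 2
        assert k.imputed_rows[5] == False  # noqa: E712 - observed row
        assert k.imputed_rows[50] == True  # noqa: E712 - never observed

    def test_single_observation_trajectories_do_not_contribute(self):
        corpus = [traj("a", [(40, 3), (41, 4)]), traj("b", [(50, 3), (51, 3)])]
        with_single = corpus + [traj("c", [(60, 3)])]
        k1, k2 = estimate_kernel(corpus), estimate_kernel(with_single)
        np.testing.assert_array_equal(k1.matrix, k2.matrix)
        np.testing.assert_array_equal(k1.support_counts, k2.support_counts)

    def test_all_single_observation_rejected(self):
        with pytest.raises(ValueError, match="more than one observation"):
            estimate_kernel([traj("a", [(40, 3)]), traj("b", [(50, 7)])])

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        trajs = [
            traj(i, [(40 + j, int(s)) for j, s in enumerate(rng.integers(0, 20, 4))])
            for i in range(50)
        ]
        k1 = estimate_kernel(trajs)
        k2 = estimate_kernel(list(reversed(trajs)))
        np.testing.assert_array_equal(k1.matrix, k2.matrix)

    def test_interpolated_pairs_count_like_observed(self):
        # (40,1),(42,5) contributes pairs 1->3 and 3->5 after imputation
        k = estimate_kernel([traj("a", [(40, 1), (42, 5)]), traj("pad", [(50, 0), (51, 0)])])
        assert k.matrix[1, 3] == 1.0
        assert k.matrix[3, 5] == 1.0
        assert k.support_counts[1] == 1 and k.support_counts[3] == 1

    def test_rows_are_stochastic_and_entries_in_unit_interval(self):
        rng = np.random.default_rng(5)
        trajs = [
            traj(i, [(40 + j, int(s)) for j, s in enumerate(rng.integers(0, 101, 5))])
            for i in range(200)
        ]
        k = estimate_kernel(trajs)
        np.testing.assert_allclose(k.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((k.matrix >= 0) & (k.matrix <= 1))

    def test_mean_drift_mode_concentrates_on_rounded_mean(self):
        trajs = [traj("a", [(40, 10), (41, 12)]), traj("b", [(40, 10), (41, 15)])]
        k = estimate_kernel(trajs, mode="mean-drift")
        row = k.matrix[10]
        assert row[14] == 1.0  # mean next score 13.5 rounds half-up to 14
        assert row.sum() == 1.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            estimate_kernel([traj("a", [(40, 1), (41, 2)])], mode="bogus")

    @pytest.mark.parametrize("n_pairs,tv_bound", [(100, 0.25), (1000, 0.10), (10000, 0.04)])
    def test_row_recovery_tightens_with_sample_size(self, n_pairs, tv_bound):
        # one heavily sampled row from a known next-state distribution
        rng = np.random.default_rng(77)
        truth = np.zeros(101)
        truth[[8, 10, 11, 13, 20]] = [0.1, 0.4, 0.3, 0.15, 0.05]
        nxt = rng.choice(101, size=n_pairs, p=truth)
        trajs = [traj(i, [(40, 10), (41, int(t))]) for i, t in enumerate(nxt)]
        k = estimate_kernel(trajs)
        tv = 0.5 * np.abs(k.matrix[10] - truth).sum()
        assert tv < tv_bound


class TestKernelIO:
    def test_round_trip_with_support_sidecar(self, tmp_path, true_kernel):
        kern = TransitionKernel(true_kernel.matrix, np.arange(101))
        write_kernel(kern, tmp_path / "k.csv", tmp_path / "s.csv")
        back = read_kernel(tmp_path / "k.csv", tmp_path / "s.csv")
        np.testing.assert_allclose(back.matrix, kern.matrix, atol=1e-12)
        np.testing.assert_array_equal(back.support_counts, kern.support_counts)

    def test_trajectory_file_round_trip(self, tmp_path):
        trajs = [traj("a", [(40.5, 1), (42.5, 5)]), traj("b", [(60, 0)])]
        write_trajectories(trajs, tmp_path / "t.csv")
        back = read_trajectories(tmp_path / "t.csv")
        assert back == trajs
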
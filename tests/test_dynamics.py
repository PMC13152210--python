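"""State dynamics: runs, occupancy, transitions, coupling, fingerprints."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import attnstates as at
from attnstates.dynamics import (_empirical_p, dunn_posthoc, dwell_times,
                                 switch_indicator)


class TestRunLengths:
    def test_simple_encoding(self):
        enc = at.run_lengths(np.array([0, 0, 1, 1, 1, 0]), [6])
        assert enc[0] == [(0, 0, 2), (1, 2, 3), (0, 5, 1)]

    def test_constant_session_single_block(self):
        enc = at.run_lengths(np.full(40, 2), [40])
        assert enc[0] == [(2, 0, 40)]

    def test_runs_truncated_at_session_boundary(self):
        labels = np.array([1, 1, 1, 1])  # two sessions, both all-1
        enc = at.run_lengths(labels, [2, 2])
        assert enc[0] == [(1, 0, 2)] and enc[1] == [(1, 0, 2)]

    def test_blocks_tile_sessions_exactly(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, 100)
        enc = at.run_lengths(labels, [60, 40])
        for session, n in zip(enc, (60, 40)):
            assert sum(length for _, _, length in session) == n


class TestDwell:
    def test_mean_dwell_matches_markov_theory(self):
        cfg = at.SyntheticConfig(n_sessions=1, trials_per_session=20_000,
                                 acc_self_p=0.9, seed=4)
        _, _, truth = at.simulate_sessions(cfg)
        dw = dwell_times(truth.acc_states, truth.session_lengths)
        se = dw.std(ddof=1) / np.sqrt(dw.size)
        assert abs(dw.mean() - 10.0) < 3 * se + 1e-9

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            at.dwell_tests({"only": [1, 2, 3]})

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.geometric(1 / 5, 300),
                  "b": rng.geometric(1 / 10, 300)}
        result, posthoc = at.dwell_tests(groups)
        assert result.p_value < 0.01
        assert posthoc is not None and (posthoc["p_adj"] < 0.05).any()

    def test_dunn_z_matches_hand_computation(self):
        """No-tie fixture: mean ranks 2/5/8, pooled var 7.5."""
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0],
                  "c": [7.0, 8.0, 9.0]}
        table = dunn_posthoc(groups)
        row = table[(table.group1 == "a") & (table.group2 == "b")].iloc[0]
        se = np.sqrt(7.5 * (2 / 3))
        assert row["z"] == pytest.approx((2 - 5) / se)
        assert row["p_adj"] == pytest.approx(min(1.0, 3 * row["p"]))


class TestOccupancy:
    def test_constant_sequence(self):
        occ = at.occupancy(np.zeros(50, dtype=int), [50], 4)
        assert np.allclose(occ[0], [1, 0, 0, 0])

    def test_uniform_sequence_balanced(self):
        rng = np.random.default_rng(2)
        occ = at.occupancy(rng.integers(0, 4, 10_000), [10_000], 4)
        assert np.allclose(occ[0], 0.25, atol=3 * 0.013 / 3 + 0.013)

    def test_proportions_sum_to_one_per_half(self):
        rng = np.random.default_rng(3)
        occ = at.occupancy(rng.integers(0, 4, 301), [301], 4, by="half")
        assert occ.shape == (1, 2, 4)
        assert np.allclose(occ.sum(axis=2), 1.0)

    def test_odd_middle_trial_in_first_half(self):
        occ = at.occupancy(np.array([1, 1, 1, 0, 0]), [5], 2, by="half")
        assert occ[0, 0].tolist() == [0.0, 1.0]  # 3 trials, all state 1

    def test_identical_groups_give_p_one(self):
        occ = np.tile(np.array([[0.25, 0.25, 0.25, 0.25]]), (6, 1))
        res = at.occupancy_tests(occ, ["a"] * 3 + ["b"] * 3, n_perm=200,
                                 rng=np.random.default_rng(0))
        assert all(r.p_value == 1.0 for r in res)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(4)
        occ_a = rng.dirichlet([8, 8, 8, 8], 10)
        occ_b = rng.dirichlet([8, 8, 8, 8], 10)
        occ_b[:, 0] += 0.2
        occ_b /= occ_b.sum(axis=1, keepdims=True)
        res = at.occupancy_tests(np.vstack([occ_a, occ_b]),
                                 ["a"] * 10 + ["b"] * 10, n_perm=500,
                                 rng=np.random.default_rng(5))
        global_state0 = [r for r in res
                        if r.name == "occupancy_global_state0"][0]
        assert global_state0.p_value < 0.05

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            at.occupancy_tests(np.ones((3, 4)) / 4, ["a", "a", "a"])


class TestTransitions:
    def test_strict_two_cycle(self):
        tm = at.transition_matrix(np.array([0, 1] * 20), [40], 2)
        assert tm.offdiag[0, 1] == 1.0 and tm.offdiag[1, 0] == 1.0
        assert tm.probs[0, 1] == 1.0

    def test_mle_consistency_on_long_chain(self):
        rng = np.random.default_rng(6)
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        labels = np.empty(50_000, dtype=int)
        labels[0] = 0
        u = rng.random(labels.size - 1)
        for t in range(1, labels.size):
            labels[t] = (labels[t - 1] + (u[t - 1]
                         > P[labels[t - 1], labels[t - 1]])) % 2
        tm = at.transition_matrix(labels, [labels.size], 2)
        assert np.allclose(tm.probs, P, atol=0.01)

    def test_unvisited_state_row_masked(self):
        tm = at.transition_matrix(np.array([0, 1, 0, 1]), [4], 3)
        assert np.isnan(tm.probs[2]).all()

    def test_rows_stochastic_to_machine_precision(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 4, 2000)
        tm = at.transition_matrix(labels, [1000, 1000], 4)
        assert np.allclose(tm.probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(tm.offdiag.sum(axis=1), 1.0, atol=1e-12)


class TestBlockShuffle:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=5, max_size=60),
           st.integers(0, 2 ** 31 - 1))
    def test_run_length_multiset_preserved(self, labels, seed):
        labels = np.asarray(labels)
        rng = np.random.default_rng(seed)
        shuffled = at.block_shuffle(labels, [labels.size], rng)

        def multiset(x):
            return sorted((lab, length) for session
                          in at.run_lengths(x, [x.size])
                          for lab, _, length in session)

        assert multiset(shuffled) == multiset(labels)

    def test_composite_null_detects_planted_coswitching(self):
        """Chains forced to switch together load distracted<->efficient."""
        rng = np.random.default_rng(8)
        chain = np.concatenate([np.full(rng.integers(3, 10), i % 2)
                                for i in range(80)])[:400]
        speed, acc = chain.copy(), chain.copy()
        tm = at.composite_transition_null(speed, acc, [400], n_shuffle=300,
                                          rng=np.random.default_rng(9))
        # composite alternates between distracted (0) and efficient (3)
        assert tm.flags[0, 3] and tm.flags[3, 0]

    def test_independent_chains_rarely_flagged(self):
        cfg = at.SyntheticConfig(n_sessions=2, trials_per_session=400,
                                 seed=10)
        _, _, truth = at.simulate_sessions(cfg)
        tm = at.composite_transition_null(truth.speed_states,
                                          truth.acc_states,
                                          truth.session_lengths,
                                          n_shuffle=300,
                                          rng=np.random.default_rng(11))
        assert tm.flags.sum() <= 2


class TestGroupComparison:
    def _mats(self, self_p, n, seed):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            labels = np.empty(300, dtype=int)
            labels[0] = 0
            for t in range(1, 300):
                stay = rng.random() < self_p
                labels[t] = labels[t - 1] if stay else rng.integers(0, 4)
            out.append(at.transition_matrix(labels, [300], 4).probs)
        return out

    def test_identical_matrices_zero_distance(self):
        mats = self._mats(0.8, 4, 0)
        res, _ = at.group_transition_comparison(
            mats + mats, ["a"] * 4 + ["b"] * 4, n_perm=100, n_boot=50,
            rng=np.random.default_rng(1))
        assert res[0].statistic == pytest.approx(0.0, abs=1e-12)

    def test_different_dynamics_detected(self):
        mats = self._mats(0.7, 8, 2) + self._mats(0.92, 8, 3)
        res, cells = at.group_transition_comparison(
            mats, ["a"] * 8 + ["b"] * 8, n_perm=300, n_boot=100,
            rng=np.random.default_rng(4))
        assert res[0].p_value < 0.05
        assert ("a", "b") in cells


class TestSwitchCoupling:
    def test_identical_sequences_couple_at_lag_zero(self):
        rng = np.random.default_rng(12)
        labels = rng.integers(0, 2, 300)
        curve = at.switch_coupling(labels, labels.copy(), [300], max_lag=5,
                                   n_shift=100,
                                   rng=np.random.default_rng(13))
        assert curve.coupling[curve.lags.tolist().index(0)] == 1.0

    def test_planted_one_trial_lag_detected(self):
        cfg = at.SyntheticConfig(n_sessions=2, trials_per_session=400,
                                 seed=14)
        _, _, truth = at.simulate_sessions(cfg)
        speed = truth.speed_states
        acc = np.concatenate([np.roll(s, 1) for s
                              in truth.per_session("speed_states")])
        curve = at.switch_coupling(speed, acc, truth.session_lengths,
                                   max_lag=5, n_shift=1000,
                                   rng=np.random.default_rng(15))
        i = curve.lags.tolist().index(1)
        assert curve.coupling[i] > 0.99
        assert curve.flags[i]

    def test_boundary_trials_not_switches(self):
        ind = switch_indicator(np.array([0, 1, 1, 1]), [2, 2])
        assert ind[0].tolist() == [False, True]
        assert ind[1].tolist() == [False, False]


class TestFingerprints:
    def test_identical_groups_maximally_similar(self, batch, fitted):
        fps = at.session_fingerprints(batch["frames"],
                                      fitted["composite"].labels,
                                      fitted["composite"].session_lengths)
        assert fps.shape == (6, 20)
        res = at.fingerprint_comparison(np.vstack([fps, fps]),
                                        ["a"] * 6 + ["b"] * 6, n_perm=200,
                                        rng=np.random.default_rng(0))
        assert res[0].extra["pearson_r"] > 0.999
        assert res[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert res[0].p_value > 0.9

    def test_scaled_pattern_high_r_nonzero_distance(self, batch, fitted):
        fps = at.session_fingerprints(batch["frames"],
                                      fitted["composite"].labels,
                                      fitted["composite"].session_lengths)
        scaled = 2.0 * fps
        res = at.fingerprint_comparison(np.vstack([fps, scaled]),
                                        ["a"] * 6 + ["b"] * 6, n_perm=300,
                                        rng=np.random.default_rng(1))
        assert res[0].extra["pearson_r"] > 0.95
        assert res[0].statistic > 0.5

    def test_unvisited_state_entries_masked(self):
        frame = pd.DataFrame({m: np.random.default_rng(2).normal(size=10)
                              for m in at.METRICS})
        labels = np.zeros(10, dtype=int)  # state 0 only
        fps = at.session_fingerprints([frame], labels, [10])
        assert np.isfinite(fps[0, :5]).all()
        assert np.isnan(fps[0, 5:]).all()


def test_empirical_p_plus_one_correction():
    null = np.arange(99)
    assert _empirical_p(1000.0, null, two_sided=False) \
        == pytest.approx(1 / 100)
    assert _empirical_p(-5.0, null, two_sided=False) == 1.0
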
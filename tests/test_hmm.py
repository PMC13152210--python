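"""State inference: padding, EM fitting, decoding, conjunction."""

import itertools

import numpy as np
import pytest
from hmmlearn.hmm import GaussianHMM
from scipy.stats import multivariate_normal

import attnstates as at
from attnstates.hmm import (AXIS_METRICS, HmmModel, _semantic_order,
                            em_loglik_trace)


class TestPadding:
    def test_two_sessions_padded_length(self, batch):
        X, mask, lengths = at.pad_sessions(batch["frames"][:2],
                                           AXIS_METRICS["speed"], pad=50)
        assert X.shape[0] == sum(lengths) + 50
        assert mask.sum() == 50

    def test_single_session_unpadded(self, batch):
        X, mask, lengths = at.pad_sessions(batch["frames"][:1],
                                           AXIS_METRICS["speed"], pad=50)
        assert X.shape[0] == lengths[0] and not mask.any()

    def test_pad_rows_constant(self, batch):
        X, mask, _ = at.pad_sessions(batch["frames"][:3],
                                     AXIS_METRICS["accuracy"],
                                     pad=50, pad_value=10.0)
        assert np.all(X[mask] == 10.0)


class TestFitting:
    def test_pad_state_absorbs_pads_with_high_posterior(self, batch,
                                                        fitted):
        model = fitted["speed_model"]
        X, mask, _ = at.pad_sessions(batch["frames"],
                                     AXIS_METRICS["speed"])
        post = model.model.predict_proba(X)
        assert post[mask, model.pad_state].mean() > 0.99

    def test_transition_rows_sum_to_one(self, fitted):
        for key in ("speed_model", "acc_model"):
            rows = fitted[key].transmat.sum(axis=1)
            assert np.allclose(rows, 1.0, atol=1e-12)

    def test_em_loglikelihood_monotone(self, batch):
        # pad-free data: the constant padding cluster drives a covariance
        # towards singularity, where the regulariser breaks exact EM ascent
        X, _, _ = at.pad_sessions(batch["frames"][:2],
                                  AXIS_METRICS["speed"], pad=0)
        trace = em_loglik_trace(X, n_states=2, seed=0, n_iter=15)
        diffs = np.diff(trace)
        assert np.all(diffs > -1e-6)

    def test_nonfinite_observations_rejected(self):
        X = np.full((50, 2), np.nan)
        with pytest.raises(ValueError):
            at.fit_axis_hmm(X, np.zeros(50, dtype=bool), axis="speed")

    def test_zero_noise_data_recovered_exactly(self):
        """Near-noiseless emissions: decoding reproduces the planted chains.

        Binary rates cannot be exactly 0/1 (a Gaussian state with exactly
        singular covariance breaks EM), so a 0.2% flip floor remains; the
        agreement threshold leaves room for those genuinely flipped trials.
        """
        means = at.synthetic._default_means().copy()
        means["hit"] = (0.002, 0.998)
        means["bias"] = (0.998, 0.002)
        means["precision"] = (0.6, 0.8)
        cfg = at.SyntheticConfig(
            n_sessions=3, trials_per_session=200, seed=2, miss_frac=0.0,
            emission_means=means,
            emission_sds={"precision": 0.01, "rt": 0.02, "speed": 1.0})
        _, sessions, truth = at.simulate_sessions(cfg)
        frames, _ = at.preprocess_group(sessions, smoothing_window=1)
        kept = np.concatenate([
            f["trial_index"].to_numpy() + i * cfg.trials_per_session
            for i, f in enumerate(frames)])
        _, speed_seq = at.fit_axis(frames, "speed", restarts=5, seed=0,
                                   min_covar=1e-6)
        _, acc_seq = at.fit_axis(frames, "accuracy", restarts=5, seed=1,
                                 min_covar=1e-6)
        comp = at.conjoin(speed_seq, acc_seq)
        assert (comp.labels == truth.composite_states[kept]).mean() > 0.99


class TestDecoding:
    def test_decoded_majority_matches_truth(self, batch, fitted):
        truth = batch["truth"]
        kept = batch["kept"]
        agree = (fitted["speed_seq"].labels
                 == truth.speed_states[kept]).mean()
        assert agree > 0.8

    @staticmethod
    def _make_model(perm):
        """A hand-built 2-state speed-axis model with states in ``perm``
        order (raw index perm[i] plays semantic role i)."""
        base_means = np.array([[0.8, -0.8], [-0.8, 0.8]])  # slow, fast
        base_trans = np.array([[0.85, 0.15], [0.2, 0.8]])
        base_start = np.array([0.5, 0.5])
        raw = GaussianHMM(n_components=2, covariance_type="full")
        raw.n_features = 2
        inv = np.argsort(perm)
        raw.means_ = base_means[perm]
        raw.transmat_ = base_trans[np.ix_(perm, perm)]
        raw.startprob_ = base_start[perm]
        raw.covars_ = np.array([np.eye(2) * 0.5] * 2)
        return HmmModel(
            axis="speed", means=raw.means_, covars=raw.covars_,
            transmat=raw.transmat_, startprob=raw.startprob_,
            log_likelihood=0.0, pad_state=None,
            state_order=_semantic_order("speed", raw.means_,
                                        AXIS_METRICS["speed"]),
            metrics=AXIS_METRICS["speed"], model=raw)

    def test_semantic_labels_invariant_to_state_permutation(self):
        """Swapping the model's internal state order leaves output fixed."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 2))
        mask = np.zeros(200, dtype=bool)
        seq_a = at.decode_states(self._make_model([0, 1]), X, mask, [200])
        seq_b = at.decode_states(self._make_model([1, 0]), X, mask, [200])
        assert np.array_equal(seq_a.labels, seq_b.labels)

    def test_high_state_is_fast_and_accurate(self, fitted):
        sm = fitted["speed_model"]
        speed_col = sm.metrics.index("speed")
        high, low = sm.state_order[1], sm.state_order[0]
        assert sm.means[high, speed_col] > sm.means[low, speed_col]
        am = fitted["acc_model"]
        hit_col = am.metrics.index("hit")
        high, low = am.state_order[1], am.state_order[0]
        assert am.means[high, hit_col] > am.means[low, hit_col]


class TestPosteriorOracle:
    """Posterior decoding against brute-force enumeration of all paths."""

    @staticmethod
    def _brute_force_posteriors(model, X):
        T = X.shape[0]
        K = model.n_components
        post = np.zeros((T, K))
        for path in itertools.product(range(K), repeat=T):
            logp = np.log(model.startprob_[path[0]])
            logp += multivariate_normal.logpdf(
                X[0], model.means_[path[0]], model.covars_[path[0]])
            for t in range(1, T):
                logp += np.log(model.transmat_[path[t - 1], path[t]])
                logp += multivariate_normal.logpdf(
                    X[t], model.means_[path[t]], model.covars_[path[t]])
            p = np.exp(logp)
            for t, k in enumerate(path):
                post[t, k] += p
        return post / post.sum(axis=1, keepdims=True)

    @pytest.mark.parametrize("T", [4, 6, 8])
    def test_posterior_matches_enumeration(self, T):
        rng = np.random.default_rng(T)
        model = GaussianHMM(n_components=2, covariance_type="full")
        model.n_features = 2
        model.startprob_ = np.array([0.6, 0.4])
        model.transmat_ = np.array([[0.85, 0.15], [0.3, 0.7]])
        model.means_ = np.array([[0.0, 0.5], [1.5, -0.5]])
        model.covars_ = np.array([np.eye(2) * 0.8, np.eye(2) * 1.2])
        X = rng.normal(size=(T, 2))
        expected = self._brute_force_posteriors(model, X)
        assert np.allclose(model.predict_proba(X), expected, atol=1e-8)


class TestConjunction:
    def _seq(self, axis, labels):
        names = {"speed": ("slow", "fast"),
                 "accuracy": ("inaccurate", "accurate")}[axis]
        return at.StateSequence(axis=axis,
                                labels=np.asarray(labels, dtype=np.int8),
                                session_lengths=[len(labels)],
                                state_names=names)

    def test_fast_accurate_is_efficient(self):
        comp = at.conjoin(self._seq("speed", [1]),
                          self._seq("accuracy", [1]))
        assert comp.state_names[comp.labels[0]] == "efficient"

    def test_slow_inaccurate_is_distracted(self):
        comp = at.conjoin(self._seq("speed", [0]),
                          self._seq("accuracy", [0]))
        assert comp.state_names[comp.labels[0]] == "distracted"

    def test_constant_inputs_give_constant_composite(self):
        comp = at.conjoin(self._seq("speed", [1] * 10),
                          self._seq("accuracy", [0] * 10))
        assert np.all(comp.labels == comp.labels[0])
        assert comp.state_names[comp.labels[0]] == "impulsive"

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            at.conjoin(self._seq("speed", [0, 1]),
                       self._seq("accuracy", [0]))

    def test_both_chains_visiting_both_states_give_four_labels(self, batch,
                                                               fitted):
        comp = fitted["composite"]
        assert set(np.unique(comp.labels)) == {0, 1, 2, 3}


class TestJointModel:
    def test_four_separated_clusters_recovered(self):
        means = at.synthetic._default_means().copy()
        means["hit"] = (0.1, 0.9)
        means["bias"] = (0.9, 0.1)
        means["precision"] = (0.55, 0.85)
        cfg = at.SyntheticConfig(n_sessions=4, trials_per_session=300,
                                 seed=6, emission_means=means)
        _, sessions, truth = at.simulate_sessions(cfg)
        frames, _ = at.preprocess_group(sessions)
        model, seq = at.fit_joint_hmm(frames, restarts=6, seed=0)
        assert model.means.shape[0] == 4
        occ = np.bincount(seq.labels, minlength=4) / len(seq.labels)
        assert np.all(occ > 0.05)

    def test_two_cluster_data_collapses_states(self):
        """With no accuracy-axis signal, states pair up on the 2 clusters.

        Unsmoothed input keeps the two speed clusters crisp (smoothing adds
        genuine intermediate ramp levels that a 4-state model can fit), so
        at least one pair of states must nearly coincide in the
        signal-carrying rt/speed dimensions.
        """
        means = at.synthetic._default_means().copy()
        means["hit"] = (0.5, 0.5)
        means["bias"] = (0.5, 0.5)
        means["precision"] = (0.7, 0.7)
        cfg = at.SyntheticConfig(
            n_sessions=4, trials_per_session=300, seed=7,
            emission_means=means,
            emission_sds={"precision": 0.02, "rt": 0.05, "speed": 3.0})
        _, sessions, _ = at.simulate_sessions(cfg)
        frames, _ = at.preprocess_group(sessions, smoothing_window=1)
        model, _ = at.fit_joint_hmm(frames, restarts=6, seed=0)
        cols = [list(at.METRICS).index(m) for m in ("rt", "speed")]
        d = np.array([np.linalg.norm(model.means[i][cols]
                                     - model.means[j][cols])
                      for i in range(4) for j in range(i + 1, 4)])
        assert d.min() < 0.2
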
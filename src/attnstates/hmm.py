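"""Latent attentional-state inference with Gaussian hidden Markov models.

One 2-state Gaussian HMM is fitted per performance axis (accuracy: hit,
bias, precision; speed: rt, speed) on the group's concatenated sessions.
Sessions are separated by 50 trials of a constant sentinel value; the model
is fitted with one extra state that absorbs this padding and is discarded,
so that state probabilities do not leak across session boundaries.  The two
binary sequences are conjoined into four composite attentional states:
distracted (slow, inaccurate), deliberate (slow, accurate), impulsive
(fast, inaccurate) and efficient (fast, accurate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .synthetic import ACC_METRICS, COMPOSITE_NAMES, SPEED_METRICS

AXIS_METRICS = {"accuracy": list(ACC_METRICS), "speed": list(SPEED_METRICS)}
AXIS_STATE_NAMES = {"accuracy": ("inaccurate", "accurate"),
                    "speed": ("slow", "fast")}

PAD_TRIALS = 50
PAD_VALUE = 10.0  # standardised units, far outside the data range


@dataclass
class HmmModel:
    """A fitted axis (or joint) model after removal of the padding state."""

    axis: str
    means: np.ndarray             # (n_real, d), real states only
    covars: np.ndarray            # (n_real, d, d)
    transmat: np.ndarray          # (n_real, n_real), renormalised
    startprob: np.ndarray
    log_likelihood: float
    pad_state: int | None
    state_order: np.ndarray       # semantic order -> raw state index
    metrics: list
    model: GaussianHMM = field(repr=False, default=None)
    loglik_trace: list = field(default_factory=list)


@dataclass
class StateSequence:
    axis: str
    labels: np.ndarray            # int8, 0 = low, 1 = high performance
    session_lengths: list
    state_names: tuple

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def boundaries(self) -> np.ndarray:
        """Start index of each session in the concatenated labels."""
        return np.concatenate(([0], np.cumsum(self.session_lengths)[:-1]))


@dataclass
class CompositeSequence:
    labels: np.ndarray            # int8 in 0..3, index = 2*speed + accuracy
    session_lengths: list
    state_names: tuple = COMPOSITE_NAMES

    def __len__(self) -> int:
        return int(self.labels.size)


def pad_sessions(frames, metrics, pad: int = PAD_TRIALS,
                 pad_value: float = PAD_VALUE):
    """Concatenate sessions with constant-valued pad trials in between.

    Returns the (T_total, d) observation matrix, a boolean pad mask and the
    per-session lengths.  A single session is returned unpadded.
    """
    blocks, mask, lengths = [], [], []
    pad_block = np.full((pad, len(metrics)), pad_value)
    for i, frame in enumerate(frames):
        X = frame[list(metrics)].to_numpy(dtype=float)
        if i > 0 and pad > 0:
            blocks.append(pad_block)
            mask.append(np.ones(pad, dtype=bool))
        blocks.append(X)
        mask.append(np.zeros(len(X), dtype=bool))
        lengths.append(len(X))
    return np.vstack(blocks), np.concatenate(mask), lengths


class _FlooredGaussianHMM(GaussianHMM):
    """GaussianHMM whose covariance eigenvalues are floored each M-step.

    Smoothed binary metrics have discretisation atoms (e.g. the all-zero
    5-trial window) on which an unconstrained Gaussian state collapses to
    near-zero variance for an unbounded likelihood gain; hmmlearn's
    ``min_covar`` is not enforced in the full-covariance M-step, so the
    floor is applied here by eigenvalue clipping.
    """

    def _do_mstep(self, stats):
        super()._do_mstep(stats)
        floored = []
        for cv in self._covars_:
            vals, vecs = np.linalg.eigh((cv + cv.T) / 2.0)
            vals = np.maximum(vals, self.min_covar)
            floored.append(vecs @ np.diag(vals) @ vecs.T)
        self._covars_ = np.asarray(floored)


def _fit_once(X, n_states, seed, tol, max_iter, min_covar):
    """One EM run from a kmeans initialisation.

    Means and covariances are seeded from a kmeans partition (per-cluster
    covariance, not the global one: initialising every state at the full
    data covariance lets EM collapse well-separated clusters into a single
    merged state).
    """
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=n_states, random_state=seed, n_init=4).fit(X)
        d = X.shape[1]
        covars = np.empty((n_states, d, d))
        for k in range(n_states):
            sub = X[km.labels_ == k]
            if len(sub) > d:
                cv = np.atleast_2d(np.cov(sub.T))
                vals, vecs = np.linalg.eigh((cv + cv.T) / 2.0)
                vals = np.maximum(vals, min_covar)
                covars[k] = vecs @ np.diag(vals) @ vecs.T
            else:
                covars[k] = np.eye(d)
        model = _FlooredGaussianHMM(
            n_components=n_states, covariance_type="full",
            n_iter=max_iter, tol=tol, random_state=seed,
            min_covar=min_covar, init_params="st")
        jitter = 0.05 * rng.standard_normal((n_states, d))
        model.means_ = km.cluster_centers_ + jitter
        model.covars_ = covars
        model.fit(X)
    return model, float(model.score(X))


def fit_axis_hmm(X: np.ndarray, pad_mask: np.ndarray, axis: str = "accuracy",
                 n_real_states: int = 2, restarts: int = 10,
                 tol: float = 1e-4, max_iter: int = 500, seed: int = 0,
                 pad_occupancy_min: float = 0.9, min_covar: float = 0.05,
                 metrics: list | None = None) -> HmmModel:
    """Fit a Gaussian HMM with one extra padding-absorbing state.

    The best of ``restarts`` random initialisations (by log-likelihood) is
    kept.  When the data contain pad trials, the state with the highest
    occupancy on them is identified as the padding state and removed; its
    occupancy on pads must reach ``pad_occupancy_min``, otherwise the
    sentinel value did not separate and an error asks for a different
    ``pad_value``.
    """
    if not np.all(np.isfinite(X)):
        raise ValueError("observations must be finite (mask NaNs upstream)")
    has_pads = bool(pad_mask.any())
    n_states = n_real_states + (1 if has_pads else 0)
    seeds = np.random.SeedSequence(seed).generate_state(restarts)
    best, best_ll, best_pad = None, -np.inf, None
    pad_fail = False
    for s in seeds:
        try:
            model, ll = _fit_once(X, n_states, int(s % (2 ** 31)), tol,
                                  max_iter, min_covar)
        except (ValueError, np.linalg.LinAlgError):
            continue
        pad_state = None
        if has_pads:
            hard = model.predict(X)
            occ = np.bincount(hard[pad_mask],
                              minlength=n_states) / pad_mask.sum()
            pad_state = int(np.argmax(occ))
            if occ[pad_state] < pad_occupancy_min:
                pad_fail = True
                continue
            # for the 2-state axis fits, reject solutions in which a second
            # state also sits on the padding cluster and a single state
            # absorbs all real trials; over-parameterised joint fits may
            # legitimately leave a state (near-)empty
            if n_real_states == 2:
                real_occ = np.bincount(hard[~pad_mask],
                                       minlength=n_states) \
                    / (~pad_mask).sum()
                if any(real_occ[k] < 0.01 for k in range(n_states)
                       if k != pad_state):
                    continue
        # reject near-singular real states: on standardised (and, for the
        # binaries, smoothed) inputs the likelihood is unbounded for a
        # component collapsing onto a discretisation atom
        eigs = [np.linalg.eigvalsh(model.covars_[k]).min()
                for k in range(n_states) if k != pad_state]
        if min(eigs) < 0.99 * min_covar:
            continue
        if ll > best_ll:
            best, best_ll, best_pad = model, ll, pad_state
    if best is None:
        if pad_fail:
            raise RuntimeError(
                "padding state not separable from the data in any restart; "
                "use a different pad_value")
        raise RuntimeError("all HMM restarts failed or were degenerate; "
                           "increase restarts or change pad_value")
    pad_state = best_pad

    keep = [k for k in range(n_states) if k != pad_state]
    transmat = best.transmat_[np.ix_(keep, keep)]
    transmat = transmat / transmat.sum(axis=1, keepdims=True)
    startprob = best.startprob_[keep]
    startprob = startprob / max(startprob.sum(), 1e-300)
    metrics = metrics if metrics is not None else AXIS_METRICS.get(axis)
    model = HmmModel(axis=axis, means=best.means_[keep],
                     covars=best.covars_[keep], transmat=transmat,
                     startprob=startprob, log_likelihood=best_ll,
                     pad_state=pad_state,
                     state_order=_semantic_order(axis, best.means_[keep],
                                                 metrics),
                     metrics=list(metrics) if metrics else [],
                     model=best)
    return model


def _semantic_order(axis, means, metrics):
    """Raw state indices ordered as (low-performance, high-performance).

    Speed axis: the *fast* state has the higher standardised movement speed
    (reaction time should be lower; a contradiction is resolved by the
    first-listed metric with a warning).  Accuracy axis: the *accurate*
    state has the higher mean hit rate.  Joint/other axes keep raw order.
    """
    if metrics is None or axis not in AXIS_METRICS or means.shape[0] != 2:
        return np.arange(means.shape[0])
    if axis == "speed":
        primary = metrics.index("speed") if "speed" in metrics else 0
        high = int(np.argmax(means[:, primary]))
        if "rt" in metrics:
            rt_col = metrics.index("rt")
            if means[high, rt_col] > means[1 - high, rt_col]:
                warnings.warn("speed-axis labelling ambiguous: state with "
                              "higher speed also has higher RT; labelled by "
                              "movement speed")
    else:
        primary = metrics.index("hit") if "hit" in metrics else 0
        high = int(np.argmax(means[:, primary]))
    return np.array([1 - high, high])


def decode_states(model: HmmModel, X: np.ndarray, pad_mask: np.ndarray,
                  session_lengths: list,
                  method: str = "map") -> StateSequence:
    """Per-trial state labels (pads dropped, semantically canonicalised).

    ``method='map'`` takes the per-trial posterior argmax (the default, as
    states are reported trial by trial); ``'viterbi'`` returns the single
    most probable path.
    """
    raw = model.model
    if method == "viterbi":
        hard = raw.predict(X)
    else:
        post = raw.predict_proba(X)
        if model.pad_state is not None:
            keep = [k for k in range(post.shape[1]) if k != model.pad_state]
            sub = post[:, keep]
            hard_keep = np.argmax(sub, axis=1)
            hard = np.array(keep)[hard_keep]
        else:
            hard = np.argmax(post, axis=1)
    hard = hard[~pad_mask]
    keep = [k for k in range(raw.n_components) if k != model.pad_state]
    remap = -np.ones(raw.n_components, dtype=int)
    for compact, k in enumerate(keep):
        remap[k] = compact
    compact = remap[hard]
    if model.pad_state is not None and np.any(compact < 0):
        # real trials decoded into the padding state: snap to nearest real
        # state by Mahalanobis-free Euclidean distance to the state means
        bad = compact < 0
        d = np.linalg.norm(X[~pad_mask][bad][:, None, :]
                           - model.means[None, :, :], axis=2)
        compact[bad] = np.argmin(d, axis=1)
    if model.means.shape[0] == 2:
        # canonicalise: label 1 = high-performance state
        semantic = np.zeros_like(compact)
        semantic[compact == model.state_order[1]] = 1
    else:
        semantic = compact
    names = AXIS_STATE_NAMES.get(model.axis,
                                 tuple(f"state{k}"
                                       for k in range(model.means.shape[0])))
    return StateSequence(axis=model.axis, labels=semantic.astype(np.int8),
                         session_lengths=list(session_lengths),
                         state_names=names)


def conjoin(speed: StateSequence, acc: StateSequence) -> CompositeSequence:
    """Four-way composite labels: index = 2 * speed_label + accuracy_label."""
    if len(speed) != len(acc) or speed.session_lengths != acc.session_lengths:
        raise ValueError("speed and accuracy sequences are not aligned")
    labels = (2 * speed.labels + acc.labels).astype(np.int8)
    return CompositeSequence(labels=labels,
                             session_lengths=list(speed.session_lengths))


def fit_axis(frames, axis: str, pad: int = PAD_TRIALS,
             pad_value: float = PAD_VALUE, **fit_kwargs):
    """Pad, fit and decode one axis in a single call."""
    metrics = AXIS_METRICS[axis]
    X, pad_mask, lengths = pad_sessions(frames, metrics, pad, pad_value)
    model = fit_axis_hmm(X, pad_mask, axis=axis, metrics=metrics,
                         **fit_kwargs)
    seq = decode_states(model, X, pad_mask, lengths)
    return model, seq


def fit_joint_hmm(frames, n_real_states: int = 4, pad: int = PAD_TRIALS,
                  pad_value: float = PAD_VALUE, **fit_kwargs):
    """Single HMM over all five metrics (comparison fit).

    Same padding logic as the axis models; the extra state absorbs the pads
    and is discarded.  State labels are in raw model order (no semantic
    canonicalisation is defined for the joint fit).
    """
    from .synthetic import METRICS

    X, pad_mask, lengths = pad_sessions(frames, list(METRICS), pad, pad_value)
    model = fit_axis_hmm(X, pad_mask, axis="joint",
                         n_real_states=n_real_states, metrics=list(METRICS),
                         **fit_kwargs)
    seq = decode_states(model, X, pad_mask, lengths)
    return model, seq


def em_loglik_trace(X: np.ndarray, n_states: int, seed: int = 0,
                    n_iter: int = 30) -> list:
    """Per-iteration log-likelihoods of a single EM run (diagnostic).

    Runs EM one step at a time from a fixed initialisation so the full
    trace is observable; the likelihood must be non-decreasing.
    """
    model = GaussianHMM(n_components=n_states, covariance_type="full",
                        n_iter=1, tol=-np.inf, random_state=seed,
                        min_covar=1e-3, covars_prior=0.0,
                        init_params="stmc")
    trace = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_iter):
            model.fit(X)
            trace.append(float(model.score(X)))
            model.init_params = ""  # keep parameters on subsequent steps
    return trace


def sequences_frame(session_ids, speed: StateSequence, acc: StateSequence,
                    composite: CompositeSequence,
                    trial_indices) -> pd.DataFrame:
    """Tidy CSV-ready table of per-trial state labels."""
    return pd.DataFrame({
        "session_id": session_ids,
        "trial_index": trial_indices,
        "speed_state": np.asarray(speed.state_names)[speed.labels],
        "acc_state": np.asarray(acc.state_names)[acc.labels],
        "composite_state": np.asarray(composite.state_names)[composite.labels],
    })
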
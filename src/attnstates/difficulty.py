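"""Task difficulty around state transitions.

If state switches were triggered by task attributes rather than internally
generated, trials around a transition would be systematically easier or
harder than average.  This module averages the difficulty series aligned to
transitions of a requested direction and compares the curve to shuffled
controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import _empirical_p, _split


@dataclass
class TransitionLockedCurve:
    offsets: np.ndarray          # relative trial offsets, transition at 0
    mean_difficulty: np.ndarray
    reference: float             # overall mean difficulty
    null_lo: np.ndarray
    null_hi: np.ndarray
    null_min: np.ndarray
    null_max: np.ndarray
    p_values: np.ndarray
    flags: np.ndarray
    n_transitions: int


def _transition_times(labels: np.ndarray, direction: str) -> np.ndarray:
    """Session-local indices t where the state changes in the requested
    direction between t-1 and t (t is the first trial of the new state)."""
    if direction == "low_to_high":
        hits = (labels[:-1] == 0) & (labels[1:] == 1)
    elif direction == "high_to_low":
        hits = (labels[:-1] == 1) & (labels[1:] == 0)
    elif direction == "any":
        hits = labels[:-1] != labels[1:]
    else:
        raise ValueError("direction must be low_to_high, high_to_low or any")
    return np.flatnonzero(hits) + 1


def _curve(diff_sessions, times_per_session, window):
    offsets = np.arange(-window, window + 1)
    acc = np.zeros(offsets.size)
    n = 0
    for d, times in zip(diff_sessions, times_per_session):
        ok = times[(times - window >= 0) & (times + window < d.size)]
        for t in ok:
            acc += d[t - window:t + window + 1]
        n += ok.size
    return (acc / n if n else np.full(offsets.size, np.nan)), n


def difficulty_around_transitions(difficulty: np.ndarray,
                                  labels: np.ndarray, session_lengths,
                                  direction: str = "any", window: int = 10,
                                  n_shuffle: int = 1000,
                                  null: str = "positions",
                                  alpha: float = 0.05,
                                  rng: np.random.Generator | None = None
                                  ) -> TransitionLockedCurve:
    """Mean difficulty at offsets -window..+window around transitions.

    Only transitions with the full window inside their session qualify.
    ``null='positions'`` (default) redraws the same number of transition
    times uniformly within each session, preserving the difficulty series'
    autocorrelation; ``null='difficulty'`` instead shuffles the difficulty
    values within sessions while keeping the real transition times.
    """
    rng = rng or np.random.default_rng()
    diff_sessions = _split(np.asarray(difficulty, dtype=float),
                           session_lengths)
    lab_sessions = _split(np.asarray(labels), session_lengths)
    times = [_transition_times(lab, direction) for lab in lab_sessions]
    observed, n_trans = _curve(diff_sessions, times, window)
    offsets = np.arange(-window, window + 1)
    if n_trans == 0:
        warnings.warn("no qualifying transitions; returning an empty curve")
        nanv = np.full(offsets.size, np.nan)
        return TransitionLockedCurve(offsets, nanv, float("nan"), nanv, nanv,
                                     nanv, nanv, nanv,
                                     np.zeros(offsets.size, bool), 0)

    counts = [t[(t - window >= 0) & (t + window < d.size)].size
              for t, d in zip(times, diff_sessions)]
    null_curves = np.empty((n_shuffle, offsets.size))
    for b in range(n_shuffle):
        if null == "positions":
            fake = [rng.integers(window, d.size - window, size=c)
                    if c else np.empty(0, dtype=int)
                    for d, c in zip(diff_sessions, counts)]
            null_curves[b], _ = _curve(diff_sessions, fake, window)
        elif null == "difficulty":
            shuffled = [rng.permutation(d) for d in diff_sessions]
            null_curves[b], _ = _curve(shuffled, times, window)
        else:
            raise ValueError("null must be 'positions' or 'difficulty'")

    p = np.array([_empirical_p(observed[i], null_curves[:, i])
                  for i in range(offsets.size)])
    lo = np.percentile(null_curves, 100 * alpha / 2, axis=0)
    hi = np.percentile(null_curves, 100 * (1 - alpha / 2), axis=0)
    return TransitionLockedCurve(
        offsets=offsets, mean_difficulty=observed,
        reference=float(np.concatenate(diff_sessions).mean()),
        null_lo=lo, null_hi=hi,
        null_min=null_curves.min(axis=0), null_max=null_curves.max(axis=0),
        p_values=p, flags=(observed < lo) | (observed > hi),
        n_transitions=n_trans)
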
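"""Session-level preprocessing of the five behavioural metrics.

Fixed pipeline order: trial filtering -> (human) learning cutoff ->
quadratic detrend of the continuous metrics -> 5-trial centred smoothing
-> per-session standardisation.  Sessions are preprocessed independently
and concatenated per group afterwards.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthetic import METRICS

CONTINUOUS = ("precision", "rt", "speed")  # detrended; binaries are not

MAX_DURATION_S = 10.0
MIN_PATH_LENGTH = 250.0


def filter_trials(trials: pd.DataFrame,
                  max_duration_s: float = MAX_DURATION_S,
                  min_path_length: float = MIN_PATH_LENGTH) -> np.ndarray:
    """Retention mask: drop missing values, over-long and too-short trials."""
    complete = trials[list(METRICS)].notna().all(axis=1).to_numpy()
    dur_ok = trials["duration_s"].to_numpy() <= max_duration_s
    len_ok = trials["path_length"].to_numpy() >= min_path_length
    return complete & dur_ok & len_ok


def learning_cutoff(session: pd.DataFrame, rolling_window: int = 20,
                    tol: float = 1.0) -> int:
    """First trial from which RT and speed have stabilised.

    Rolling means of both metrics are compared with the mean of the second
    half of the session; the cutoff is the first index from which both stay
    within ``tol`` second-half SDs for the rest of the session.
    """
    T = len(session)
    if T < 2 * rolling_window:
        warnings.warn("session too short for a learning cutoff; returning 0")
        return 0
    cutoff = 0
    for metric in ("rt", "speed"):
        x = session[metric].to_numpy(dtype=float)
        half = x[T // 2:]
        mu, sd = np.nanmean(half), np.nanstd(half)
        roll = pd.Series(x).rolling(rolling_window, min_periods=1,
                                    center=True).mean().to_numpy()
        outside = np.abs(roll - mu) > tol * max(sd, 1e-12)
        idx = np.flatnonzero(outside)
        first_stable = 0 if idx.size == 0 else int(idx[-1]) + 1
        cutoff = max(cutoff, first_stable)
    return min(cutoff, T - 1)


def detrend_quadratic(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares quadratic in trial index (NaN-safe)."""
    x = np.asarray(series, dtype=float)
    out = x.copy()
    good = np.isfinite(x)
    if good.sum() < 3:
        return out
    t = np.arange(x.size, dtype=float)
    poly = np.polynomial.Polynomial.fit(t[good], x[good], deg=2)
    out[good] = x[good] - poly(t[good])
    return out


def smooth_centered(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred rolling mean; shrinking windows at the edges, NaNs skipped."""
    if window < 1:
        raise ValueError("window must be >= 1")
    return (pd.Series(np.asarray(series, dtype=float))
            .rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def standardise(series: np.ndarray) -> np.ndarray:
    """Zero mean, unit SD; zero-variance input raises (caller masks it)."""
    x = np.asarray(series, dtype=float)
    good = np.isfinite(x)
    sd = np.nanstd(x)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("zero variance: cannot standardise")
    return (x - np.nanmean(x)) / sd


def preprocess_session(session: pd.DataFrame, is_human: bool = False,
                       smoothing_window: int = 5, rolling_window: int = 20,
                       cutoff_tol: float = 1.0,
                       max_duration_s: float = MAX_DURATION_S,
                       min_path_length: float = MIN_PATH_LENGTH):
    """Run the full per-session pipeline.

    Returns the processed frame (retained trials only, metric columns
    transformed in place, original ``trial_index`` preserved) and a report
    dict with exclusion counts and the learning cutoff.
    """
    mask = filter_trials(session, max_duration_s, min_path_length)
    report = {
        "n_trials": int(len(session)),
        "n_excluded": int((~mask).sum()),
        "learning_cutoff": 0,
    }
    kept = session.loc[mask].reset_index(drop=True)

    if is_human and len(kept) > 0:
        cut = learning_cutoff(kept, rolling_window, cutoff_tol)
        report["learning_cutoff"] = int(cut)
        kept = kept.iloc[cut:].reset_index(drop=True)

    kept = kept.copy()
    for m in CONTINUOUS:
        kept[m] = detrend_quadratic(kept[m].to_numpy())
    for m in METRICS:
        kept[m] = smooth_centered(kept[m].to_numpy(), smoothing_window)
    masked_metrics = []
    for m in METRICS:
        try:
            kept[m] = standardise(kept[m].to_numpy())
        except ValueError:
            warnings.warn(f"metric {m!r} has zero variance in session "
                          f"{kept['session_id'].iloc[0] if len(kept) else '?'};"
                          " masked")
            kept[m] = np.nan
            masked_metrics.append(m)
    report["masked_metrics"] = masked_metrics
    report["n_retained"] = int(len(kept))
    return kept, report


def preprocess_group(sessions, is_human: bool = False, **kwargs):
    """Preprocess each session independently; return frames + reports."""
    frames, reports = [], []
    for sess in sessions:
        frame, report = preprocess_session(sess, is_human=is_human, **kwargs)
        frames.append(frame)
        reports.append(report)
    return frames, reports
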
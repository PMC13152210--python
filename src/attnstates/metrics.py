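"""Per-trial behavioural metrics from VR trajectories and trial outcomes.

Five metrics summarise each trial: a binary hit indicator, a binary
side-perseveration bias, endpoint precision in [0, 1], reaction time
(first significant heading change, in seconds) and average movement
speed (path length over duration, VR units/s).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LEFT, RIGHT = "L", "R"


def side_of_endpoint(x: float) -> str:
    """Sign convention: lateral endpoint < 0 is left, >= 0 is right."""
    return LEFT if x < 0 else RIGHT


def compute_hit(outcome: str) -> int:
    """1 for a correct trial, 0 for incorrect or miss."""
    if outcome not in ("correct", "incorrect", "miss"):
        raise ValueError(f"unknown outcome {outcome!r}")
    return int(outcome == "correct")


def compute_bias(chosen_side: str, prev_chosen_side: str | None,
                 target_side: str) -> int:
    """1 iff the previous choice was repeated although the target switched.

    The first trial of a session (no predecessor) and miss trials (no choice
    made) score 0.
    """
    if prev_chosen_side is None or chosen_side == "none" \
            or prev_chosen_side == "none":
        return 0
    return int(chosen_side == prev_chosen_side and target_side != chosen_side)


def compute_speed(path: pd.DataFrame) -> float:
    """Total path length divided by trial duration (VR units/s)."""
    t = path["time"].to_numpy()
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("path needs >= 2 samples with strictly increasing time")
    dx = np.diff(path["lateral"].to_numpy())
    dy = np.diff(path["forward"].to_numpy())
    length = np.sqrt(dx ** 2 + dy ** 2).sum()
    return float(length / (t[-1] - t[0]))


def compute_precision(endpoint: np.ndarray, side: str,
                      correct_endpoints: dict, norm_distance: float) -> float:
    """Closeness of an endpoint to the session's mean correct endpoint.

    ``correct_endpoints`` maps side -> (n, 2) array of correct-response
    endpoints for that side in the same session.  Returns
    1 - distance / norm_distance, clipped to [0, 1].  Raises if the side has
    no correct endpoints (the caller should mask the trial).
    """
    pts = np.asarray(correct_endpoints.get(side, ()), dtype=float)
    if pts.size == 0:
        raise ValueError(f"no correct endpoints for side {side!r}")
    centre = pts.reshape(-1, 2).mean(axis=0)
    d = float(np.linalg.norm(np.asarray(endpoint, dtype=float) - centre))
    return float(np.clip(1.0 - d / norm_distance, 0.0, 1.0))


def detect_reaction_time(path: pd.DataFrame, window_s: float = 0.25,
                         decay_half_life_s: float | None = None,
                         threshold_k: float = 3.0,
                         baseline_frac: float = 0.2) -> float | None:
    """Reaction time from the lateral trajectory.

    A sliding-window linear regression of lateral position on time is run
    with exponentially decaying weights (recent samples weighted more;
    half-life defaults to the window length).  The reported RT is the first
    time at which the absolute regression slope exceeds
    ``threshold_k`` * MAD of the early-trial baseline slopes.  Returns None
    when no turn is detected.
    """
    t = path["time"].to_numpy(dtype=float)
    x = path["lateral"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("path needs >= 2 samples")
    dt = np.median(np.diff(t))
    w = max(int(round(window_s / dt)), 3)
    if t.size < w:
        raise ValueError("fewer samples than the regression window")
    if decay_half_life_s is None:
        decay_half_life_s = window_s
    ages = (np.arange(w)[::-1]) * dt  # age of each in-window sample
    weights = 0.5 ** (ages / decay_half_life_s)

    n = t.size
    slopes = np.full(n, np.nan)
    tw = np.lib.stride_tricks.sliding_window_view(t, w)   # (n-w+1, w)
    xw = np.lib.stride_tricks.sliding_window_view(x, w)
    wsum = weights.sum()
    tc = tw - (tw * weights).sum(axis=1, keepdims=True) / wsum
    xc = xw - (xw * weights).sum(axis=1, keepdims=True) / wsum
    denom = (weights * tc ** 2).sum(axis=1)
    slopes[w - 1:] = (weights * tc * xc).sum(axis=1) / denom

    valid = slopes[w - 1:]
    n_base = max(int(round(baseline_frac * valid.size)), 3)
    base = valid[:n_base]
    # robust sigma estimate of baseline slope noise (MAD * 1.4826)
    sigma = 1.4826 * np.median(np.abs(base - np.median(base)))
    threshold = threshold_k * max(sigma, 1e-12)
    above = np.abs(slopes) > threshold
    # overlapping windows make noise excursions persist ~1 window, so a
    # genuine turn must hold the slope above threshold for half a window
    sustain = max(w // 2, 2)
    run = 0
    for i in range(above.size):
        run = run + 1 if above[i] else 0
        if run >= sustain:
            # back-track from the crossing to the turn onset: the last
            # sample at which the slope was still at baseline noise level
            j = i - run + 1
            while j > 0 and np.isfinite(slopes[j - 1]) \
                    and abs(slopes[j - 1]) > max(sigma, 1e-12):
                j -= 1
            return float(t[j])
    return None


def session_metrics(trials: pd.DataFrame, paths: dict | None = None,
                    norm_distance: float = 500.0,
                    rt_kwargs: dict | None = None) -> pd.DataFrame:
    """Compute the five metrics for one session's trial table.

    ``paths`` maps trial_index -> trajectory frame; when absent, RT and
    speed are taken from pre-computed columns if present, else left NaN.
    Precision is NaN (masked) for miss trials and for sides without any
    correct endpoint.
    """
    trials = trials.sort_values("trial_index").reset_index(drop=True)
    rt_kwargs = rt_kwargs or {}
    correct = trials[trials["outcome"] == "correct"]
    correct_endpoints = {
        side: sub[["endpoint_x", "endpoint_y"]].to_numpy()
        for side, sub in correct.groupby("chosen_side") if side != "none"
    }

    out = []
    prev_side: str | None = None
    for _, row in trials.iterrows():
        hit = compute_hit(row["outcome"])
        bias = compute_bias(row["chosen_side"], prev_side, row["target_side"])
        if row["outcome"] != "miss":
            prev_side = row["chosen_side"]

        precision = np.nan
        if row["outcome"] != "miss" and np.isfinite(row["endpoint_x"]):
            side = side_of_endpoint(row["endpoint_x"])
            try:
                precision = compute_precision(
                    (row["endpoint_x"], row["endpoint_y"]), side,
                    correct_endpoints, norm_distance)
            except ValueError:
                precision = np.nan

        rt, speed = np.nan, np.nan
        if paths is not None and row["trial_index"] in paths:
            path = paths[row["trial_index"]]
            speed = compute_speed(path)
            det = detect_reaction_time(path, **rt_kwargs)
            rt = np.nan if det is None else det
        else:
            rt = row.get("rt", np.nan)
            speed = row.get("speed", np.nan)

        out.append((row["session_id"], row["trial_index"],
                    hit, bias, precision, rt, speed))
    return pd.DataFrame(out, columns=["session_id", "trial_index",
                                      "hit", "bias", "precision",
                                      "rt", "speed"])
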
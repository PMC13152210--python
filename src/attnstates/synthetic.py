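"""Synthetic VR-trial behaviour generator.

Simulates sessions of a two-alternative navigation task in which five
behavioural metrics (hit, bias, precision, reaction time, movement speed)
are driven by two latent binary Markov chains: an *accuracy* chain (drives
hit, bias, precision) and a *speed* chain (drives reaction time and speed).
Optional features mirror structure seen in real sessions: a slow rhythmic
modulation of the speed chain, slow quadratic drift of the continuous
metrics, a human-like early learning transient, and per-trial difficulty
levels that shift error probability and reaction time.

Each emitted metric depends only on its own axis chain; cross-talk between
the axes is available but off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

METRICS = ("hit", "bias", "precision", "rt", "speed")
ACC_METRICS = ("hit", "bias", "precision")
SPEED_METRICS = ("rt", "speed")

#: composite labels indexed by 2 * speed_state + acc_state
COMPOSITE_NAMES = ("distracted", "deliberate", "impulsive", "efficient")


def _default_means() -> dict:
    # per metric: (low-state value, high-state value) on the metric's own axis.
    # hit/bias are Bernoulli rates; precision/rt/speed are truncated-Gaussian means.
    return {
        "hit": (0.55, 0.90),
        "bias": (0.40, 0.05),
        # precision couples only weakly to the accuracy chain, as in real
        # sessions where it tracks motor execution more than the decision
        "precision": (0.68, 0.72),
        "rt": (1.8, 1.0),         # seconds; fast state turns earlier
        "speed": (120.0, 180.0),  # VR units / s; typical paths ~500-700 units
    }


def _default_sds() -> dict:
    return {"precision": 0.10, "rt": 0.40, "speed": 30.0}


@dataclass
class SyntheticConfig:
    """Generation parameters for a batch of sessions.

    ``rhythm_period`` (trials), when set, replaces the Markov speed chain by a
    square wave of that period whose label is flipped per trial with
    probability ``rhythm_flip_p`` — a binary sequence with a controllable
    planted period.
    """

    n_sessions: int = 10
    trials_per_session: int = 500
    group: str = "synthetic"
    speed_self_p: float = 0.85
    acc_self_p: float = 0.85
    rhythm_period: int | None = None
    rhythm_flip_p: float = 0.15
    emission_means: dict = field(default_factory=_default_means)
    emission_sds: dict = field(default_factory=_default_sds)
    drift_coeffs: dict = field(default_factory=dict)  # metric -> (a2, a1) on t/T
    learning_transient: bool = False
    learning_len: int = 50
    difficulty_levels: tuple = (0.2, 0.4, 0.6, 0.8)
    difficulty_weights: tuple | None = None
    difficulty_effect: float = 0.0
    mean_trial_duration_s: float = 4.0
    duration_log_sd: float = 0.35
    miss_frac: float = 0.15  # fraction of non-correct outcomes that are misses
    cross_talk: float = 0.0
    norm_distance: float = 500.0  # VR units, scene constant used by precision
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (("speed_self_p", self.speed_self_p),
                        ("acc_self_p", self.acc_self_p),
                        ("rhythm_flip_p", self.rhythm_flip_p),
                        ("miss_frac", self.miss_frac)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for m, (lo, hi) in self.emission_means.items():
            if m in ("hit", "bias") and not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise ValueError(f"Bernoulli rate for {m} outside [0, 1]")
        for m, sd in self.emission_sds.items():
            if sd <= 0:
                raise ValueError(f"emission SD for {m} must be > 0, got {sd}")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.rhythm_period is not None and self.rhythm_period < 2:
            raise ValueError("rhythm_period must be >= 2 trials")

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list, indent=2)


@dataclass
class GroundTruth:
    """Latent per-trial chain states across all sessions, concatenated."""

    speed_states: np.ndarray      # int8, 0 = slow, 1 = fast
    acc_states: np.ndarray        # int8, 0 = inaccurate, 1 = accurate
    session_lengths: list

    @property
    def composite_states(self) -> np.ndarray:
        return (2 * self.speed_states + self.acc_states).astype(np.int8)

    def per_session(self, attr: str) -> list:
        values = getattr(self, attr)
        out, start = [], 0
        for n in self.session_lengths:
            out.append(values[start:start + n])
            start += n
        return out


def _markov_chain(n: int, self_p: float, rng: np.random.Generator) -> np.ndarray:
    states = np.empty(n, dtype=np.int8)
    states[0] = rng.integers(2)
    flips = rng.random(n - 1) >= self_p if n > 1 else np.empty(0, dtype=bool)
    for t in range(1, n):
        states[t] = states[t - 1] ^ flips[t - 1]
    return states

def _rhythmic_chain(n: int, period: int, flip_p: float,
                    rng: np.random.Generator) -> np.ndarray:
    phase = rng.integers(period)
    base = (((np.arange(n) + phase) % period) < period / 2).astype(np.int8)
    flips = rng.random(n) < flip_p
    return base ^ flips


def _truncated_normal(mean, sd, lo, hi, rng) -> np.ndarray:
    """Rejection-free clipped Gaussian; adequate when truncation is mild."""
    x = rng.normal(mean, sd)
    return np.clip(x, lo, hi)


def simulate_sessions(config: SyntheticConfig):
    """Generate a trial table, per-session metric frames, and ground truth.

    Returns
    -------
    trials : pandas.DataFrame
        One row per trial: session_id, group, trial_index, outcome,
        chosen_side, target_side, difficulty, duration_s, path_length,
        endpoint_x, endpoint_y plus the five raw metric columns.
    sessions : list of pandas.DataFrame
        Per-session metric frames (the HMM observation source).
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)
    T = config.trials_per_session
    means, sds = config.emission_means, config.emission_sds
    levels = np.asarray(config.difficulty_levels, dtype=float)
    weights = config.difficulty_weights
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    d_mean = float(np.average(levels, weights=weights))

    rows, session_frames = [], []
    speed_all, acc_all, lengths = [], [], []

    for s in range(config.n_sessions):
        if config.rhythm_period is not None:
            speed_chain = _rhythmic_chain(T, config.rhythm_period,
                                          config.rhythm_flip_p, rng)
        else:
            speed_chain = _markov_chain(T, config.speed_self_p, rng)
        acc_chain = _markov_chain(T, config.acc_self_p, rng)

        difficulty = rng.choice(levels, size=T, p=weights)
        t_norm = np.arange(T) / max(T - 1, 1)

        # accuracy axis, optionally nudged by the speed chain (cross-talk)
        acc_level = acc_chain + config.cross_talk * (speed_chain - 0.5)
        p_hit = np.clip(means["hit"][0]
                        + (means["hit"][1] - means["hit"][0]) * acc_level
                        - config.difficulty_effect * (difficulty - d_mean),
                        0.0, 1.0)
        p_bias = np.clip(means["bias"][0]
                         + (means["bias"][1] - means["bias"][0]) * acc_level,
                         0.0, 1.0)
        hit = (rng.random(T) < p_hit).astype(float)
        bias = (rng.random(T) < p_bias).astype(float)
        mu_prec = means["precision"][0] \
            + (means["precision"][1] - means["precision"][0]) * acc_level
        precision = _truncated_normal(mu_prec, sds["precision"], 0.0, 1.0, rng)

        speed_level = speed_chain + config.cross_talk * (acc_chain - 0.5)
        mu_rt = means["rt"][0] + (means["rt"][1] - means["rt"][0]) * speed_level \
            + 0.25 * config.difficulty_effect * (difficulty - d_mean)
        rt = _truncated_normal(mu_rt, sds["rt"], 0.05, np.inf, rng)
        mu_speed = means["speed"][0] \
            + (means["speed"][1] - means["speed"][0]) * speed_level
        speed = _truncated_normal(mu_speed, sds["speed"], 1.0, np.inf, rng)

        # slow quadratic drift on the continuous metrics
        for m, series in (("precision", precision), ("rt", rt), ("speed", speed)):
            if m in config.drift_coeffs:
                a2, a1 = config.drift_coeffs[m]
                series += a2 * t_norm ** 2 + a1 * t_norm

        # human-like early learning transient: slow, sluggish start
        if config.learning_transient:
            L = config.learning_len
            decay = np.exp(-3.0 * np.arange(T) / max(L, 1))
            rt = rt + 1.2 * decay
            speed = np.maximum(speed - 15.0 * decay, 1.0)

        duration = rng.lognormal(np.log(config.mean_trial_duration_s),
                                 config.duration_log_sd, size=T)
        duration = np.maximum(duration, np.minimum(rt * 1.05, 9.0))

        # outcome / side bookkeeping consistent with hit and bias
        outcome = np.where(hit == 1, "correct",
                           np.where(rng.random(T) < config.miss_frac,
                                    "miss", "incorrect"))
        target = rng.choice(["L", "R"], size=T)
        chosen = np.where(outcome == "correct", target,
                          np.where(target == "L", "R", "L"))
        chosen = np.where(outcome == "miss", "none", chosen)

        # miss trials have no endpoint: RT and precision are undefined
        rt = np.where(outcome == "miss", np.nan, rt)
        precision_obs = np.where(outcome == "miss", np.nan, precision)

        path_length = speed * duration
        endpoint_x = np.where(chosen == "L", -150.0, 150.0) \
            + rng.normal(0, 15.0, T)
        endpoint_x = np.where(chosen == "none", np.nan, endpoint_x)
        endpoint_y = np.where(chosen == "none", np.nan,
                              400.0 + rng.normal(0, 10.0, T))

        frame = pd.DataFrame({
            "session_id": f"{config.group}_s{s:02d}",
            "group": config.group,
            "trial_index": np.arange(T),
            "outcome": outcome,
            "chosen_side": chosen,
            "target_side": target,
            "difficulty": difficulty,
            "duration_s": duration,
            "path_length": path_length,
            "endpoint_x": endpoint_x,
            "endpoint_y": endpoint_y,
            "hit": hit,
            "bias": bias,
            "precision": precision_obs,
            "rt": rt,
            "speed": speed,
        })
        rows.append(frame)
        session_frames.append(frame)
        speed_all.append(speed_chain)
        acc_all.append(acc_chain)
        lengths.append(T)

    trials = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(np.concatenate(speed_all), np.concatenate(acc_all),
                        lengths)
    return trials, session_frames, truth


def simulate_trajectory(duration_s: float, turn_time_s: float | None,
                        side: str = "R", noise_sd: float = 0.0,
                        sample_hz: float = 50.0, forward_speed: float = 50.0,
                        lateral_rate: float = 80.0,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Simulate one 2D VR path: straight ahead, then a drift toward ``side``.

    ``turn_time_s=None`` produces a no-turn path (a miss). Additive Gaussian
    noise of ``noise_sd`` VR units is applied to the lateral coordinate.
    """
    if turn_time_s is not None and turn_time_s >= duration_s:
        raise ValueError("turn_time_s must be smaller than duration_s")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / sample_hz)
    forward = forward_speed * t
    lateral = np.zeros_like(t)
    if turn_time_s is not None:
        sign = -1.0 if side == "L" else 1.0
        post = t > turn_time_s
        lateral[post] = sign * lateral_rate * (t[post] - turn_time_s)
    if noise_sd > 0:
        lateral = lateral + rng.normal(0.0, noise_sd, size=t.size)
    return pd.DataFrame({"time": t, "lateral": lateral, "forward": forward})


def write_outputs(trials: pd.DataFrame, truth: GroundTruth, config: SyntheticConfig,
                  outdir) -> None:
    """Write the trial table (CSV), ground truth (JSON) and config (JSON)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials.to_csv(outdir / "trials.csv", index=False, float_format="%.6g")
    gt = {
        "speed_states": truth.speed_states.tolist(),
        "acc_states": truth.acc_states.tolist(),
        "composite_states": truth.composite_states.tolist(),
        "session_lengths": list(truth.session_lengths),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(gt))
    (outdir / "config.json").write_text(config.to_json())
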
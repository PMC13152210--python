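"""Superlet time-frequency analysis of binary state sequences.

Superlets estimate power at each centre frequency with a *set* of Morlet
wavelets sharing that frequency but differing in cycle count, combining
their magnitude responses by a geometric mean — keeping the temporal
precision of short wavelets and the frequency resolution of long ones.

One trial is one sample; the sampling rate is fixed at 1000, so frequency
is expressed in cycles per 1000 trials and period (trials) = 1000 / f.
The analysed band 6.7-66.7 cycles/1000 trials corresponds to periods of
150 down to 15 trials.  Sessions are mean-centred and mirror-padded before
the transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

SAMPLING_RATE = 1000.0  # samples per 1000 trials: one trial = one sample
FREQ_MIN, FREQ_MAX = 6.7, 66.7  # cycles / 1000 trials (periods 150-15 trials)
PEAK_BAND_TRIALS = (40.0, 80.0)


def default_freq_grid(n: int = 121) -> np.ndarray:
    return np.linspace(FREQ_MIN, FREQ_MAX, n)


@dataclass
class SuperletConfig:
    """Transform parameters.

    ``base_cycles`` is the cycle count of the shortest wavelet; the order
    (number of wavelets per frequency, cycle counts base * {1..o}) grows
    linearly from ``order_min`` at the lowest analysed frequency to
    ``order_max`` at the highest.
    """

    sampling_rate: float = SAMPLING_RATE
    freqs: np.ndarray = field(default_factory=default_freq_grid)
    base_cycles: int = 3
    order_min: int = 1
    order_max: int = 5
    support_sigmas: float = 2.5  # wavelet truncated at +/- this many SDs

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.freqs <= 0) or np.any(self.freqs
                                             > self.sampling_rate / 2):
            raise ValueError("frequencies must be positive and below Nyquist")
        if self.order_min < 1 or self.order_max < self.order_min:
            raise ValueError("invalid order range")

    @property
    def periods(self) -> np.ndarray:
        """Period axis in trials: exactly sampling_rate / frequency."""
        return self.sampling_rate / self.freqs

    def order_at(self, freq: float) -> int:
        f0, f1 = self.freqs.min(), self.freqs.max()
        frac = 0.0 if f1 == f0 else (freq - f0) / (f1 - f0)
        return int(round(self.order_min
                         + frac * (self.order_max - self.order_min)))

    def max_halfwidth(self) -> int:
        f_trial = self.freqs.min() / self.sampling_rate
        sigma = self.base_cycles / (5.0 * f_trial)
        return int(np.ceil(self.support_sigmas * sigma))


def _morlet(f_trial: float, n_cycles: float, support_sigmas: float
            ) -> np.ndarray:
    """Complex Morlet, amplitude-normalised: a unit-amplitude sinusoid at
    the centre frequency yields responses of magnitude ~1 for every order."""
    sigma = n_cycles / (5.0 * f_trial)
    h = int(np.ceil(support_sigmas * sigma))
    t = np.arange(-h, h + 1, dtype=float)
    env = np.exp(-t ** 2 / (2.0 * sigma ** 2))
    env *= 2.0 / env.sum()
    return env * np.exp(2j * np.pi * f_trial * t)


def superlet_transform(signal: np.ndarray, config: SuperletConfig
                       ) -> np.ndarray:
    """Time x frequency power of one session's (binary) state sequence.

    The signal is mean-centred and mirror-padded by the longest wavelet
    half-width; per frequency, power is the squared geometric mean of the
    magnitude responses of the order set.  Sessions shorter than the
    longest wavelet support cannot be analysed.
    """
    x = np.asarray(signal, dtype=float)
    pad = config.max_halfwidth()
    if x.size <= pad:
        raise ValueError(
            f"session of {x.size} trials is shorter than the longest "
            f"wavelet support ({pad + 1} trials); skip it or raise the "
            "minimum analysed frequency")
    x = x - x.mean()
    xp = np.pad(x, pad, mode="reflect")
    power = np.empty((x.size, config.freqs.size))
    for fi, f in enumerate(config.freqs):
        f_trial = f / config.sampling_rate
        order = config.order_at(f)
        log_mag = np.zeros(x.size)
        for k in range(1, order + 1):
            w = _morlet(f_trial, config.base_cycles * k,
                        config.support_sigmas)
            resp = fftconvolve(xp, w, mode="same")[pad:pad + x.size]
            log_mag += np.log(np.abs(resp) + 1e-300)
        power[:, fi] = np.exp(2.0 * log_mag / order)  # (geometric mean)^2
    return power


@dataclass
class SpectrumResult:
    freqs: np.ndarray
    mean_power: np.ndarray                 # group mean over sessions
    session_power: np.ndarray              # (n_sessions, n_freqs)
    null_mean: np.ndarray | None = None
    null_lo: np.ndarray | None = None
    null_hi: np.ndarray | None = None
    significant: np.ndarray | None = None

    @property
    def periods(self) -> np.ndarray:
        return SAMPLING_RATE / self.freqs

    def peak_period(self, band_trials: tuple | None = None) -> float:
        """Period (trials) of maximal mean power, optionally in a band.

        Ties break toward the longer period.
        """
        periods = self.periods
        sel = np.ones(periods.size, dtype=bool)
        if band_trials is not None:
            lo, hi = band_trials
            sel = (periods >= lo) & (periods <= hi)
        p = np.where(sel, self.mean_power, -np.inf)
        best = np.max(p)
        candidates = np.flatnonzero(p >= best - 1e-15)
        return float(periods[candidates].max())


def mean_spectrum(session_signals: list, config: SuperletConfig | None = None
                  ) -> SpectrumResult:
    """Time-average each session's transform, then average across sessions."""
    config = config or SuperletConfig()
    spectra = []
    for sig in session_signals:
        try:
            spectra.append(superlet_transform(sig, config).mean(axis=0))
        except ValueError as err:
            warnings.warn(str(err))
    if not spectra:
        raise ValueError("no session was long enough to analyse")
    session_power = np.vstack(spectra)
    return SpectrumResult(freqs=config.freqs,
                          mean_power=session_power.mean(axis=0),
                          session_power=session_power)


def session_peak_periods(result: SpectrumResult,
                         band_trials: tuple = PEAK_BAND_TRIALS) -> np.ndarray:
    """Per-session dominant period within the peak band (ties -> longer)."""
    periods = result.periods
    sel = (periods >= band_trials[0]) & (periods <= band_trials[1])
    peaks = []
    for row in result.session_power:
        p = np.where(sel, row, -np.inf)
        cand = np.flatnonzero(p >= np.max(p) - 1e-15)
        peaks.append(periods[cand].max())
    return np.asarray(peaks)


def spectrum_null(filtered_sessions: list, axis: str, n_shuffle: int = 1000,
                  config: SuperletConfig | None = None, seed: int = 0,
                  smoothing_window: int = 5, hmm_restarts: int = 2,
                  observed: SpectrumResult | None = None) -> SpectrumResult:
    """Shuffle-null band for the mean state-sequence spectrum.

    Each surrogate permutes whole trials within each session of the
    *filtered but not yet detrended/smoothed/scaled* metric frames, re-runs
    detrend -> smooth -> scale -> HMM fit -> decoding, and recomputes the
    superlet mean spectrum.  The 2.5/97.5 percentiles of the surrogate mean
    spectra form the null band; with ``observed`` given, frequencies whose
    real power falls outside the band are flagged significant.

    Refitting an HMM per surrogate is expensive; fewer than ~100 shuffles
    give an unstable band (a warning is raised).
    """
    from .hmm import fit_axis
    from .preprocess import CONTINUOUS, detrend_quadratic, smooth_centered, \
        standardise
    from .synthetic import METRICS

    if n_shuffle < 100:
        warnings.warn(f"n_shuffle={n_shuffle}: null band will be unstable")
    config = config or SuperletConfig()
    rng = np.random.default_rng(seed)
    null_power = np.empty((n_shuffle, config.freqs.size))
    for b in range(n_shuffle):
        shuffled = []
        for frame in filtered_sessions:
            idx = rng.permutation(len(frame))
            sf = frame.iloc[idx].reset_index(drop=True).copy()
            for m in CONTINUOUS:
                sf[m] = detrend_quadratic(sf[m].to_numpy())
            for m in METRICS:
                sf[m] = smooth_centered(sf[m].to_numpy(), smoothing_window)
            for m in METRICS:
                sf[m] = standardise(sf[m].to_numpy())
            shuffled.append(sf)
        seq = None
        for _ in range(5):  # a single-restart fit can land degenerate
            try:
                _, seq = fit_axis(shuffled, axis, restarts=hmm_restarts,
                                  seed=int(rng.integers(2 ** 31)))
                break
            except RuntimeError:
                continue
        if seq is None:
            raise RuntimeError("HMM refit failed repeatedly on shuffled "
                               "data; raise hmm_restarts")
        signals = np.split(seq.labels.astype(float),
                           np.cumsum(seq.session_lengths)[:-1])
        null_power[b] = mean_spectrum(signals, config).mean_power
    lo = np.percentile(null_power, 2.5, axis=0)
    hi = np.percentile(null_power, 97.5, axis=0)
    mean = null_power.mean(axis=0)
    if observed is not None:
        sig = (observed.mean_power < lo) | (observed.mean_power > hi)
        return SpectrumResult(freqs=config.freqs,
                              mean_power=observed.mean_power,
                              session_power=observed.session_power,
                              null_mean=mean, null_lo=lo, null_hi=hi,
                              significant=sig)
    return SpectrumResult(freqs=config.freqs, mean_power=mean,
                          session_power=null_power, null_mean=mean,
                          null_lo=lo, null_hi=hi)


def peak_comparison(peaks: np.ndarray, group_labels, n_perm: int = 5000,
                    rng: np.random.Generator | None = None):
    """Group differences in session peak periods (label permutation null).

    For each group pair, the statistic is the difference of group-mean peak
    periods; the null permutes session labels, subsampling to the group
    sizes; Bonferroni correction across pairs.
    """
    import pandas as pd

    from .dynamics import StatResult, _empirical_p

    rng = rng or np.random.default_rng()
    peaks = np.asarray(peaks, dtype=float)
    groups = np.asarray(group_labels)
    names = list(pd.unique(groups))
    if min((groups == g).sum() for g in names) < 2:
        raise ValueError("need >= 2 sessions per group to compare peaks")
    n_pairs = len(names) * (len(names) - 1) // 2
    results = []
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            sel = (groups == gi) | (groups == gj)
            sub, labs = peaks[sel], groups[sel]
            n_i = int((labs == gi).sum())
            obs = sub[labs == gi].mean() - sub[labs == gj].mean()
            null = np.empty(n_perm)
            for b in range(n_perm):
                perm = rng.permutation(sub.size)
                null[b] = sub[perm[:n_i]].mean() - sub[perm[n_i:]].mean()
            p = _empirical_p(obs, null, two_sided=True)
            results.append(StatResult(
                f"peak_period_{gi}_vs_{gj}", float(obs),
                min(p * n_pairs, 1.0), correction="bonferroni"))
    return results


def seconds_signal(labels: np.ndarray, durations_s: np.ndarray) -> np.ndarray:
    """Trial labels expanded to ~1 s resolution by repeating each label
    round(duration) times (at least once)."""
    reps = np.maximum(np.round(np.asarray(durations_s)).astype(int), 1)
    return np.repeat(np.asarray(labels, dtype=float), reps)


def spectrum_seconds(session_labels: list, session_durations: list,
                     config: SuperletConfig | None = None) -> SpectrumResult:
    """Seconds-domain spectrum: expand labels by trial duration, then
    transform as usual (frequency axis now cycles / 1000 s)."""
    signals = [seconds_signal(lab, dur)
               for lab, dur in zip(session_labels, session_durations)]
    return mean_spectrum(signals, config)
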
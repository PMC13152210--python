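"""State-dynamics statistics: dwell times, occupancy, transitions,
switch coupling and cross-group state fingerprints, with permutation nulls.

Conventions used throughout:

* sequences are concatenated over sessions; ``session_lengths`` gives the
  per-session trial counts, and no statistic ever crosses a session
  boundary (runs are truncated there, boundary trials are not switches);
* empirical p-values use the +1 correction (b + 1) / (n + 1);
* two-sided permutation p-values double the smaller tail (capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# --------------------------------------------------------------------------
# helpers

def _split(values: np.ndarray, session_lengths) -> list:
    out, start = [], 0
    for n in session_lengths:
        out.append(values[start:start + n])
        start += n
    return out


def _empirical_p(obs: float, null: np.ndarray, two_sided: bool = True) -> float:
    null = np.asarray(null, dtype=float)
    n = null.size
    ge = np.sum(null >= obs)
    le = np.sum(null <= obs)
    if two_sided:
        p = 2.0 * (min(ge, le) + 1) / (n + 1)
    else:
        p = (ge + 1) / (n + 1)
    return float(min(p, 1.0))


@dataclass
class StatResult:
    name: str
    statistic: float
    p_value: float
    correction: str = "none"
    extra: dict | None = None


# --------------------------------------------------------------------------
# run lengths and dwell times

def run_lengths(labels: np.ndarray, session_lengths) -> list:
    """Per-session run-length encoding: list of (label, start, length).

    Starts are session-local; runs never cross session boundaries.
    """
    encodings = []
    for seq in _split(np.asarray(labels), session_lengths):
        if seq.size == 0:
            encodings.append([])
            continue
        change = np.flatnonzero(np.diff(seq) != 0) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [seq.size]))
        encodings.append([(int(seq[s]), int(s), int(e - s))
                          for s, e in zip(starts, ends)])
    return encodings


def dwell_times(labels: np.ndarray, session_lengths, state: int | None = None):
    """Flat array of run lengths (optionally of one state only)."""
    out = []
    for enc in run_lengths(labels, session_lengths):
        out.extend(length for lab, _, length in enc
                   if state is None or lab == state)
    return np.asarray(out, dtype=float)


def dunn_posthoc(groups: dict, correction: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based post-hoc test for all group pairs.

    z_ij = (mean_rank_i - mean_rank_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    with the usual tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float)
                             for g in names])
    sizes = {g: len(groups[g]) for g in names}
    ranks = stats.rankdata(values)
    mean_ranks, start = {}, 0
    for g in names:
        mean_ranks[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    N = values.size
    _, counts = np.unique(values, return_counts=True)
    ties = np.sum(counts ** 3 - counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - ties
    rows = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(p * n_pairs, 1.0) if correction == "bonferroni" else p
            rows.append((gi, gj, z, p, p_adj))
    return pd.DataFrame(rows, columns=["group1", "group2", "z", "p", "p_adj"])


def dwell_tests(dwells_per_group: dict, alpha: float = 0.05):
    """Kruskal-Wallis across groups, Dunn + Bonferroni when significant."""
    if len(dwells_per_group) < 2:
        raise ValueError("dwell comparison needs >= 2 groups")
    H, p = stats.kruskal(*dwells_per_group.values())
    result = StatResult("kruskal_wallis_dwell", float(H), float(p))
    posthoc = dunn_posthoc(dwells_per_group) if p < alpha else None
    return result, posthoc


# --------------------------------------------------------------------------
# occupancy

def occupancy(labels: np.ndarray, session_lengths, n_states: int,
              by: str = "session") -> np.ndarray:
    """Per-session state proportions.

    ``by='session'`` -> (n_sessions, n_states); ``by='half'`` ->
    (n_sessions, 2, n_states), the halves split at floor(T/2) with the odd
    middle trial in the first half.
    """
    sessions = _split(np.asarray(labels), session_lengths)
    if by == "session":
        return np.stack([np.bincount(s, minlength=n_states) / s.size
                         for s in sessions])
    if by != "half":
        raise ValueError("by must be 'session' or 'half'")
    out = []
    for s in sessions:
        cut = (s.size + 1) // 2  # odd middle trial goes to the first half
        halves = [s[:cut], s[cut:]]
        out.append([np.bincount(h, minlength=n_states) / max(h.size, 1)
                    for h in halves])
    return np.asarray(out)


def occupancy_tests(occ: np.ndarray, group_labels, n_perm: int = 5000,
                    rng: np.random.Generator | None = None):
    """Permutation tests for group differences in per-state occupancy.

    Global test per state: max pairwise difference of group means, against
    a null built by shuffling session-level group labels.  Pairwise tests
    per state and group pair use the two-group mean difference (two-sided).
    """
    rng = rng or np.random.default_rng()
    occ = np.asarray(occ, dtype=float)
    groups = np.asarray(group_labels)
    names = list(pd.unique(groups))
    if len(names) < 2 or min((groups == g).sum() for g in names) < 2:
        raise ValueError("need >= 2 groups with >= 2 sessions each")
    n_states = occ.shape[1]

    def max_pair_diff(occ_col, labs):
        means = [occ_col[labs == g].mean() for g in names]
        return max(abs(a - b) for i, a in enumerate(means)
                   for b in means[i + 1:])

    results = []
    for k in range(n_states):
        obs = max_pair_diff(occ[:, k], groups)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = max_pair_diff(occ[:, k], rng.permutation(groups))
        results.append(StatResult(f"occupancy_global_state{k}", obs,
                                  _empirical_p(obs, null, two_sided=False)))
    for gi_idx, gi in enumerate(names):
        for gj in names[gi_idx + 1:]:
            sel = (groups == gi) | (groups == gj)
            sub, labs = occ[sel], groups[sel]
            for k in range(n_states):
                obs = sub[labs == gi, k].mean() - sub[labs == gj, k].mean()
                null = np.empty(n_perm)
                for b in range(n_perm):
                    perm = rng.permutation(labs)
                    null[b] = sub[perm == gi, k].mean() \
                        - sub[perm == gj, k].mean()
                results.append(StatResult(
                    f"occupancy_{gi}_vs_{gj}_state{k}", obs,
                    _empirical_p(obs, null, two_sided=True)))
    return results


# --------------------------------------------------------------------------
# transition matrices

@dataclass
class TransitionMatrix:
    probs: np.ndarray            # (K, K), row-stochastic, NaN-masked rows
    offdiag: np.ndarray          # diagonal removed and renormalised
    counts: np.ndarray
    p_values: np.ndarray | None = None
    flags: np.ndarray | None = None
    null_lo: np.ndarray | None = None
    null_hi: np.ndarray | None = None


def transition_matrix(labels: np.ndarray, session_lengths,
                      n_states: int) -> TransitionMatrix:
    """ML bigram estimates within sessions; plus the off-diagonal variant.

    Rows of states never visited (or never left, for the off-diagonal
    variant) are NaN-masked.
    """
    counts = np.zeros((n_states, n_states))
    for seq in _split(np.asarray(labels), session_lengths):
        if seq.size < 2:
            continue
        np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row > 0, counts / row, np.nan)
        off = counts.copy()
        np.fill_diagonal(off, 0.0)
        off_row = off.sum(axis=1, keepdims=True)
        offdiag = np.where(off_row > 0, off / off_row, np.nan)
    np.fill_diagonal(offdiag, 0.0)
    return TransitionMatrix(probs=probs, offdiag=offdiag, counts=counts)


def block_shuffle(labels: np.ndarray, session_lengths,
                  rng: np.random.Generator) -> np.ndarray:
    """Shuffle same-state runs within each session, preserving dwell times.

    Run *lengths* are permuted within each label class while the sequence of
    block labels is kept; a naive permutation of whole blocks would place
    same-label blocks next to each other, merging runs and changing the
    run-length multiset, which this scheme preserves exactly.
    """
    out = []
    for seq, enc in zip(_split(np.asarray(labels), session_lengths),
                        run_lengths(labels, session_lengths)):
        if not enc:
            out.append(seq)
            continue
        block_labels = np.array([lab for lab, _, _ in enc])
        lengths = np.array([length for _, _, length in enc])
        shuffled = lengths.copy()
        for lab in np.unique(block_labels):
            sel = block_labels == lab
            shuffled[sel] = lengths[sel][rng.permutation(sel.sum())]
        out.append(np.repeat(block_labels, shuffled).astype(seq.dtype))
    return np.concatenate(out) if out else np.asarray([], dtype=int)


def composite_transition_null(speed_labels: np.ndarray,
                              acc_labels: np.ndarray, session_lengths,
                              n_shuffle: int = 2000, alpha: float = 0.05,
                              rng: np.random.Generator | None = None
                              ) -> TransitionMatrix:
    """Off-diagonal composite transition matrix against a block-shuffle null.

    Speed and accuracy sequences are block-shuffled independently per
    session, recombined into composite labels and the off-diagonal matrix is
    recomputed; per-cell two-sided empirical p-values are BH-FDR corrected
    across off-diagonal cells.
    """
    rng = rng or np.random.default_rng()
    K = 4
    observed = transition_matrix(2 * speed_labels + acc_labels,
                                 session_lengths, K)
    null = np.empty((n_shuffle, K, K))
    for b in range(n_shuffle):
        sp = block_shuffle(speed_labels, session_lengths, rng)
        ac = block_shuffle(acc_labels, session_lengths, rng)
        null[b] = transition_matrix(2 * sp + ac, session_lengths, K).offdiag
    off_idx = ~np.eye(K, dtype=bool)
    p = np.full((K, K), np.nan)
    for i in range(K):
        for j in range(K):
            if i == j or not np.isfinite(observed.offdiag[i, j]):
                continue
            cell = null[:, i, j]
            cell = cell[np.isfinite(cell)]
            p[i, j] = _empirical_p(observed.offdiag[i, j], cell)
    valid = off_idx & np.isfinite(p)
    flags = np.zeros((K, K), dtype=bool)
    if valid.any():
        rej, _, _, _ = multipletests(p[valid], alpha=alpha, method="fdr_bh")
        flags[valid] = rej
    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(null, 2.5, axis=0)
        hi = np.nanpercentile(null, 97.5, axis=0)
    return TransitionMatrix(probs=observed.probs, offdiag=observed.offdiag,
                            counts=observed.counts, p_values=p, flags=flags,
                            null_lo=lo, null_hi=hi)


def group_transition_comparison(session_matrices: list, group_labels,
                                n_perm: int = 2000, n_boot: int = 2000,
                                alpha: float = 0.05,
                                rng: np.random.Generator | None = None):
    """Cross-group transition-matrix tests on per-session matrices.

    Global test per group pair: Frobenius distance between the group-mean
    matrices against a session-label permutation null.  Per-cell tests on
    the mean difference (BH-FDR across cells), with bootstrap 95% CIs.
    """
    rng = rng or np.random.default_rng()
    mats = np.asarray(session_matrices, dtype=float)
    groups = np.asarray(group_labels)
    names = list(pd.unique(groups))

    def group_mean(sel_mats):
        with np.errstate(invalid="ignore"):
            return np.nanmean(sel_mats, axis=0)

    def frob(a, b):
        d = a - b
        return float(np.sqrt(np.nansum(d * d)))

    results, cell_tables = [], {}
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            sel = (groups == gi) | (groups == gj)
            sub, labs = mats[sel], groups[sel]
            mi, mj = group_mean(sub[labs == gi]), group_mean(sub[labs == gj])
            obs = frob(mi, mj)
            null = np.empty(n_perm)
            diff_null = np.empty((n_perm,) + mats.shape[1:])
            for b in range(n_perm):
                perm = rng.permutation(labs)
                pi, pj = group_mean(sub[perm == gi]), group_mean(sub[perm == gj])
                null[b] = frob(pi, pj)
                diff_null[b] = pi - pj
            results.append(StatResult(
                f"frobenius_{gi}_vs_{gj}", obs,
                _empirical_p(obs, null, two_sided=False)))
            # per-cell two-sided tests, FDR-corrected
            obs_diff = mi - mj
            K = obs_diff.shape[0]
            pcell = np.full_like(obs_diff, np.nan)
            for r in range(K):
                for c in range(K):
                    if not np.isfinite(obs_diff[r, c]):
                        continue
                    cell = diff_null[:, r, c]
                    cell = cell[np.isfinite(cell)]
                    pcell[r, c] = _empirical_p(obs_diff[r, c], cell)
            valid = np.isfinite(pcell)
            rej = np.zeros_like(valid)
            if valid.any():
                rej[valid], _, _, _ = multipletests(pcell[valid], alpha=alpha,
                                                    method="fdr_bh")
            boot = np.empty((n_boot,) + mats.shape[1:])
            idx_i = np.flatnonzero(labs == gi)
            idx_j = np.flatnonzero(labs == gj)
            for b in range(n_boot):
                bi = rng.choice(idx_i, idx_i.size, replace=True)
                bj = rng.choice(idx_j, idx_j.size, replace=True)
                boot[b] = group_mean(sub[bi]) - group_mean(sub[bj])
            with np.errstate(invalid="ignore"):
                ci_lo = np.nanpercentile(boot, 2.5, axis=0)
                ci_hi = np.nanpercentile(boot, 97.5, axis=0)
            cell_tables[(gi, gj)] = {"diff": obs_diff, "p": pcell,
                                     "flags": rej, "ci_lo": ci_lo,
                                     "ci_hi": ci_hi}
    return results, cell_tables


# --------------------------------------------------------------------------
# switch coupling

@dataclass
class SwitchCouplingCurve:
    lags: np.ndarray
    coupling: np.ndarray          # C(l) = P(acc switch at t+l | speed switch at t)
    null_lo: np.ndarray
    null_hi: np.ndarray
    p_values: np.ndarray
    flags: np.ndarray             # BH-FDR significant lags


def switch_indicator(labels: np.ndarray, session_lengths) -> list:
    """Per-session boolean arrays: trial t is a switch iff label changed
    from t-1 to t; the first trial of a session is never a switch."""
    out = []
    for seq in _split(np.asarray(labels), session_lengths):
        ind = np.zeros(seq.size, dtype=bool)
        if seq.size > 1:
            ind[1:] = seq[1:] != seq[:-1]
        out.append(ind)
    return out


def _coupling_curve(speed_switch: list, acc_switch: list,
                    lags: np.ndarray) -> np.ndarray:
    num = np.zeros(lags.size)
    den = np.zeros(lags.size)
    for sp, ac in zip(speed_switch, acc_switch):
        t = np.flatnonzero(sp)
        for li, lag in enumerate(lags):
            tt = t + lag
            ok = (tt >= 0) & (tt < ac.size)
            den[li] += ok.sum()
            num[li] += ac[tt[ok]].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def switch_coupling(speed_labels: np.ndarray, acc_labels: np.ndarray,
                    session_lengths, max_lag: int = 10, n_shift: int = 1000,
                    alpha: float = 0.05,
                    rng: np.random.Generator | None = None
                    ) -> SwitchCouplingCurve:
    """Lagged switch coupling C(l) with a circular-shift null.

    The accuracy switch indicator of each session is circularly shifted by
    a uniform random amount of at least ``max_lag + 1`` trials (per session,
    per surrogate), preserving its autocorrelation while destroying the
    cross-alignment.  Band = 2.5/97.5 percentiles; per-lag two-sided
    empirical p-values are BH-FDR corrected.
    """
    rng = rng or np.random.default_rng()
    lags = np.arange(-max_lag, max_lag + 1)
    sp = switch_indicator(speed_labels, session_lengths)
    ac = switch_indicator(acc_labels, session_lengths)
    observed = _coupling_curve(sp, ac, lags)
    null = np.empty((n_shift, lags.size))
    for b in range(n_shift):
        shifted = []
        for a in ac:
            lo, hi = max_lag + 1, a.size - max_lag - 1
            shift = int(rng.integers(lo, max(hi, lo + 1)))
            shifted.append(np.roll(a, shift))
        null[b] = _coupling_curve(sp, shifted, lags)
    p = np.array([_empirical_p(observed[i], null[:, i])
                  if np.isfinite(observed[i]) else np.nan
                  for i in range(lags.size)])
    valid = np.isfinite(p)
    flags = np.zeros(lags.size, dtype=bool)
    if valid.any():
        flags[valid], _, _, _ = multipletests(p[valid], alpha=alpha,
                                              method="fdr_bh")
    return SwitchCouplingCurve(
        lags=lags, coupling=observed,
        null_lo=np.nanpercentile(null, 2.5, axis=0),
        null_hi=np.nanpercentile(null, 97.5, axis=0),
        p_values=p, flags=flags)


# --------------------------------------------------------------------------
# fingerprints

def session_fingerprints(metrics_frames: list, composite_labels: np.ndarray,
                         session_lengths) -> np.ndarray:
    """Per-session 20-vectors: mean of each metric within each composite state.

    Layout: state-major (state 0 metrics, state 1 metrics, ...); entries for
    states never visited in a session are NaN.
    """
    from .synthetic import METRICS

    per_sess = _split(np.asarray(composite_labels), session_lengths)
    out = np.full((len(metrics_frames), 4 * len(METRICS)), np.nan)
    for i, (frame, labs) in enumerate(zip(metrics_frames, per_sess)):
        X = frame[list(METRICS)].to_numpy(dtype=float)
        for k in range(4):
            sel = labs == k
            if sel.any():
                out[i, k * len(METRICS):(k + 1) * len(METRICS)] = \
                    X[sel].mean(axis=0)
    return out


def fingerprint_comparison(fingerprints: np.ndarray, group_labels,
                           n_perm: int = 5000,
                           rng: np.random.Generator | None = None):
    """Pairwise group similarity of mean fingerprints.

    Pearson r and Euclidean distance between group-mean 20-vectors (NaN
    entries excluded pairwise); permutation p for the distance by shuffling
    session-level group labels.
    """
    rng = rng or np.random.default_rng()
    fps = np.asarray(fingerprints, dtype=float)
    groups = np.asarray(group_labels)
    names = list(pd.unique(groups))

    def summarise(a, b):
        with np.errstate(invalid="ignore"):
            ma = np.nanmean(a, axis=0)
            mb = np.nanmean(b, axis=0)
        ok = np.isfinite(ma) & np.isfinite(mb)
        r = float(np.corrcoef(ma[ok], mb[ok])[0, 1])
        dist = float(np.linalg.norm(ma[ok] - mb[ok]))
        return r, dist

    results = []
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            sel = (groups == gi) | (groups == gj)
            sub, labs = fps[sel], groups[sel]
            r, dist = summarise(sub[labs == gi], sub[labs == gj])
            null = np.empty(n_perm)
            for b in range(n_perm):
                perm = rng.permutation(labs)
                _, null[b] = summarise(sub[perm == gi], sub[perm == gj])
            results.append(StatResult(
                f"fingerprint_{gi}_vs_{gj}", dist,
                _empirical_p(dist, null, two_sided=False),
                extra={"pearson_r": r}))
    return results
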
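"""End-to-end orchestration: simulate -> preprocess -> cluster -> fit ->
dynamics -> spectrum -> difficulty, with per-stage seed substreams and a
run manifest.

Every stochastic stage draws its seed from a substream of one master seed,
so changing one stage's repetition count never shifts another stage's
randomness.  Trial indices are 0-based; intervals half-open.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import METRICS, SyntheticConfig, simulate_sessions, \
    write_outputs
from .preprocess import preprocess_group
from .structure import cluster_metrics, cluster_report, correlate_metrics
from .hmm import fit_axis, conjoin, sequences_frame
from .dynamics import (composite_transition_null, dwell_times, occupancy,
                       run_lengths, session_fingerprints, switch_coupling,
                       transition_matrix)
from .spectral import SuperletConfig, mean_spectrum, session_peak_periods, \
    spectrum_null
from .difficulty import difficulty_around_transitions

ALL_STAGES = ("simulate", "preprocess", "cluster", "fit", "dynamics",
              "spectrum", "difficulty")
# substream index per stage (fixed, order-independent)
_STREAM = {name: i for i, name in enumerate(ALL_STAGES)}


@dataclass
class RunConfig:
    outdir: str = "attnstates_run"
    stages: tuple = ALL_STAGES
    master_seed: int = 0
    synthetic: dict = field(default_factory=dict)
    is_human: bool = False
    smoothing_window: int = 5
    pad: int = 50
    pad_value: float = 10.0
    hmm_restarts: int = 10
    hmm_tol: float = 1e-4
    hmm_max_iter: int = 500
    n_block_shuffle: int = 2000
    coupling_max_lag: int = 10
    n_shift: int = 1000
    spectrum_null_shuffles: int = 0   # 0 disables the expensive HMM-refit null
    difficulty_window: int = 10
    n_difficulty_shuffle: int = 1000

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    child = np.random.SeedSequence(cfg.master_seed).spawn(len(ALL_STAGES))
    return int(child[_STREAM[stage]].generate_state(1)[0] % (2 ** 31))


def _require(artifacts: dict, key: str, stage: str):
    if key not in artifacts:
        raise RuntimeError(
            f"stage {stage!r} requires output of stage {key!r}, "
            "which did not run")
    return artifacts[key]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order; write outputs under cfg.outdir.

    Returns the in-memory artifact bundle (also useful programmatically).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    if "simulate" in cfg.stages:
        syn = dict(cfg.synthetic)
        syn.setdefault("seed", _stage_seed(cfg, "simulate"))
        sconfig = SyntheticConfig(**syn)
        trials, sessions, truth = simulate_sessions(sconfig)
        write_outputs(trials, truth, sconfig, outdir)
        artifacts["simulate"] = {"trials": trials, "sessions": sessions,
                                 "truth": truth, "config": sconfig}

    if "preprocess" in cfg.stages:
        sim = _require(artifacts, "simulate", "preprocess")
        frames, reports = preprocess_group(
            sim["sessions"], is_human=cfg.is_human,
            smoothing_window=cfg.smoothing_window)
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "preprocessed.csv", index=False, float_format="%.6g")
        (outdir / "preprocess_report.json").write_text(
            json.dumps(reports, indent=2))
        artifacts["preprocess"] = {"frames": frames, "reports": reports}

    if "cluster" in cfg.stages:
        pre = _require(artifacts, "preprocess", "cluster")
        concat = pd.concat(pre["frames"], ignore_index=True)
        corr = correlate_metrics(concat)
        result = cluster_metrics(corr)
        (outdir / "cluster.json").write_text(
            json.dumps(cluster_report(result), indent=2))
        artifacts["cluster"] = result

    if "fit" in cfg.stages:
        pre = _require(artifacts, "preprocess", "fit")
        seed = _stage_seed(cfg, "fit")
        kwargs = dict(restarts=cfg.hmm_restarts, tol=cfg.hmm_tol,
                      max_iter=cfg.hmm_max_iter)
        speed_model, speed_seq = fit_axis(pre["frames"], "speed",
                                          pad=cfg.pad,
                                          pad_value=cfg.pad_value,
                                          seed=seed, **kwargs)
        acc_model, acc_seq = fit_axis(pre["frames"], "accuracy",
                                      pad=cfg.pad, pad_value=cfg.pad_value,
                                      seed=seed + 1, **kwargs)
        composite = conjoin(speed_seq, acc_seq)
        concat = pd.concat(pre["frames"], ignore_index=True)
        table = sequences_frame(concat["session_id"], speed_seq, acc_seq,
                                composite, concat["trial_index"])
        table.to_csv(outdir / "states.csv", index=False)
        params = {
            axis: {"means": m.means.tolist(),
                   "transmat": m.transmat.tolist(),
                   "log_likelihood": m.log_likelihood}
            for axis, m in (("speed", speed_model), ("accuracy", acc_model))
        }
        (outdir / "hmm_params.json").write_text(json.dumps(params, indent=2))
        artifacts["fit"] = {"speed_model": speed_model,
                            "acc_model": acc_model,
                            "speed_seq": speed_seq, "acc_seq": acc_seq,
                            "composite": composite}

    if "dynamics" in cfg.stages:
        fit = _require(artifacts, "fit", "dynamics")
        pre = _require(artifacts, "preprocess", "dynamics")
        rng = np.random.default_rng(_stage_seed(cfg, "dynamics"))
        composite, lengths = fit["composite"], fit["composite"].session_lengths
        dw = dwell_times(composite.labels, lengths)
        occ = occupancy(composite.labels, lengths, 4)
        tm = composite_transition_null(
            fit["speed_seq"].labels, fit["acc_seq"].labels, lengths,
            n_shuffle=cfg.n_block_shuffle, rng=rng)
        coupling = switch_coupling(fit["speed_seq"].labels,
                                   fit["acc_seq"].labels, lengths,
                                   max_lag=cfg.coupling_max_lag,
                                   n_shift=cfg.n_shift, rng=rng)
        fps = session_fingerprints(pre["frames"], composite.labels, lengths)
        pd.DataFrame({"dwell_trials": dw}).to_csv(outdir / "dwell.csv",
                                                  index=False)
        pd.DataFrame(occ, columns=list(composite.state_names)).to_csv(
            outdir / "occupancy.csv", index=False)
        pd.DataFrame(fps).to_csv(outdir / "fingerprints.csv", index=False)
        summary = {
            "median_dwell_trials": float(np.median(dw)),
            "mean_dwell_trials": float(np.mean(dw)),
            "transition_matrix": np.where(np.isfinite(tm.probs),
                                          tm.probs, None).tolist(),
            "transition_offdiag": np.where(np.isfinite(tm.offdiag),
                                           tm.offdiag, None).tolist(),
            "transition_flags": tm.flags.tolist(),
            "coupling_lags": coupling.lags.tolist(),
            "coupling": np.where(np.isfinite(coupling.coupling),
                                 coupling.coupling, None).tolist(),
            "coupling_flags": coupling.flags.tolist(),
        }
        (outdir / "dynamics.json").write_text(json.dumps(summary, indent=2))
        artifacts["dynamics"] = {"dwell": dw, "occupancy": occ,
                                 "transitions": tm, "coupling": coupling,
                                 "fingerprints": fps}

    if "spectrum" in cfg.stages:
        fit = _require(artifacts, "fit", "spectrum")
        scfg = SuperletConfig()
        seq = fit["speed_seq"]
        signals = np.split(seq.labels.astype(float),
                           np.cumsum(seq.session_lengths)[:-1])
        spec = mean_spectrum(signals, scfg)
        if cfg.spectrum_null_shuffles > 0:
            pre = _require(artifacts, "preprocess", "spectrum")
            spec = spectrum_null(pre["frames"], "speed",
                                 n_shuffle=cfg.spectrum_null_shuffles,
                                 config=scfg,
                                 seed=_stage_seed(cfg, "spectrum"),
                                 observed=spec)
        peaks = session_peak_periods(spec)
        table = pd.DataFrame({"frequency": spec.freqs,
                              "period_trials": spec.periods,
                              "power": spec.mean_power})
        if spec.null_lo is not None:
            table["null_lo"] = spec.null_lo
            table["null_hi"] = spec.null_hi
            table["significant"] = spec.significant
        table.to_csv(outdir / "spectrum.csv", index=False,
                     float_format="%.6g")
        pd.DataFrame({"peak_period_trials": peaks}).to_csv(
            outdir / "peaks.csv", index=False, float_format="%.6g")
        artifacts["spectrum"] = {"spectrum": spec, "peaks": peaks}

    if "difficulty" in cfg.stages:
        fit = _require(artifacts, "fit", "difficulty")
        pre = _require(artifacts, "preprocess", "difficulty")
        rng = np.random.default_rng(_stage_seed(cfg, "difficulty"))
        diff = pd.concat(pre["frames"],
                         ignore_index=True)["difficulty"].to_numpy()
        curves = {}
        for direction in ("low_to_high", "high_to_low"):
            curves[direction] = difficulty_around_transitions(
                diff, fit["speed_seq"].labels,
                fit["speed_seq"].session_lengths, direction=direction,
                window=cfg.difficulty_window,
                n_shuffle=cfg.n_difficulty_shuffle, rng=rng)
        rows = []
        for direction, c in curves.items():
            for i, off in enumerate(c.offsets):
                rows.append((direction, int(off), c.mean_difficulty[i],
                             c.null_lo[i], c.null_hi[i], bool(c.flags[i])))
        pd.DataFrame(rows, columns=["direction", "offset", "mean_difficulty",
                                    "null_lo", "null_hi", "flag"]).to_csv(
            outdir / "difficulty_curves.csv", index=False,
            float_format="%.6g")
        artifacts["difficulty"] = curves

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "master_seed": cfg.master_seed,
        "stages": list(cfg.stages),
        "config": {k: v for k, v in asdict(cfg).items()
                   if k not in ("outdir",)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return artifacts
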
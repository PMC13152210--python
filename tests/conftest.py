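import warnings

import numpy as np
import pytest

import attnstates as at

warnings.filterwarnings("ignore", message="Model is not converging")


@pytest.fixture(scope="session")
def batch():
    """A moderate synthetic batch shared by inference/dynamics tests."""
    cfg = at.SyntheticConfig(n_sessions=6, trials_per_session=300, seed=11)
    trials, sessions, truth = at.simulate_sessions(cfg)
    frames, reports = at.preprocess_group(sessions)
    kept = np.concatenate([
        f["trial_index"].to_numpy() + i * cfg.trials_per_session
        for i, f in enumerate(frames)])
    return {"config": cfg, "trials": trials, "sessions": sessions,
            "truth": truth, "frames": frames, "reports": reports,
            "kept": kept}


@pytest.fixture(scope="session")
def fitted(batch):
    """Axis HMMs fitted on the shared batch, plus decoded sequences."""
    speed_model, speed_seq = at.fit_axis(batch["frames"], "speed",
                                         restarts=6, seed=0)
    acc_model, acc_seq = at.fit_axis(batch["frames"], "accuracy",
                                     restarts=6, seed=1)
    composite = at.conjoin(speed_seq, acc_seq)
    return {"speed_model": speed_model, "speed_seq": speed_seq,
            "acc_model": acc_model, "acc_seq": acc_seq,
            "composite": composite}
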
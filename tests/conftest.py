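import pandas as pd
import pytest

import fcmodes as fm


def make_blocks(sizes, subjects=None):
    """Block index DataFrame for raw matrices used outside the generator."""
    rows, start = [], 0
    for i, t in enumerate(sizes):
        sub = subjects[i] if subjects is not None else f"s{i + 1:02d}"
        rows.append({"subject": sub, "session": "ses1", "start": start, "stop": start + t})
        start += t
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def separable_dataset():
    """Well-separated 4-state data: 20 session chains of 300 frames, 8 nodes."""
    cfg = fm.SynthConfig(
        n_subjects=10, sessions_per_subject=[2] * 10, runs_per_session=1,
        timepoints_per_run=300, n_nodes=8, n_states=4,
        state_mean_scale=2.0, noise_sd=1.0, seed=11,
    )
    runs, truth = fm.generate_hmm_timeseries(cfg)
    X, blocks = fm.standardize_concat(runs)
    return cfg, runs, truth, X, blocks


@pytest.fixture(scope="session")
def separable_fit(separable_dataset):
    cfg, runs, truth, X, blocks = separable_dataset
    fit = fm.fit_hmm(X, blocks, n_states=cfg.n_states, n_restarts=3, seed=0)
    return truth, X, blocks, fit


@pytest.fixture(scope="session")
def planted_study():
    """Default study shape (23 subjects, 64 subject-sessions) with the
    planted canonical mode at coupling 0.85."""
    cfg = fm.SynthConfig(seed=7)
    runs, truth = fm.generate_hmm_timeseries(cfg)
    behavior = fm.generate_behavior(truth, cfg)
    return cfg, truth, behavior
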
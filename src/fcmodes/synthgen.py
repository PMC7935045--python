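"""Ground-truth-known synthetic data for the two-arm connectivity analysis.

Emulates the study design the pipeline expects: ~23 subjects scanned in 2-3
sessions of 2 resting-state runs each (180 timepoints/run at TR = 2 s), a
configurable node count (small by default, 439 at full scale), a K-state
Gaussian HMM generating the node signals (default K = 12, with a
block-structured transition matrix so that metastates exist), a behavior
table of 31 task/questionnaire measures carrying an 8-factor structure, and
6-parameter motion traces. One latent behavioral factor is coupled to a
planted linear combination of the true state fractional occupancies, which
plants a single canonical mode between brain dynamics and behavior.

State Gaussians use means drawn on a +/- sign grid scaled by
``state_mean_scale`` with a shared spherical covariance ``noise_sd**2 I``,
so state separability is controlled by one knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gauss_hmm import HMMModel
from .preprocess import NodeTimeSeries

# 31 behavioral measures: 6 Spatial WM, 6 DSST, 3 Stroop, 4 Color WM,
# 8 VAS, 3 BIS, 1 box completion.
BEHAVIOR_MEASURES: tuple[str, ...] = (
    "spatialwm_acc_match", "spatialwm_acc_nonmatch",
    "spatialwm_rt_median_match", "spatialwm_rt_median_nonmatch",
    "spatialwm_rt_sd_match", "spatialwm_rt_sd_nonmatch",
    "dsst_acc_match", "dsst_acc_nonmatch",
    "dsst_rt_median_match", "dsst_rt_median_nonmatch",
    "dsst_rt_sd_match", "dsst_rt_sd_nonmatch",
    "stroop_acc_incongruent", "stroop_rt_diff_median", "stroop_rt_diff_sd",
    "colorwm_rt_median", "colorwm_rt_sd", "colorwm_err_median", "colorwm_err_sd",
    "vas_anxious", "vas_happy", "vas_sad", "vas_nauseous",
    "vas_drowsy", "vas_jittery", "vas_fatigued", "vas_dizzy",
    "bis_attentional", "bis_motor", "bis_nonplanning",
    "box_completion_time",
)
N_BEHAVIOR_MEASURES = len(BEHAVIOR_MEASURES)
N_BEHAVIOR_FACTORS = 8

# measure index groups assigned to each of the 8 latent factors
_FACTOR_GROUPS: tuple[tuple[int, ...], ...] = (
    (2, 3, 4, 5),            # spatial WM reaction times
    (8, 9, 10, 11),          # DSST reaction times
    (0, 1, 6, 7, 12, 13),    # accuracies + stroop RT (task general)
    (15, 16, 17, 18),        # color WM precision / RT
    (20, 21, 22),            # affect (happy/sad/nauseous)
    (19, 23, 24, 25, 26),    # arousal (anxious/drowsy/jittery/fatigued/dizzy)
    (27, 28, 29),            # impulsivity (BIS)
    (14, 30),                # residual speed (stroop RT sd, box completion)
)
_PRIMARY_LOADING = 0.8


@dataclass
class SynthConfig:
    """Study-shape constants and generator knobs.

    Defaults mirror the emulated study: 23 subjects, two 6-minute runs of
    180 volumes per session at TR = 2 s, sessions 1-2 for everyone and a
    third session for 18 of the 23 subjects, and a 12-state HMM with a
    2/9/1 metastate block structure.
    """

    n_subjects: int = 23
    sessions_per_subject: Sequence[int] | None = None
    runs_per_session: int = 2
    timepoints_per_run: int = 180
    tr: float = 2.0
    n_nodes: int = 20
    n_states: int = 12
    transition_blocks: Sequence[Sequence[int]] | None = None
    within_block_mass: float = 0.9
    state_mean_scale: float = 1.0
    behavior_coupling: float = 0.85
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.runs_per_session, self.timepoints_per_run,
               self.n_nodes, self.n_states) < 1:
            raise ValueError("all counts must be >= 1")
        if self.sessions_per_subject is None:
            n3 = int(round(self.n_subjects * 18 / 23))
            self.sessions_per_subject = [3] * n3 + [2] * (self.n_subjects - n3)
        self.sessions_per_subject = list(self.sessions_per_subject)
        if len(self.sessions_per_subject) != self.n_subjects:
            raise ValueError("sessions_per_subject length must equal n_subjects")
        if any(s < 1 for s in self.sessions_per_subject):
            raise ValueError("session counts must be >= 1")
        if not 0.0 <= self.within_block_mass <= 1.0:
            raise ValueError("within_block_mass must lie in [0, 1]")
        if not 0.0 <= self.behavior_coupling <= 1.0:
            raise ValueError("behavior_coupling must lie in [0, 1]")
        if self.transition_blocks is None:
            self.transition_blocks = _default_blocks(self.n_states)
        self.transition_blocks = [list(b) for b in self.transition_blocks]
        flat = sorted(s for b in self.transition_blocks for s in b)
        if flat != list(range(self.n_states)):
            raise ValueError("transition_blocks must partition the states 0..K-1")

    @classmethod
    def full_scale(cls, **overrides) -> "SynthConfig":
        """The full study shape: 23 subjects (18 with 3 sessions), 2 x 180
        volumes per session, 439 nodes."""
        kw = dict(n_subjects=23, sessions_per_subject=[3] * 18 + [2] * 5,
                  runs_per_session=2, timepoints_per_run=180, n_nodes=439)
        kw.update(overrides)
        return cls(**kw)

    @property
    def subject_ids(self) -> list[str]:
        return [f"sub{i + 1:02d}" for i in range(self.n_subjects)]

    def subject_sessions(self) -> list[tuple[str, str]]:
        out = []
        for sid, n_ses in zip(self.subject_ids, self.sessions_per_subject):
            out.extend((sid, f"ses{j + 1}") for j in range(n_ses))
        return out


def _default_blocks(n_states: int) -> list[list[int]]:
    # 2 / (K-3) / 1 partition, mirroring the 2/9/1 metastate structure at K=12
    if n_states >= 4:
        return [[0, 1], list(range(2, n_states - 1)), [n_states - 1]]
    return [list(range(n_states))]


@dataclass
class GroundTruth:
    """Generating quantities kept for evaluation."""

    state_paths: dict          # (subject, session) -> int array, 0-based labels
    true_model: HMMModel
    true_fo: pd.DataFrame      # one row per subject-session, K FO columns
    planted_weights: tuple = field(default=(None, None))  # (brain over FO, behavior over measures)


def build_transition_matrix(config: SynthConfig) -> np.ndarray:
    """Block-structured row-stochastic transition matrix.

    Within-block mass ``w`` is spread uniformly over the block (self
    included); the remaining 1 - w uniformly over the other states.
    """
    K = config.n_states
    theta = np.zeros((K, K))
    w = config.within_block_mass
    for block in config.transition_blocks:
        m = len(block)
        for i in block:
            if m == K:
                theta[i, :] = 1.0 / K
                continue
            theta[i, block] = w / m
            others = [j for j in range(K) if j not in block]
            theta[i, others] = (1.0 - w) / len(others)
    return theta


def _state_means(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    K, p = config.n_states, config.n_nodes
    signs = rng.choice([-1.0, 1.0], size=(K, p))
    # enforce separation on the sign grid: any two states differ in >= p/4 coords
    for _ in range(200):
        ok = True
        for i in range(K):
            for j in range(i):
                if np.sum(signs[i] != signs[j]) < max(1, p // 4):
                    signs[j] = rng.choice([-1.0, 1.0], size=p)
                    ok = False
        if ok:
            break
    return config.state_mean_scale * signs


def generate_hmm_timeseries(config: SynthConfig) -> tuple[list[NodeTimeSeries], GroundTruth]:
    """Sample per-session Markov chains and Gaussian observations.

    The chain is continuous within a session (runs are contiguous slices of
    it) and restarts at every subject-session boundary, matching how the
    pipeline concatenates data.
    """
    if config.noise_sd <= 0:
        raise ValueError("noise_sd must be > 0: a zero observation covariance is degenerate")
    rng = np.random.default_rng([config.seed, 1])
    K, p = config.n_states, config.n_nodes
    theta = build_transition_matrix(config)
    means = _state_means(config, rng)
    covs = np.repeat((config.noise_sd**2 * np.eye(p))[None], K, axis=0)
    startprob = np.full(K, 1.0 / K)
    true_model = HMMModel(means, covs, theta, startprob)

    t_sess = config.runs_per_session * config.timepoints_per_run
    runs: list[NodeTimeSeries] = []
    paths: dict[tuple[str, str], np.ndarray] = {}
    fo_rows = []
    cum_theta = np.cumsum(theta, axis=1)
    for sub, ses in config.subject_sessions():
        path = np.empty(t_sess, dtype=int)
        path[0] = rng.integers(K)
        u = rng.random(t_sess)
        for t in range(1, t_sess):
            path[t] = int(np.searchsorted(cum_theta[path[t - 1]], u[t]))
        obs = means[path] + config.noise_sd * rng.standard_normal((t_sess, p))
        paths[(sub, ses)] = path
        fo = np.bincount(path, minlength=K) / t_sess
        fo_rows.append({"subject": sub, "session": ses,
                        **{f"fo_state_{k + 1}": fo[k] for k in range(K)}})
        for r in range(config.runs_per_session):
            sl = slice(r * config.timepoints_per_run, (r + 1) * config.timepoints_per_run)
            runs.append(NodeTimeSeries(sub, ses, f"run{r + 1}", obs[sl].copy(), config.tr))

    w_brain = rng.standard_normal(K)
    w_brain /= np.linalg.norm(w_brain)
    truth = GroundTruth(
        state_paths=paths,
        true_model=true_model,
        true_fo=pd.DataFrame(fo_rows),
        planted_weights=(w_brain, None),
    )
    return runs, truth


def _factor_loadings() -> np.ndarray:
    L = np.zeros((N_BEHAVIOR_MEASURES, N_BEHAVIOR_FACTORS))
    for f, group in enumerate(_FACTOR_GROUPS):
        L[list(group), f] = _PRIMARY_LOADING
    return L


@dataclass
class BehaviorData:
    """Generated behavior table plus its generating latent structure."""

    table: pd.DataFrame          # subject, session + 31 measure columns
    factor_scores: np.ndarray    # (rows, 8) latent factor scores
    loadings: np.ndarray         # (31, 8) generating loadings


def generate_behavior(truth: GroundTruth, config: SynthConfig) -> BehaviorData:
    """Behavior measures loading on 8 latent factors, one coupled to FO.

    Factor 0's score is a ``behavior_coupling``-weighted mixture of the
    planted brain combination (standardized FO projected on the planted
    brain weights) and fresh noise; measures are factors times loadings
    plus Gaussian measurement noise of SD ``0.6 * noise_sd`` (uniqueness
    matching the 0.8 primary loadings at noise_sd = 1).
    """
    if not 0.0 <= config.behavior_coupling <= 1.0:
        raise ValueError("behavior_coupling must lie in [0, 1]")
    rng = np.random.default_rng([config.seed, 2])
    fo_cols = [c for c in truth.true_fo.columns if c.startswith("fo_state_")]
    fo = truth.true_fo[fo_cols].to_numpy()
    n = fo.shape[0]
    w_brain = truth.planted_weights[0]
    brain = fo @ w_brain
    sd = brain.std()
    brain_z = (brain - brain.mean()) / (sd if sd > 0 else 1.0)

    c = config.behavior_coupling
    factors = rng.standard_normal((n, N_BEHAVIOR_FACTORS))
    factors[:, 0] = c * brain_z + np.sqrt(1.0 - c**2) * factors[:, 0]

    L = _factor_loadings()
    noise = 0.6 * config.noise_sd * rng.standard_normal((n, N_BEHAVIOR_MEASURES))
    measures = factors @ L.T + noise

    w_measures = L[:, 0] / np.linalg.norm(L[:, 0])
    truth.planted_weights = (w_brain, w_measures)

    table = truth.true_fo[["subject", "session"]].copy()
    for j, name in enumerate(BEHAVIOR_MEASURES):
        table[name] = measures[:, j]
    return BehaviorData(table=table, factor_scores=factors, loadings=L)


def generate_motion(
    config: SynthConfig,
    *,
    amplitude: float = 1.0,
    trans_step_sd_mm: float = 0.03,
    rot_step_sd_rad: float = 4e-4,
    spike_prob: float = 0.01,
    spike_mm: float = 0.3,
) -> dict[tuple[str, str, str], np.ndarray]:
    """Random-walk motion traces with occasional spikes, one table per run.

    Default step sizes put mean FD near the emulated sample's 0.14 mm. The
    whole trace scales with ``amplitude`` (0 gives all-zero parameters and
    hence zero FD).
    """
    rng = np.random.default_rng([config.seed, 3])
    T = config.timepoints_per_run
    out: dict[tuple[str, str, str], np.ndarray] = {}
    for sub, ses in config.subject_sessions():
        for r in range(config.runs_per_session):
            steps = np.empty((T, 6))
            steps[:, :3] = trans_step_sd_mm * rng.standard_normal((T, 3))
            steps[:, 3:] = rot_step_sd_rad * rng.standard_normal((T, 3))
            spikes = rng.random(T) < spike_prob
            steps[spikes, :3] += spike_mm * rng.choice([-1, 1], size=(int(spikes.sum()), 3))
            steps[0] = 0.0
            out[(sub, ses, f"run{r + 1}")] = amplitude * np.cumsum(steps, axis=0)
    return out


def phase_randomize(ts: NodeTimeSeries, seed: int) -> NodeTimeSeries:
    """Phase-randomized surrogate: per-node Fourier amplitudes preserved.

    Each node gets an independent uniform phase draw at every positive
    frequency; the zero-frequency (and Nyquist, for even length) components
    are kept, so the output is real with the input's mean and amplitude
    spectrum.
    """
    data = ts.data
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in input")
    T = data.shape[0]
    rng = np.random.default_rng(seed)
    F = np.fft.rfft(data, axis=0)
    nf = F.shape[0]
    hi = nf - 1 if T % 2 == 0 else nf  # exclude Nyquist bin for even T
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(hi - 1, data.shape[1]))
    F[1:hi] = np.abs(F[1:hi]) * np.exp(1j * phases)
    surrogate = np.fft.irfft(F, n=T, axis=0)
    return NodeTimeSeries(ts.subject_id, ts.session_id, f"{ts.run_id}_surr",
                          surrogate, ts.tr)
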
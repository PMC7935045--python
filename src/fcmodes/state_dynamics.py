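"""Temporal and spatial statistics of inferred HMM states.

Per subject-session: fractional occupancy (FO, mean posterior probability
per state) and switching rate (mean absolute change of the state
probability vector between consecutive timepoints, summed over states,
divided by the number of timepoints). Metastates are found by
single-linkage agglomerative clustering of the rows of the transition
matrix (Euclidean distance) cut at 3 clusters; metastate time courses are
the column sums of their member states, and their FO/switching rate follow
the same definitions. At the defaults (12 states, 3 metastates) the
assembled feature matrix has 17 columns: 12 + 3 FOs plus the two mean
switching rates.

Motion QC correlates each feature with session-specific mean framewise
displacement across subjects and applies Benjamini-Hochberg FDR jointly
across all (feature, session) tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .gauss_hmm import StateTimeCourse

DEFAULT_N_METASTATES = 3
DEFAULT_OVERLAP_THRESHOLD = 0.40


def _block_iter(stc: StateTimeCourse):
    for row in stc.blocks.itertuples():
        yield row.subject, row.session, stc.probs[int(row.start):int(row.stop)]


def fractional_occupancy(stc: StateTimeCourse, prefix: str = "fo_state_") -> pd.DataFrame:
    """Mean posterior probability per state for each subject-session."""
    rows = []
    for sub, ses, g in _block_iter(stc):
        if g.shape[0] == 0:
            raise ValueError(f"empty block for subject={sub} session={ses}")
        fo = g.mean(axis=0)
        rows.append({"subject": sub, "session": ses,
                     **{f"{prefix}{k + 1}": fo[k] for k in range(stc.n_states)}})
    return pd.DataFrame(rows)


def switching_rate(
    stc: StateTimeCourse,
    denominator: str = "timepoints",
    column: str = "switching_rate",
) -> pd.DataFrame:
    """Mean absolute probability change per block.

    SR(b) = (1/D) * sum_t sum_k |P[t+1, k] - P[t, k]| with D the number of
    timepoints in the block (``denominator="timepoints"``, the default) or
    the number of transitions (``"transitions"``). The absolute value is
    essential: the signed sum telescopes to ~0.
    """
    if denominator not in ("timepoints", "transitions"):
        raise ValueError("denominator must be 'timepoints' or 'transitions'")
    rows = []
    for sub, ses, g in _block_iter(stc):
        t = g.shape[0]
        if t < 2:
            raise ValueError(f"block for subject={sub} session={ses} has < 2 frames")
        total = np.abs(np.diff(g, axis=0)).sum()
        denom = t if denominator == "timepoints" else t - 1
        rows.append({"subject": sub, "session": ses, column: total / denom})
    return pd.DataFrame(rows)


@dataclass
class MetastatePartition:
    """State -> cluster assignment with the linkage tree that produced it."""

    labels: np.ndarray          # (K,) cluster ids 0..M-1
    linkage_tree: np.ndarray    # scipy linkage matrix (merge heights)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def as_sets(self) -> set[frozenset]:
        return {frozenset(self.members(c).tolist()) for c in range(self.n_clusters)}


def cluster_metastates(transmat: np.ndarray, n_clusters: int = DEFAULT_N_METASTATES) -> MetastatePartition:
    """Single-linkage / Euclidean clustering of the transition-matrix rows."""
    theta = np.asarray(transmat, dtype=float)
    K = theta.shape[0]
    if theta.shape != (K, K) or not np.allclose(theta.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix must be square and row-stochastic")
    if not 1 <= n_clusters <= K:
        raise ValueError("n_clusters must lie in [1, n_states]")
    tree = linkage(theta, method="single", metric="euclidean")
    raw = fcluster(tree, t=n_clusters, criterion="maxclust")
    # relabel clusters 0..M-1 in order of first appearance over states
    remap: dict[int, int] = {}
    labels = np.empty(K, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = remap.setdefault(int(r), len(remap))
    return MetastatePartition(labels=labels, linkage_tree=tree)


def metastate_timecourse(stc: StateTimeCourse, partition: MetastatePartition) -> StateTimeCourse:
    """Pool state probabilities by metastate (column sums of members)."""
    if partition.labels.size != stc.n_states:
        raise ValueError("partition does not cover the states of this time course")
    M = partition.n_clusters
    pooled = np.empty((stc.probs.shape[0], M))
    for m in range(M):
        pooled[:, m] = stc.probs[:, partition.members(m)].sum(axis=1)
    return StateTimeCourse(probs=pooled, blocks=stc.blocks)


def assemble_state_features(
    stc: StateTimeCourse,
    partition: MetastatePartition,
    sr_denominator: str = "timepoints",
) -> pd.DataFrame:
    """Per subject-session CCA feature matrix.

    Columns: FO of each state, FO of each metastate, mean switching rate
    across states, mean switching rate across metastates (17 columns at the
    12-state / 3-metastate defaults).
    """
    meta_stc = metastate_timecourse(stc, partition)
    fo_states = fractional_occupancy(stc, prefix="fo_state_")
    fo_meta = fractional_occupancy(meta_stc, prefix="fo_meta_")
    sr_states = switching_rate(stc, sr_denominator, column="sr_states")
    sr_meta = switching_rate(meta_stc, sr_denominator, column="sr_metastates")
    out = fo_states
    for other in (fo_meta, sr_states, sr_meta):
        out = out.merge(other, on=["subject", "session"], validate="one_to_one")
    return out


def feature_columns(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns if c not in ("subject", "session")]


def overlap_index(
    state_map: np.ndarray,
    network_nodes,
    threshold_frac: float = DEFAULT_OVERLAP_THRESHOLD,
) -> float:
    """Thresholded-map overlap with a network, normalized by network size.

    The top ``threshold_frac`` of positive-valued nodes (by value) and the
    top ``threshold_frac`` of negative-valued nodes (by magnitude) are
    selected (counts rounded to nearest, ties broken by node index); the
    index is |selected ∩ network| / |network|. Invariant to positive
    rescaling of the map.
    """
    v = np.asarray(state_map, dtype=float)
    network = np.asarray(list(network_nodes), dtype=int)
    if network.size == 0:
        raise ValueError("empty network")
    if not 0.0 < threshold_frac <= 1.0:
        raise ValueError("threshold_frac must lie in (0, 1]")

    def _top(idx: np.ndarray, magnitude: np.ndarray) -> np.ndarray:
        if idx.size == 0:
            return idx
        n_sel = int(np.floor(threshold_frac * idx.size + 0.5))
        order = np.lexsort((idx, -magnitude))  # by magnitude desc, then node index
        return idx[order[:n_sel]]

    pos = np.flatnonzero(v > 0)
    neg = np.flatnonzero(v < 0)
    selected = set(_top(pos, v[pos]).tolist()) | set(_top(neg, -v[neg]).tolist())
    return len(selected & set(network.tolist())) / network.size


def qc_confound_association(features: pd.DataFrame, mean_fd: pd.DataFrame) -> pd.DataFrame:
    """Correlate every HMM-derived feature with mean FD, per session.

    Pearson r per (feature, session) across subjects, with BH-FDR applied
    jointly across all tests (17 features x 3 sessions = 51 at the study
    defaults). Constant features yield missing r/p and are excluded from
    the correction.
    """
    merged = features.merge(mean_fd, on=["subject", "session"], validate="one_to_one")
    cols = [c for c in feature_columns(features) if c != "mean_fd"]
    rows = []
    for ses, grp in merged.groupby("session", sort=True):
        fd = grp["mean_fd"].to_numpy()
        for col in cols:
            x = grp[col].to_numpy()
            if np.std(x) == 0 or np.std(fd) == 0 or len(x) < 3:
                rows.append({"feature": col, "session": ses, "r": np.nan, "p": np.nan})
            else:
                r, p = pearsonr(x, fd)
                rows.append({"feature": col, "session": ses, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adjusted"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out
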
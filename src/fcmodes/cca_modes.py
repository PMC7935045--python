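"""Canonical correlation between brain features and behavior factors.

CCA finds weight matrices A, B such that the variates U = X A and V = Y B
are maximally correlated, mode by mode. Inference respects the repeated-
measures design: all sessions of a subject form one exchangeability block,
and permutations move X's subject blocks relative to Y only among blocks
with the same session count (so a permuted design stays row-aligned).
Significance of mode k compares its observed canonical correlation to the
permutation distribution of the k-th correlation, with the add-one
convention p = (1 + #{perm >= obs}) / (1 + n_perm). Cross-validation fits
on 80% of subject blocks, projects the held-out 20% with the training
weights, and tests the held-out mode correlation by the same grouped
permutation procedure.

The solver whitens each side with the symmetric inverse square root of its
covariance (eigendecomposition, small eigenvalues dropped -> automatic rank
reduction) and reads modes off the SVD of the whitened cross-covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .behavior_factors import fit_factors
from .static_fc import pca_reduce

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000
DEFAULT_N_FOLDS = 1_000
DEFAULT_TRAIN_FRAC = 0.8
_RANK_RTOL = 1e-10


@dataclass
class GroupStructure:
    """Row -> subject-block mapping; blocks move as units under permutation."""

    subjects: np.ndarray  # one subject label per row

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects)

    @property
    def n_rows(self) -> int:
        return self.subjects.size

    def blocks(self) -> list[np.ndarray]:
        """Row-index arrays per block, in order of first appearance."""
        seen: dict = {}
        for i, s in enumerate(self.subjects):
            seen.setdefault(s, []).append(i)
        return [np.asarray(v) for v in seen.values()]

    def size_classes(self) -> dict[int, list[np.ndarray]]:
        classes: dict[int, list[np.ndarray]] = {}
        for b in self.blocks():
            classes.setdefault(len(b), []).append(b)
        return classes

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, column: str = "subject") -> "GroupStructure":
        return cls(frame[column].to_numpy())


@dataclass
class CCAResult:
    x_weights: np.ndarray       # d1 x m
    y_weights: np.ndarray       # d2 x m
    x_variates: np.ndarray      # n x m
    y_variates: np.ndarray      # n x m
    correlations: np.ndarray    # m, nonincreasing in [0, 1]
    x_mean: np.ndarray
    y_mean: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.correlations.size

    def transform(self, X: np.ndarray, Y: np.ndarray):
        """Project new rows with the fitted weights (training-mean centered)."""
        U = (np.asarray(X, float) - self.x_mean) @ self.x_weights
        V = (np.asarray(Y, float) - self.y_mean) @ self.y_weights
        return U, V


def _whitener(S: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    keep = w > max(w.max(), 0) * _RANK_RTOL
    if not keep.all():
        logger.info("rank-deficient side: keeping %d of %d directions", keep.sum(), keep.size)
    return V[:, keep] / np.sqrt(w[keep])


def cca(X: np.ndarray, Y: np.ndarray) -> CCAResult:
    """Classical CCA of two row-aligned matrices (columns centered internally)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with equal row counts")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    Kx = _whitener(Sxx)
    Ky = _whitener(Syy)
    M = Kx.T @ Sxy @ Ky
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    m = min(Kx.shape[1], Ky.shape[1])
    A = Kx @ u[:, :m]
    B = Ky @ vt[:m].T
    # deterministic sign: largest-|entry| X weight positive per mode
    for j in range(m):
        i = np.argmax(np.abs(A[:, j]))
        if A[i, j] < 0:
            A[:, j] *= -1
            B[:, j] *= -1
    return CCAResult(
        x_weights=A,
        y_weights=B,
        x_variates=Xc @ A,
        y_variates=Yc @ B,
        correlations=np.clip(s[:m], 0.0, 1.0),
        x_mean=x_mean,
        y_mean=y_mean,
    )


# ---------------------------------------------------------------------------
# grouped permutation inference
# ---------------------------------------------------------------------------

def _grouped_permutation(groups: GroupStructure, rng: np.random.Generator) -> np.ndarray:
    """A row permutation moving whole blocks among equal-session-count blocks."""
    perm = np.arange(groups.n_rows)
    for _, members in sorted(groups.size_classes().items()):
        if len(members) < 2:
            continue
        order = rng.permutation(len(members))
        for dest, src in zip(members, (members[i] for i in order)):
            perm[dest] = src
    return perm


def _check_exchangeable(groups: GroupStructure) -> None:
    if all(len(m) < 2 for m in groups.size_classes().values()):
        raise ValueError(
            "no exchange possible: every block has a unique session count"
        )


@dataclass
class PermutationResult:
    p_values: np.ndarray
    observed: np.ndarray
    n_perm: int
    statistic: str


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    groups: GroupStructure,
    n_perm: int = DEFAULT_N_PERM,
    *,
    seed: int = 0,
    statistic: str = "per_mode",
) -> PermutationResult:
    """Permutation p-value per CCA mode under the grouped null.

    ``statistic="per_mode"`` compares mode k's observed correlation to the
    permutation distribution of the k-th correlation; ``"max"`` compares
    every mode to the distribution of the first (largest) correlation for
    family-wise control.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("per_mode", "max"):
        raise ValueError("statistic must be 'per_mode' or 'max'")
    if groups.n_rows != np.asarray(X).shape[0]:
        raise ValueError("groups do not cover the rows")
    _check_exchangeable(groups)
    observed = cca(X, Y).correlations
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = _grouped_permutation(groups, rng)
        corr = cca(np.asarray(X)[perm], Y).correlations
        ref = corr[: observed.size] if statistic == "per_mode" else np.full_like(observed, corr[0])
        exceed += ref >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationResult(p_values=p, observed=observed, n_perm=n_perm, statistic=statistic)


@dataclass
class CrossValidationResult:
    fold_correlations: np.ndarray   # n_folds x m (held-out variate correlations)
    fold_p: np.ndarray              # n_folds x m
    significant_fraction: np.ndarray  # m, fraction of folds with p < alpha
    alpha: float
    train_subjects: list = field(default_factory=list)


def _heldout_corrs(X, Y, train_rows, test_rows, m) -> np.ndarray:
    fit = cca(X[train_rows], Y[train_rows])
    U, V = fit.transform(X[test_rows], Y[test_rows])
    k = min(m, fit.n_modes)
    return np.array([pearsonr(U[:, j], V[:, j])[0] for j in range(k)])


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    groups: GroupStructure,
    n_folds: int = DEFAULT_N_FOLDS,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    *,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> CrossValidationResult:
    """Grouped train/test robustness check of the CCA modes.

    Each fold draws ``train_frac`` of the subject blocks, fits CCA on those
    rows and projects the held-out rows with the training weights; the
    fold statistic is each mode's held-out variate correlation. Its null
    is rebuilt with the same grouped permutation scheme as the main test:
    X's subject blocks are permuted across the whole design (within
    equal-session-count classes), the training CCA is refitted on the
    permuted data, and the held-out correlation recomputed. (Permuting
    only the handful of held-out blocks would leave too few distinct
    rearrangements for the p-value to resolve the test level.)
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    blocks = groups.blocks()
    n_blocks = len(blocks)
    n_train = int(round(train_frac * n_blocks))
    if n_blocks - n_train < 3:
        raise ValueError("held-out set would have fewer than 3 blocks")
    _check_exchangeable(groups)
    rng = np.random.default_rng(seed)
    m = min(np.linalg.matrix_rank(X - X.mean(0)), np.linalg.matrix_rank(Y - Y.mean(0)))
    fold_corr = np.zeros((n_folds, m))
    fold_p = np.ones((n_folds, m))
    train_subject_log = []
    for f in range(n_folds):
        order = rng.permutation(n_blocks)
        train_rows = np.concatenate([blocks[i] for i in order[:n_train]])
        test_rows = np.concatenate([blocks[i] for i in order[n_train:]])
        obs = _heldout_corrs(X, Y, train_rows, test_rows, m)
        k = obs.size
        exceed = np.zeros(k)
        for _ in range(n_perm):
            perm = _grouped_permutation(groups, rng)
            exceed += _heldout_corrs(X[perm], Y, train_rows, test_rows, m)[:k] >= obs
        fold_corr[f, :k] = obs
        fold_p[f, :k] = (1.0 + exceed) / (1.0 + n_perm)
        train_subject_log.append(sorted(set(groups.subjects[train_rows].tolist())))
    return CrossValidationResult(
        fold_correlations=fold_corr,
        fold_p=fold_p,
        significant_fraction=(fold_p < alpha).mean(axis=0),
        alpha=alpha,
        train_subjects=train_subject_log,
    )


def posthoc_loadings(
    result: CCAResult,
    X: np.ndarray,
    Y: np.ndarray,
    x_names=None,
    y_names=None,
) -> pd.DataFrame:
    """Pearson r of each original variable with its own side's variates."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    x_names = list(x_names) if x_names is not None else [f"x{j + 1}" for j in range(X.shape[1])]
    y_names = list(y_names) if y_names is not None else [f"y{j + 1}" for j in range(Y.shape[1])]
    rows = []
    for side, data, names, variates in (
        ("x", X, x_names, result.x_variates),
        ("y", Y, y_names, result.y_variates),
    ):
        for mode in range(result.n_modes):
            v = variates[:, mode]
            for j, name in enumerate(names):
                col = data[:, j]
                if np.std(col) == 0 or np.std(v) == 0:
                    logger.info("constant variable %s: loading undefined", name)
                    r = np.nan
                else:
                    r = pearsonr(col, v)[0]
                rows.append({"side": side, "variable": name, "mode": mode + 1, "r": r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mode-stability sweep over (n_factors, n_pcs) configurations
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    configs: list                  # (n_factors, n_pcs) in enumeration order
    measure_loadings: np.ndarray   # n_configs x n_measures (NaN rows = failed fits)
    similarity: np.ndarray         # n_configs x n_configs Pearson r


def mode_stability_sweep(
    brain_features: np.ndarray,
    behavior_table: pd.DataFrame,
    factor_range=range(1, 10),
    pc_range=range(1, 21),
    *,
    mode: int = 1,
    seed: int = 0,
) -> SweepResult:
    """First-mode behavioral loading stability across analysis settings.

    For every (number of behavioral factors, number of brain PCs) pair the
    pipeline is re-run (factor scores -> PCA scores -> CCA) and the post
    hoc correlations of the raw behavioral measures with the mode's
    behavioral variate are stored; similarity is the Pearson correlation
    between those loading vectors across configurations (sign-agnostic
    summaries are up to the caller). Configurations that fail to fit are
    recorded as missing and the sweep continues.
    """
    id_cols = [c for c in ("subject", "session") if c in behavior_table.columns]
    measures = [c for c in behavior_table.columns if c not in id_cols]
    raw = behavior_table[measures].to_numpy(dtype=float)

    factor_scores: dict[int, np.ndarray] = {}
    for nf in factor_range:
        try:
            factor_scores[nf] = fit_factors(behavior_table, nf, seed=seed).score_matrix()
        except Exception as exc:  # recorded as missing below
            logger.warning("factor fit failed at n_factors=%d: %s", nf, exc)

    configs, vectors = [], []
    for nf in factor_range:
        for npc in pc_range:
            configs.append((nf, npc))
            try:
                Yf = factor_scores[nf]
                Xp = pca_reduce(brain_features, npc).scores
                fit = cca(Xp, Yf)
                v = fit.y_variates[:, mode - 1]
                loads = np.array([
                    pearsonr(raw[:, j], v)[0] if np.std(raw[:, j]) > 0 else np.nan
                    for j in range(raw.shape[1])
                ])
                vectors.append(loads)
            except Exception as exc:
                logger.warning("sweep config (nf=%s, npc=%s) failed: %s", nf, npc, exc)
                vectors.append(np.full(raw.shape[1], np.nan))
    V = np.vstack(vectors)
    n_cfg = len(configs)
    sim = np.full((n_cfg, n_cfg), np.nan)
    for i in range(n_cfg):
        for j in range(i, n_cfg):
            a, b = V[i], V[j]
            if np.isnan(a).any() or np.isnan(b).any() or a.std() == 0 or b.std() == 0:
                continue
            sim[i, j] = sim[j, i] = pearsonr(a, b)[0]
    return SweepResult(configs=configs, measure_loadings=V, similarity=sim)
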
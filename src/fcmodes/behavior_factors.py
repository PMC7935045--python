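"""Exploratory factor analysis of the 31-measure behavioral battery.

Measures are standardized, factored by maximum likelihood (default 8
factors), rotated obliquely with promax (power 4, after varimax), and
scored by the regression (Thurstone) method. The oblique solution reports
a pattern-loading matrix and a factor correlation matrix Phi; communalities
are diag(L Phi L').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

# qualitative factor labels of the emulated battery, in factor order
STUDY_FACTOR_LABELS: tuple[str, ...] = (
    "Processing Reaction Time",
    "Task General",
    "Working Memory Reaction Time",
    "Working Memory Precision Reaction Time",
    "Affect",
    "Processing Accuracy",
    "Arousal",
    "Impulsivity",
)

DEFAULT_N_FACTORS = 8
_PROMAX_POWER = 4


@dataclass
class FactorSolution:
    """Oblique factor solution for a behavior table."""

    loadings: pd.DataFrame        # measures x factors (pattern matrix)
    phi: np.ndarray               # factor correlation matrix
    scores: pd.DataFrame          # subject, session + factor score columns
    uniquenesses: np.ndarray
    labels: tuple[str, ...]
    converged: bool

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        return np.einsum("if,fg,ig->i", L, self.phi, L)

    def score_matrix(self) -> np.ndarray:
        return self.scores[list(self.scores.columns[2:])].to_numpy()


def _varimax(loadings: np.ndarray, max_iter: int = 1000, tol: float = 1e-12):
    """Varimax rotation with Kaiser row normalization; returns (rotated, R)."""
    L = loadings.copy()
    p, k = L.shape
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    L = L / h[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        B = L.T @ (Lr**3 - Lr * ((Lr**2).sum(axis=0) / p))
        u, s, vt = np.linalg.svd(B)
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    return (L @ R) * h[:, None], R


def _promax(loadings: np.ndarray, power: int = _PROMAX_POWER):
    """Promax oblique rotation (varimax target raised elementwise to ``power``).

    Returns (pattern, phi, rotation) with ``pattern = loadings @ rotation``
    and ``phi`` the factor correlation matrix.
    """
    V, R_vm = _varimax(loadings)
    target = V * np.abs(V) ** (power - 1)
    U, *_ = np.linalg.lstsq(V, target, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    rotation = R_vm @ U
    ui = np.linalg.inv(rotation)
    phi = ui @ ui.T
    return loadings @ rotation, phi, rotation


def fit_factors(
    table: pd.DataFrame,
    n_factors: int = DEFAULT_N_FACTORS,
    *,
    rotate: bool = True,
    max_iter: int = 2000,
    seed: int = 0,
) -> FactorSolution:
    """Maximum-likelihood factor analysis with promax rotation.

    ``table`` carries subject/session identifier columns plus the measure
    columns; measures are standardized internally, so scores are invariant
    to affine rescaling of the inputs.
    """
    id_cols = [c for c in ("subject", "session") if c in table.columns]
    measures = [c for c in table.columns if c not in id_cols]
    X = table[measures].to_numpy(dtype=float)
    n, p = X.shape
    if n <= n_factors:
        raise ValueError("need more rows than factors")
    if n_factors < 1 or n_factors >= p:
        raise ValueError("n_factors must lie in [1, n_measures)")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [measures[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant measure(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd

    fa = FactorAnalysis(n_components=n_factors, max_iter=max_iter,
                        svd_method="lapack", random_state=seed)
    fa.fit(Z)
    if fa.n_iter_ >= max_iter:
        raise RuntimeError(f"factor extraction did not converge in {max_iter} iterations")
    L0 = fa.components_.T  # p x k, unrotated ML loadings (standardized metric)

    if rotate and n_factors > 1:
        L, phi, _ = _promax(L0)
    else:
        L, phi = L0, np.eye(n_factors)

    comm = np.einsum("if,fg,ig->i", L, phi, L)
    if np.any(comm > 1 + 1e-6):
        warnings.warn(
            f"Heywood case: communalities up to {comm.max():.4f} exceed 1; clipping",
            RuntimeWarning,
        )
        comm = np.minimum(comm, 1.0)
    uniq = np.clip(1.0 - comm, 0.0, None)

    # regression-method scores: F = Z R^{-1} S with S = L Phi (structure matrix)
    R = np.corrcoef(Z.T)
    S = L @ phi
    scores = Z @ np.linalg.pinv(R) @ S

    score_df = table[id_cols].copy()
    for f in range(n_factors):
        score_df[f"factor_{f + 1}"] = scores[:, f]
    return FactorSolution(
        loadings=pd.DataFrame(L, index=measures,
                              columns=[f"factor_{f + 1}" for f in range(n_factors)]),
        phi=phi,
        scores=score_df,
        uniquenesses=uniq,
        labels=tuple(f"factor_{f + 1}" for f in range(n_factors)),
        converged=True,
    )


def label_factors(solution: FactorSolution, labels=None) -> FactorSolution:
    """Attach qualitative factor labels.

    Pass a sequence of unique labels (one per factor, in factor order) or
    None to auto-name each factor after its top-|loading| measure.
    """
    k = solution.n_factors
    if labels is None:
        L = solution.loadings
        labels = []
        for col in L.columns:
            top = L[col].abs().idxmax()
            label = str(top)
            while label in labels:
                label += "+"
            labels.append(label)
    labels = list(labels)
    if len(labels) != k:
        raise ValueError(f"expected {k} labels, got {len(labels)}")
    if len(set(labels)) != k:
        raise ValueError("duplicate factor labels")
    loadings = solution.loadings.copy()
    loadings.columns = labels
    return replace(solution, loadings=loadings, labels=tuple(labels))
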
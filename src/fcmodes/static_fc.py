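"""Static functional connectivity: correlation matrices, edge vectors, PCA.

One full Pearson correlation matrix per subject-session, vectorized over
the upper triangle (row-major, diagonal excluded — 439 nodes give 96,141
edges), then reduced with column-centered PCA before CCA. Node indices are
0-based internally and reported 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

_SYMMETRY_TOL = 1e-8


@dataclass
class FCMatrix:
    """Symmetric node x node Pearson correlation matrix, unit diagonal."""

    values: np.ndarray
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric to 1e-12")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("FC matrix diagonal must be 1")
        if v.min() < -1 - 1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def correlation_matrix(ts: np.ndarray, subject_id: str = "", session_id: str = "") -> FCMatrix:
    """Pearson correlation between every node pair of a timepoints x nodes matrix."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a timepoints x nodes matrix with >= 3 timepoints")
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance node(s): {bad.tolist()}")
    c = np.corrcoef(ts.T)
    c = np.clip(0.5 * (c + c.T), -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return FCMatrix(c, subject_id, session_id)


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def edge_index(n_nodes: int) -> list[tuple[int, int]]:
    """Canonical edge ordering: upper triangle, row-major, 0-based."""
    iu = np.triu_indices(n_nodes, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def vectorize_edges(m: FCMatrix | np.ndarray) -> np.ndarray:
    """Upper-triangle edge vector of length p(p-1)/2 in canonical order."""
    v = m.values if isinstance(m, FCMatrix) else np.asarray(m, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(v, v.T, atol=_SYMMETRY_TOL):
        raise ValueError("matrix is asymmetric beyond tolerance")
    return v[np.triu_indices(v.shape[0], k=1)]


def devectorize_edges(edges: np.ndarray, n_nodes: int, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges` (diagonal restored)."""
    edges = np.asarray(edges, dtype=float)
    if edges.size != n_edges(n_nodes):
        raise ValueError(f"expected {n_edges(n_nodes)} edges for {n_nodes} nodes")
    out = np.full((n_nodes, n_nodes), diagonal)
    iu = np.triu_indices(n_nodes, k=1)
    out[iu] = edges
    out[(iu[1], iu[0])] = edges
    return out


@dataclass
class PCAResult:
    scores: np.ndarray             # rows x k
    components: np.ndarray         # k x features
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca_reduce(X: np.ndarray, n_components: int) -> PCAResult:
    """Column-centered PCA, components ordered by nonincreasing variance."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    k_max = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= k_max:
        raise ValueError(f"n_components must lie in [1, {k_max}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(
        scores=scores,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )
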
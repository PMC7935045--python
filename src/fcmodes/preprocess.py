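"""Postprocessing of node-level BOLD time series.

The pipeline applied to each run/session is the standard resting-state
postprocessing chain: nuisance (confound) regression, temporal bandpass
filtering, and per-session standardization before concatenation across
subjects. Framewise displacement (FD) is computed from the six rigid-body
motion parameters as the sum of absolute backward differences of the three
translations (mm) plus the rotations (radians) projected onto a 50 mm
sphere.

The fixed order is: confound regression -> bandpass -> standardization.
No scrubbing and no global-signal regression are performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

DEFAULT_BAND_HZ = (0.01, 0.1)
DEFAULT_FD_RADIUS_MM = 50.0
_FILTER_ORDER = 4  # forward-backward Butterworth -> zero phase


@dataclass
class NodeTimeSeries:
    """One run of node-wise signals: ``data`` is timepoints x nodes."""

    subject_id: str
    session_id: str
    run_id: str
    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("data must be a timepoints x nodes matrix with >= 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in time series data")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


def expand_confounds(base: np.ndarray) -> np.ndarray:
    """Expand base confound regressors to the 4x set.

    Columns are [base, temporal derivative, base^2, derivative^2] where the
    derivative is the backward first difference with the first frame set to
    zero. Eight base regressors (6 motion + WM + CSF) expand to 32 columns.
    """
    base = np.atleast_2d(np.asarray(base, dtype=float))
    if base.shape[1] == 0:
        raise ValueError("need at least one base regressor")
    deriv = np.vstack([np.zeros((1, base.shape[1])), np.diff(base, axis=0)])
    return np.hstack([base, deriv, base**2, deriv**2])


def regress_confounds(ts: NodeTimeSeries, design: np.ndarray | None) -> NodeTimeSeries:
    """Residualize node signals against a confound design (intercept included).

    Least-squares projection; residuals are orthogonal to every design
    column. A rank-deficient design is handled by the minimum-norm solution
    (equivalent to dropping dependent columns) and logged.
    """
    y = ts.data
    n = y.shape[0]
    if design is None or np.size(design) == 0:
        resid = y - y.mean(axis=0, keepdims=True)
        return replace(ts, data=resid)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] != n:
        raise ValueError(f"design has {design.shape[0]} rows, data has {n}")
    X = np.column_stack([np.ones(n), design])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "rank-deficient confound design (rank %d < %d columns); "
            "dependent columns contribute nothing to the projection",
            rank, X.shape[1],
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return replace(ts, data=y - X @ beta)


def bandpass(
    ts: NodeTimeSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> NodeTimeSeries:
    """Zero-phase Butterworth bandpass (default 0.01-0.1 Hz)."""
    fs = 1.0 / ts.tr
    nyquist = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist:.4g} Hz (TR={ts.tr}s)"
        )
    sos = signal.butter(_FILTER_ORDER, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return replace(ts, data=np.ascontiguousarray(filtered))


def _session_sort_key(ts: NodeTimeSeries):
    return (ts.subject_id, ts.session_id, ts.run_id)


def standardize_concat(runs: Sequence[NodeTimeSeries]) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate runs within session, z-score per session, stack sessions.

    Runs are grouped by (subject, session) and concatenated in run order;
    each session block is standardized per node (mean 0, SD 1, population
    SD). Returns the stacked matrix and a block index with one row per
    subject-session giving its [start, stop) row range.
    """
    if not runs:
        raise ValueError("no runs supplied")
    p = runs[0].n_nodes
    if any(r.n_nodes != p for r in runs):
        raise ValueError("node columns do not align across runs")
    groups: dict[tuple[str, str], list[NodeTimeSeries]] = {}
    for r in sorted(runs, key=_session_sort_key):
        groups.setdefault((r.subject_id, r.session_id), []).append(r)

    blocks, pieces, start = [], [], 0
    for (sub, ses), members in groups.items():
        block = np.vstack([m.data for m in members])
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"zero-variance node(s) {bad.tolist()} in subject={sub} session={ses}"
            )
        pieces.append((block - mu) / sd)
        stop = start + block.shape[0]
        blocks.append({"subject": sub, "session": ses, "start": start, "stop": stop})
        start = stop
    X = np.vstack(pieces)
    return X, pd.DataFrame(blocks)


def framewise_displacement(motion: np.ndarray, radius_mm: float = DEFAULT_FD_RADIUS_MM) -> np.ndarray:
    """FD per frame from a T x 6 motion table.

    Columns 0-2 are translations in mm, 3-5 rotations in radians; rotations
    are converted to arc length on a sphere of ``radius_mm``. FD of the
    first frame is 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have exactly 6 columns (3 trans mm, 3 rot rad)")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def mean_fd_table(
    motion_tables: dict[tuple[str, str, str], np.ndarray],
    radius_mm: float = DEFAULT_FD_RADIUS_MM,
) -> pd.DataFrame:
    """Mean FD per subject-session, averaged across that session's runs."""
    rows: dict[tuple[str, str], list[float]] = {}
    for (sub, ses, _run), table in motion_tables.items():
        rows.setdefault((sub, ses), []).append(float(framewise_displacement(table, radius_mm).mean()))
    return pd.DataFrame(
        [{"subject": s, "session": ses, "mean_fd": float(np.mean(v))} for (s, ses), v in sorted(rows.items())]
    )
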
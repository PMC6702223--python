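"""ROI time series to per-paradigm connectivity matrices.

Stages, in the order they are applied: nuisance regression (task
regressors, white-matter and CSF signals, the 24-parameter head-motion
expansion, frame-wise displacement), zero-phase temporal filtering
(high-pass for task runs, band-pass for rest), Pearson correlation, and
session averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "RoiTimeSeries",
    "NuisanceSet",
    "FilterSpec",
    "ConnectivityMatrix",
    "expand_motion_regressors",
    "regress_nuisance",
    "temporal_filter",
    "pearson_connectivity",
    "average_sessions",
]

logger = logging.getLogger(__name__)


@dataclass
class RoiTimeSeries:
    """Node-by-timepoint matrix of ROI mean signals for one scan run."""

    subject_id: str
    paradigm_id: str
    session_id: str
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D node x timepoint matrix")
        n_nodes, n_tp = self.data.shape
        if n_nodes < 2:
            raise ValueError(f"need >= 2 nodes, got {n_nodes}")
        if n_tp < 16:
            raise ValueError(f"need >= 16 timepoints, got {n_tp}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class NuisanceSet:
    """Per-run nuisance regressors; every series spans the full run."""

    task_regressors: np.ndarray | None = None  # timepoint x k, k may be 0
    wm_signal: np.ndarray | None = None
    csf_signal: np.ndarray | None = None
    motion6: np.ndarray | None = None  # timepoint x 6 rigid-body parameters
    fd: np.ndarray | None = None  # frame-wise displacement, mm

    def validate(self, n_timepoints: int) -> None:
        def check(name: str, arr, ncol: int | None = None) -> None:
            if arr is None:
                return
            a = np.asarray(arr, dtype=float)
            if a.shape[0] != n_timepoints:
                raise ValueError(f"{name} has {a.shape[0]} rows, expected {n_timepoints}")
            if ncol is not None and (a.ndim != 2 or a.shape[1] != ncol):
                raise ValueError(f"{name} must be timepoint x {ncol}")

        check("task_regressors", self.task_regressors)
        check("wm_signal", self.wm_signal)
        check("csf_signal", self.csf_signal)
        check("motion6", self.motion6, 6)
        check("fd", self.fd)
        if self.fd is not None and np.any(np.asarray(self.fd) < 0):
            raise ValueError("FD must be nonnegative")


@dataclass(frozen=True)
class FilterSpec:
    """Band edges in Hz for the zero-phase temporal filter."""

    mode: str  # "highpass" or "bandpass"
    low_hz: float
    high_hz: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("highpass", "bandpass"):
            raise ValueError(f"mode must be highpass or bandpass, got {self.mode!r}")
        if self.low_hz <= 0:
            raise ValueError("low_hz must be positive")
        if self.mode == "bandpass":
            if self.high_hz is None or self.high_hz <= self.low_hz:
                raise ValueError("bandpass needs 0 < low_hz < high_hz")

    @classmethod
    def parse(cls, text: str) -> "FilterSpec":
        """Parse ``highpass:0.008`` or ``bandpass:0.008-0.1``."""
        mode, _, edges = text.partition(":")
        if mode == "highpass":
            return cls("highpass", float(edges))
        if mode == "bandpass":
            lo, _, hi = edges.partition("-")
            return cls("bandpass", float(lo), float(hi))
        raise ValueError(f"cannot parse filter spec {text!r}")


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node Pearson matrix with unit diagonal."""

    subject_id: str
    paradigm_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("connectivity matrix diagonal must be 1")
        if np.nanmax(np.abs(v)) > 1.0 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def expand_motion_regressors(motion6: np.ndarray) -> np.ndarray:
    """Expand six rigid-body parameters to the 24-parameter set.

    Columns are ordered [6 parameters, 6 backward-difference derivatives
    (first row 0), 6 squared parameters, 6 squared derivatives].
    """
    m = np.asarray(motion6, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion6 must be timepoint x 6, got shape {m.shape}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 timepoints to form derivatives")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
    return np.hstack([m, deriv, m**2, deriv**2])


def _design_matrix(ts: RoiTimeSeries, nuisance: NuisanceSet | None) -> tuple[np.ndarray, list[str]]:
    n_tp = ts.n_timepoints
    cols: list[np.ndarray] = [np.ones(n_tp)]
    names: list[str] = ["intercept"]
    if nuisance is not None:
        nuisance.validate(n_tp)
        if nuisance.task_regressors is not None:
            tr = np.atleast_2d(np.asarray(nuisance.task_regressors, dtype=float))
            if tr.shape[0] != n_tp:
                tr = tr.T
            for j in range(tr.shape[1]):
                cols.append(tr[:, j])
                names.append(f"task{j}")
        for name, sig_ in (("wm", nuisance.wm_signal), ("csf", nuisance.csf_signal)):
            if sig_ is not None:
                cols.append(np.asarray(sig_, dtype=float).ravel())
                names.append(name)
        if nuisance.motion6 is not None:
            m24 = expand_motion_regressors(nuisance.motion6)
            for j in range(24):
                cols.append(m24[:, j])
                names.append(f"motion{j}")
        if nuisance.fd is not None:
            cols.append(np.asarray(nuisance.fd, dtype=float).ravel())
            names.append("fd")
    return np.column_stack(cols), names


def _drop_collinear(design: np.ndarray, names: list[str],
                    tol: float = 1e-10) -> tuple[np.ndarray, list[str]]:
    """Greedy left-to-right scan: a column exactly reproducible from the
    columns already kept is dropped (the later column loses)."""
    kept: list[int] = []
    q: np.ndarray | None = None
    for j in range(design.shape[1]):
        col = design[:, j]
        resid = col - q @ (q.T @ col) if q is not None else col.copy()
        norm = np.linalg.norm(resid)
        scale = max(np.linalg.norm(col), 1.0)
        if norm <= tol * scale:
            logger.warning("dropping exactly collinear regressor %r", names[j])
            continue
        kept.append(j)
        qcol = (resid / norm)[:, None]
        q = qcol if q is None else np.hstack([q, qcol])
    return design[:, kept], [names[j] for j in kept]


def regress_nuisance(ts: RoiTimeSeries, nuisance: NuisanceSet | None = None) -> RoiTimeSeries:
    """OLS residuals of every node series against the nuisance design.

    The design is intercept + task regressors + WM + CSF + 24 motion
    parameters (expanded internally from the six rigid-body series) + FD.
    Exactly collinear columns are dropped deterministically.  With an empty
    nuisance set this reduces to demeaning.
    """
    design, names = _design_matrix(ts, nuisance)
    design, names = _drop_collinear(design, names)
    if design.shape[1] >= ts.n_timepoints:
        raise ValueError(
            f"deficient design: {design.shape[1]} regressors ({', '.join(names)}) "
            f"for {ts.n_timepoints} timepoints")
    y = ts.data.T  # timepoint x node
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return RoiTimeSeries(ts.subject_id, ts.paradigm_id, ts.session_id,
                         resid.T, ts.tr_seconds)


def temporal_filter(ts: RoiTimeSeries, spec: FilterSpec) -> RoiTimeSeries:
    """Zero-phase 4th-order Butterworth filter (forward-backward).

    Series are demeaned before filtering; the high-pass edge removes any
    remaining DC component.
    """
    fs = 1.0 / ts.tr_seconds
    nyquist = fs / 2.0
    if spec.low_hz >= nyquist:
        raise ValueError(f"low edge {spec.low_hz} Hz at/above Nyquist {nyquist:.4f} Hz")
    if spec.mode == "bandpass":
        if spec.high_hz >= nyquist:
            raise ValueError(f"high edge {spec.high_hz} Hz at/above Nyquist {nyquist:.4f} Hz")
        sos = signal.butter(4, [spec.low_hz, spec.high_hz], btype="bandpass",
                            fs=fs, output="sos")
    else:
        sos = signal.butter(4, spec.low_hz, btype="highpass", fs=fs, output="sos")
    data = ts.data - ts.data.mean(axis=1, keepdims=True)
    filtered = signal.sosfiltfilt(sos, data, axis=1)
    return RoiTimeSeries(ts.subject_id, ts.paradigm_id, ts.session_id,
                         filtered, ts.tr_seconds)


def pearson_connectivity(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation matrix of the node series."""
    sd = ts.data.std(axis=1)
    # a constant series has zero range; sd may be ~1e-16 from cancellation
    bad = np.flatnonzero((sd == 0.0) | (np.ptp(ts.data, axis=1) == 0.0))
    if bad.size:
        raise ValueError(f"zero-variance node(s) at index {bad.tolist()}")
    r = np.corrcoef(ts.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(ts.subject_id, ts.paradigm_id, r)


def average_sessions(matrices: Sequence[ConnectivityMatrix],
                     fisher_z: bool = False) -> ConnectivityMatrix:
    """Entrywise mean of one subject/paradigm's session matrices.

    The default averages raw correlations; ``fisher_z=True`` averages on
    the arctanh scale and transforms back.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("session matrices differ in shape")
        if (m.subject_id, m.paradigm_id) != (first.subject_id, first.paradigm_id):
            raise ValueError("session matrices belong to different subject/paradigm")
    stack = np.stack([m.values for m in matrices])
    if fisher_z:
        clipped = np.clip(stack, -1.0 + 1e-15, 1.0 - 1e-15)
        avg = np.tanh(np.arctanh(clipped).mean(axis=0))
    else:
        avg = stack.mean(axis=0)
    np.fill_diagonal(avg, 1.0)
    return ConnectivityMatrix(first.subject_id, first.paradigm_id, avg)
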
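"""Construction of HRF-convolved regressors and first-level design matrices.

Events are specified in seconds from the start of their run, as half-open
intervals ``[onset, onset + duration)``; a duration of zero denotes an
impulse (a unit point mass at the onset).  Neural signals are built on an
oversampled "microtime" grid, convolved with a sampled hemodynamic response
kernel, and read out at scan acquisition times (every ``dt`` seconds).

The canonical kernel is the SPM double-gamma response (via nilearn's
``spm_hrf``), normalized to unit sum over its samples so that a sustained
unit-amplitude neural signal converges to a BOLD plateau of 1.  With that
convention, boxcar regressor amplitudes are proportional to event duration
for short events, and impulse regressors are sampled versions of the HRF
density itself — both independent of the oversampling factor chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import spm_hrf
from scipy.signal import fftconvolve

__all__ = [
    "TimeGrid",
    "HrfKernel",
    "EventTable",
    "DesignMatrix",
    "canonical_hrf",
    "temporal_derivative_kernel",
    "make_regressor",
    "cosine_drift_basis",
    "per_run_drift_regressors",
    "assemble_design",
    "read_events_tsv",
    "write_events_tsv",
]

#: BIDS events columns that must be present in every events TSV.
MANDATORY_EVENT_COLUMNS = ("onset", "duration", "trial_type")


@dataclass(frozen=True)
class TimeGrid:
    """Scan sampling grid for one or more runs.

    Parameters
    ----------
    run_lengths : tuple of float
        Duration of each run in seconds.  Each run contributes
        ``round(length / dt)`` scans.
    dt : float
        Sampling (repetition) interval in seconds.  Default 0.8.
    oversampling : int
        Microtime resolution factor; neural signals and the HRF are
        sampled at ``dt / oversampling``.  Default 50 (16 ms at dt=0.8),
        fine enough to preserve tens-of-milliseconds duration differences.
    """

    run_lengths: tuple[float, ...]
    dt: float = 0.8
    oversampling: int = 50

    def __post_init__(self) -> None:
        object.__setattr__(self, "run_lengths", tuple(float(x) for x in self.run_lengths))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if int(self.oversampling) < 1:
            raise ValueError("oversampling must be a positive integer")
        if not self.run_lengths or any(x <= 0 for x in self.run_lengths):
            raise ValueError("run lengths must be positive")

    @property
    def dt_micro(self) -> float:
        return self.dt / self.oversampling

    @property
    def n_scans_per_run(self) -> tuple[int, ...]:
        return tuple(int(round(x / self.dt)) for x in self.run_lengths)

    @property
    def n_scans(self) -> int:
        return sum(self.n_scans_per_run)

    @property
    def n_runs(self) -> int:
        return len(self.run_lengths)


@dataclass(frozen=True)
class HrfKernel:
    """A hemodynamic response kernel sampled at microtime resolution."""

    values: np.ndarray
    dt_micro: float
    span: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("kernel samples must be finite")
        object.__setattr__(self, "values", values)


def canonical_hrf(dt_micro: float, span: float = 32.0) -> HrfKernel:
    """Sample the canonical double-gamma HRF at ``dt_micro`` resolution.

    The kernel is SPM's difference of gamma densities (response peak delay
    6 s, undershoot delay 16 s, unit dispersions, peak:undershoot ratio 6),
    normalized to unit sum.  Its mode falls near 5 s post-onset.
    """
    if dt_micro <= 0:
        raise ValueError("dt_micro must be positive")
    if span < 24.0:
        raise ValueError("kernel span must cover the undershoot (>= 24 s)")
    values = spm_hrf(dt_micro, oversampling=1, time_length=span)
    values = values / values.sum()
    return HrfKernel(values=values, dt_micro=dt_micro, span=span)


def temporal_derivative_kernel(base: HrfKernel) -> HrfKernel:
    """First-order finite-difference derivative of a kernel.

    The derivative is left un-normalized: only its column space matters
    when it enters a design, so any scaling convention yields the same
    diagnostics and fits.
    """
    values = np.diff(base.values, prepend=0.0) / base.dt_micro
    return replace(base, values=values)


class EventTable:
    """Ordered collection of events with BIDS-style columns.

    Wraps a :class:`pandas.DataFrame` with mandatory columns ``onset``,
    ``duration`` and ``trial_type``; optional columns (``run``,
    ``amplitude``, ``response_time``, ``outcome``, ...) are preserved.
    Events are kept sorted by (run, onset).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in MANDATORY_EVENT_COLUMNS:
            if col not in frame.columns:
                raise ValueError(f"events table is missing mandatory column {col!r}")
        if "run" not in frame.columns:
            frame["run"] = 0
        if "amplitude" not in frame.columns:
            frame["amplitude"] = 1.0
        frame["onset"] = frame["onset"].astype(float)
        frame["duration"] = frame["duration"].astype(float)
        if (frame["onset"] < 0).any():
            raise ValueError("event onsets must be non-negative")
        if (frame["duration"] < 0).any():
            raise ValueError("event durations must be non-negative")
        if frame["trial_type"].astype(str).str.len().eq(0).any():
            raise ValueError("trial_type labels must be non-empty")
        self.frame = frame.sort_values(["run", "onset"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, trial_type: str) -> "EventTable":
        return EventTable(self.frame[self.frame["trial_type"] == trial_type])

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["trial_type"]))


def _neural_signal(
    events: EventTable, grid: TimeGrid, run: int, shape: str
) -> np.ndarray:
    """Sample the neural model for one run on the microtime grid."""
    n_micro = grid.n_scans_per_run[run] * grid.oversampling
    dtm = grid.dt_micro
    signal = np.zeros(n_micro)
    sub = events.frame[events.frame["run"] == run]
    run_len = grid.n_scans_per_run[run] * grid.dt
    eps = 1e-9
    for onset, duration, amplitude in zip(sub["onset"], sub["duration"], sub["amplitude"]):
        if onset < 0 or onset + duration > run_len + eps:
            raise ValueError(
                f"event at {onset:.3f}s (duration {duration:.3f}s) falls outside "
                f"run {run} of length {run_len:.3f}s"
            )
        if shape == "impulse" or duration == 0:
            idx = min(int(round(onset / dtm)), n_micro - 1)
            signal[idx] += amplitude / dtm  # unit point mass
        elif shape == "boxcar":
            start = int(np.ceil(onset / dtm - eps))
            stop = int(np.ceil((onset + duration) / dtm - eps))
            signal[start : min(stop, n_micro)] += amplitude
        else:
            raise ValueError(f"unknown regressor shape {shape!r}")
    return signal


def make_regressor(
    events: EventTable,
    grid: TimeGrid,
    shape: str = "boxcar",
    kernel: HrfKernel | None = None,
    with_derivative: bool = False,
) -> np.ndarray:
    """Build one (or two) HRF-convolved regressors sampled at scan times.

    Returns an array of shape ``(n_scans,)`` or, when ``with_derivative``
    is set, ``(n_scans, 2)`` with the canonical regressor first.  Runs are
    convolved independently and concatenated.
    """
    if kernel is None:
        kernel = canonical_hrf(grid.dt_micro)
    if abs(kernel.dt_micro - grid.dt_micro) > 1e-12:
        raise ValueError("kernel resolution does not match the grid's microtime step")
    kernels = [kernel.values]
    if with_derivative:
        kernels.append(temporal_derivative_kernel(kernel).values)

    pieces = []
    for run in range(grid.n_runs):
        neural = _neural_signal(events, grid, run, shape)
        cols = []
        for kv in kernels:
            conv = fftconvolve(neural, kv)[: len(neural)]
            cols.append(conv[:: grid.oversampling])
        pieces.append(np.column_stack(cols))
    out = np.concatenate(pieces, axis=0)
    return out[:, 0] if not with_derivative else out


def cosine_drift_basis(n_scans: int, dt: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass basis for one run.

    Returns an ``(n_scans, K)`` matrix with ``K = floor(2 T / cutoff)``
    unit-norm DCT-II columns (``T`` the run length in seconds), the set of
    slow cosines removed by a high-pass filter at the given cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    total = n_scans * dt
    k_max = int(np.floor(2.0 * total / cutoff))
    i = np.arange(n_scans)
    cols = [
        np.cos(np.pi * k * (2 * i + 1) / (2 * n_scans)) * np.sqrt(2.0 / n_scans)
        for k in range(1, k_max + 1)
    ]
    if not cols:
        return np.zeros((n_scans, 0))
    return np.column_stack(cols)


def per_run_drift_regressors(grid: TimeGrid, cutoff: float = 128.0) -> dict[str, np.ndarray]:
    """Block-diagonal drift columns, one DCT set per run, zero elsewhere."""
    out: dict[str, np.ndarray] = {}
    offsets = np.concatenate([[0], np.cumsum(grid.n_scans_per_run)])
    for run, n_run in enumerate(grid.n_scans_per_run):
        basis = cosine_drift_basis(n_run, grid.dt, cutoff)
        for k in range(basis.shape[1]):
            col = np.zeros(grid.n_scans)
            col[offsets[run] : offsets[run + 1]] = basis[:, k]
            out[f"drift_run{run}_{k + 1}"] = col
    return out


@dataclass
class DesignMatrix:
    """Scans x regressors matrix with named columns and run structure."""

    frame: pd.DataFrame
    grid: TimeGrid
    task_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            dupes = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate design column names: {dupes}")
        missing = [c for c in self.task_columns if c not in self.frame.columns]
        if missing:
            raise ValueError(f"task columns absent from design: {missing}")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def column_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, grid: TimeGrid | None = None,
                 task_columns: list[str] | None = None) -> "DesignMatrix":
        frame = pd.read_csv(path, sep="\t")
        if grid is None:
            grid = TimeGrid(run_lengths=(len(frame) * 0.8,))
        if task_columns is None:
            task_columns = [c for c in frame.columns
                            if c != "intercept" and not c.startswith("drift_")]
        return cls(frame=frame, grid=grid, task_columns=task_columns)


def assemble_design(
    task_regressors: dict[str, np.ndarray],
    grid: TimeGrid,
    nuisance: dict[str, np.ndarray] | None = None,
    intercept: bool = True,
) -> DesignMatrix:
    """Concatenate task, nuisance and intercept columns into a design.

    All regressors must already be sampled on the full concatenated scan
    grid.  A single intercept spans all runs (run-specific means belong in
    per-run drift blocks if needed).
    """
    nuisance = nuisance or {}
    columns: dict[str, np.ndarray] = {}
    for name, values in {**task_regressors, **nuisance}.items():
        values = np.asarray(values, dtype=float)
        if values.shape != (grid.n_scans,):
            raise ValueError(
                f"regressor {name!r} has length {values.shape}, expected ({grid.n_scans},)"
            )
        if name in columns:
            raise ValueError(f"duplicate design column name {name!r}")
        columns[name] = values
    if len(set(task_regressors) & set(nuisance)) > 0:
        raise ValueError("task and nuisance column names overlap")
    if intercept:
        if "intercept" in columns:
            raise ValueError("duplicate design column name 'intercept'")
        columns["intercept"] = np.ones(grid.n_scans)
    frame = pd.DataFrame(columns)
    return DesignMatrix(frame=frame, grid=grid, task_columns=list(task_regressors))


def read_events_tsv(path) -> EventTable:
    """Read a BIDS-style events TSV (onset, duration, trial_type, ...)."""
    frame = pd.read_csv(path, sep="\t", na_values=["n/a"])
    for col in MANDATORY_EVENT_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"events file {path} is missing mandatory column {col!r}")
    return EventTable(frame)


def write_events_tsv(table: EventTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, na_rep="n/a")
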
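"""Discrete state trajectories: I/O, transition counting, direct estimates.

A discrete trajectory is one integer state label per frame at a uniform
time step ``dt``.  This module reads/writes such trajectories, counts
transitions at a lag (sliding or strided windows, never across trajectory
boundaries), normalizes counts into column-stochastic transition-matrix
estimates, computes the directly counted time-dependent series ``T_MD(t)``,
and splits long trajectories into many short segments.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import StochasticMatrix, validate_stochastic
from .errors import (
    AllDisconnected,
    EmptyFile,
    InsufficientOrigins,
    LagTooLong,
    ParseError,
)

__all__ = [
    "DiscreteTrajectory",
    "TrajectorySet",
    "CountMatrix",
    "read_trajectories",
    "trajectory_set",
    "write_trajectory",
    "count_transitions",
    "estimate_transition_matrix",
    "transition_matrix_series",
    "split_trajectories",
]

#: Minimum number of sliding time origins for a usable T_MD(t) estimate.
DEFAULT_MIN_ORIGINS = 100


@dataclass(frozen=True)
class DiscreteTrajectory:
    """Integer state labels at uniform frame spacing ``dt``."""

    labels: np.ndarray
    dt: float = 1.0

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise ParseError("non-integer state labels")
            lab = lab.astype(np.int64)
        else:
            lab = lab.astype(np.int64)
        object.__setattr__(self, "labels", lab)
        if lab.ndim != 1 or lab.size < 2:
            raise EmptyFile("trajectory must contain at least 2 frames")
        if np.any(lab < 0):
            raise ParseError("negative state label")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class TrajectorySet:
    """Trajectories sharing ``dt`` and a dense 0..n-1 state alphabet.

    ``label_map`` retains the original -> dense index mapping when the
    set was built by :func:`read_trajectories` / :func:`trajectory_set`.
    """

    trajectories: tuple
    dt: float
    n_states: int
    label_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.trajectories) == 0:
            raise EmptyFile("empty trajectory set")
        for tr in self.trajectories:
            if tr.dt != self.dt:
                raise ValueError("inconsistent dt across trajectories")

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def total_frames(self) -> int:
        return sum(len(t) for t in self.trajectories)


def _parse_file(path, column: int | None) -> np.ndarray:
    opener = gzip.open if str(path).endswith(".gz") else open
    values = []
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split(",")[column] if column is not None else line
            try:
                values.append(int(token.strip()))
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer token {token!r}") from exc
    if not values:
        raise EmptyFile(f"{path}: no frames")
    return np.asarray(values, dtype=np.int64)


def trajectory_set(label_arrays, dt: float = 1.0) -> TrajectorySet:
    """Build a :class:`TrajectorySet` from raw label arrays.

    Labels are re-indexed to a dense ``0..n-1`` alphabet; the original ->
    dense map is kept in :attr:`TrajectorySet.label_map`.
    """
    arrays = [np.asarray(a, dtype=np.int64) for a in label_arrays]
    alphabet = np.unique(np.concatenate(arrays))
    remap = {int(orig): i for i, orig in enumerate(alphabet)}
    dense = []
    for a in arrays:
        dense.append(DiscreteTrajectory(np.searchsorted(alphabet, a), dt=dt))
    return TrajectorySet(
        trajectories=tuple(dense), dt=dt, n_states=len(alphabet), label_map=remap
    )


def read_trajectories(paths, dt: float = 1.0, column: int | None = None) -> TrajectorySet:
    """Read plain-text trajectories (one integer per line, or a CSV column).

    ``.gz`` files are handled transparently.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    return trajectory_set([_parse_file(p, column) for p in paths], dt=dt)


def write_trajectory(traj: DiscreteTrajectory, path) -> None:
    np.savetxt(path, traj.labels, fmt="%d")


@dataclass(frozen=True)
class CountMatrix:
    """Transition counts at a lag; entry ``(i, j)`` = observed ``j -> i``."""

    counts: np.ndarray
    lag: float

    def __post_init__(self):
        c = np.asarray(self.counts)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("count matrix must be square")
        if np.any(c < 0):
            raise ValueError("negative transition count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _lag_frames(lag: float, dt: float) -> int:
    steps = lag / dt
    if abs(steps - round(steps)) > 1e-9 or round(steps) < 0:
        raise ValueError(f"lag {lag} is not a non-negative multiple of dt {dt}")
    return int(round(steps))


def count_transitions(
    trajs: TrajectorySet, lag: float, mode: str = "sliding"
) -> CountMatrix:
    """Count ``j -> i`` transitions at the given lag.

    ``sliding`` counts every frame pair ``(t, t + lag)``; ``strided``
    counts non-overlapping pairs only.  Counts never cross trajectory
    boundaries.
    """
    if mode not in ("sliding", "strided"):
        raise ValueError(f"unknown counting mode {mode!r}")
    steps = _lag_frames(lag, trajs.dt)
    if steps < 1:
        raise ValueError("lag must be a positive multiple of dt")
    n = trajs.n_states
    C = np.zeros((n, n), dtype=np.int64)
    for tr in trajs.trajectories:
        if len(tr) <= steps:
            raise LagTooLong(
                f"trajectory of {len(tr)} frames shorter than lag ({steps} frames)"
            )
        lab = tr.labels
        if mode == "sliding":
            src, dst = lab[:-steps], lab[steps:]
        else:
            src, dst = lab[:-steps:steps], lab[steps::steps]
        np.add.at(C, (dst, src), 1)
    return CountMatrix(C, lag=lag)


def largest_scc(C: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly connected component of the count graph."""
    graph = csr_matrix((C > 0).astype(np.int8))
    n_comp, assign = connected_components(graph, directed=True, connection="strong")
    sizes = np.bincount(assign, minlength=n_comp)
    return np.flatnonzero(assign == np.argmax(sizes))


def estimate_transition_matrix(
    C: CountMatrix, symmetrize: bool = False
) -> StochasticMatrix:
    """Column-normalize counts into a transition-matrix estimate.

    The counts are first restricted to the largest strongly connected
    component of the directed count graph (dropped states are reported via
    a warning and the resulting matrix labels).  With ``symmetrize=True``
    the counts are replaced by ``(C + C.T) / 2`` first, which enforces
    detailed balance of the estimate.
    """
    counts = C.counts.astype(float)
    keep = largest_scc(C.counts)
    if keep.size < 2:
        raise AllDisconnected("count graph has no connected component of size >= 2")
    if keep.size < counts.shape[0]:
        dropped = sorted(set(range(counts.shape[0])) - set(keep.tolist()))
        warnings.warn(
            f"dropping {len(dropped)} disconnected state(s): {dropped}", RuntimeWarning
        )
    counts = counts[np.ix_(keep, keep)]
    if symmetrize:
        counts = 0.5 * (counts + counts.T)
    colsums = counts.sum(axis=0)
    if np.any(colsums == 0):
        raise AllDisconnected("zero-count column inside connected component")
    return validate_stochastic(
        counts / colsums, lag=C.lag, labels=tuple(int(i) for i in keep), method="MD"
    )


def transition_matrix_series(
    trajs: TrajectorySet,
    lags,
    mode: str = "sliding",
    min_origins: int = DEFAULT_MIN_ORIGINS,
) -> list[StochasticMatrix]:
    """Directly counted ``T_MD(t)``, one independent estimate per lag.

    Lag 0 yields the identity.  Each positive lag must leave at least
    ``min_origins`` sliding time origins in total, so the time average
    behind each estimate is meaningful.
    """
    out = []
    n = trajs.n_states
    for lag in lags:
        steps = _lag_frames(lag, trajs.dt)
        if steps == 0:
            # T_MD(0) is the identity; the lag field (strictly positive by
            # contract) records the grid resolution instead
            out.append(StochasticMatrix(np.eye(n), lag=trajs.dt, method="MD"))
            continue
        origins = sum(max(len(t) - steps, 0) for t in trajs.trajectories)
        if origins < min_origins:
            raise InsufficientOrigins(
                f"lag {lag}: {origins} sliding origins < required {min_origins}"
            )
        C = count_transitions(trajs, lag, mode=mode)
        colsums = C.counts.sum(axis=0).astype(float)
        if np.any(colsums == 0):
            raise AllDisconnected(f"state never visited as origin at lag {lag}")
        out.append(
            validate_stochastic(C.counts / colsums, lag=lag, method="MD")
        )
    return out


def split_trajectories(trajs: TrajectorySet, segment_frames: int) -> TrajectorySet:
    """Chop every trajectory into consecutive ``segment_frames``-long pieces.

    Trailing remainders shorter than ``segment_frames`` are dropped; the
    number of dropped frames is reported via a warning.
    """
    if segment_frames < 2:
        raise ValueError("segment_frames must be >= 2")
    pieces, dropped = [], 0
    for tr in trajs.trajectories:
        n_seg = len(tr) // segment_frames
        dropped += len(tr) - n_seg * segment_frames
        for s in range(n_seg):
            pieces.append(
                DiscreteTrajectory(
                    tr.labels[s * segment_frames : (s + 1) * segment_frames],
                    dt=trajs.dt,
                )
            )
    if dropped:
        warnings.warn(f"dropped {dropped} trailing frame(s)", RuntimeWarning)
    if not pieces:
        raise EmptyFile("no segment as long as segment_frames")
    return TrajectorySet(
        trajectories=tuple(pieces),
        dt=trajs.dt,
        n_states=trajs.n_states,
        label_map=trajs.label_map,
    )
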
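"""Stochastic-matrix primitives for Markov-type state models.

The package works throughout in the *column-stochastic* convention: a
transition matrix ``T`` has entries ``T[i, j]`` = probability of the jump
``j -> i`` per lag time, every column sums to one, and populations evolve
as ``P(t) = T(t) @ P(0)``.  Row-stochastic matrices appear only at I/O
boundaries via an explicit transpose flag.

This module provides the typed containers (:class:`StochasticMatrix`,
:class:`PopulationVector`, :class:`TimescaleSpectrum`), validation,
stationary distributions, Chapman-Kolmogorov powers and implied
timescales, plus plain-text (CSV + JSON sidecar) serialization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import (
    Disconnected,
    DimensionMismatch,
    NegativeEntry,
    NotStochastic,
)

__all__ = [
    "StochasticMatrix",
    "PopulationVector",
    "TimescaleSpectrum",
    "validate_stochastic",
    "stationary_distribution",
    "propagate_power",
    "implied_timescales",
    "write_matrix",
    "read_matrix",
]

#: Default tolerance for column-sum and positivity checks.
STOCHASTIC_TOL = 1e-10


@dataclass(frozen=True)
class StochasticMatrix:
    """A column-stochastic transition matrix with lag-time metadata.

    Parameters
    ----------
    probs
        Square array; ``probs[i, j]`` is the probability of ``j -> i``
        within one lag time.
    lag
        Lag time in the same unit as the underlying trajectory step.
    labels
        Optional state identifiers (length ``n``).
    method
        Free-form tag describing how the matrix was estimated
        (``"LE"``, ``"HS"``, ``"Mic"``, ``"MD"``, ...).
    """

    probs: np.ndarray
    lag: float
    labels: tuple | None = None
    method: str | None = None

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
            raise DimensionMismatch(f"expected square matrix, got {probs.shape}")
        if not np.all(np.isfinite(probs)):
            raise NotStochastic("matrix contains non-finite entries")
        if self.lag <= 0:
            raise ValueError(f"lag must be positive, got {self.lag}")
        if self.labels is not None and len(self.labels) != probs.shape[0]:
            raise DimensionMismatch("labels length does not match matrix size")

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    def with_(self, **kw) -> "StochasticMatrix":
        """Return a copy with selected fields replaced."""
        d = dict(probs=self.probs, lag=self.lag, labels=self.labels, method=self.method)
        d.update(kw)
        return StochasticMatrix(**d)


@dataclass(frozen=True)
class PopulationVector:
    """Per-state probabilities at an elapsed time."""

    values: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise DimensionMismatch("population vector must be one-dimensional")
        if np.any(v < -STOCHASTIC_TOL):
            raise NegativeEntry("negative population entry")
        if abs(v.sum() - 1.0) > 1e-8:
            raise NotStochastic(f"populations sum to {v.sum()}, expected 1")


@dataclass(frozen=True)
class TimescaleSpectrum:
    """Implied timescales ``-lag / ln|lambda|``, sorted descending.

    The single stationary eigenvalue (1) is excluded.  Nonstationary
    eigenvalues of modulus >= 1 - 1e-12 yield infinite timescales and are
    flagged in :attr:`flagged`.
    """

    timescales: np.ndarray
    eigenvalues: np.ndarray
    lag: float = 1.0
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def slowest(self) -> float:
        return float(self.timescales[0])


def validate_stochastic(
    M,
    tol: float = STOCHASTIC_TOL,
    lag: float = 1.0,
    labels=None,
    row_stochastic: bool = False,
    method: str | None = None,
) -> StochasticMatrix:
    """Validate and type a transition matrix.

    Columns must sum to one within ``tol`` and entries must lie in
    ``[-tol, 1 + tol]``; entries are clipped to ``[0, 1]`` afterwards.
    With ``row_stochastic=True`` the input is transposed first.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DimensionMismatch(f"expected square matrix, got {M.shape}")
    if not np.all(np.isfinite(M)):
        raise NotStochastic("matrix contains non-finite entries")
    if row_stochastic:
        M = M.T
    colsums = M.sum(axis=0)
    bad = np.abs(colsums - 1.0) > tol
    if np.any(bad):
        j = int(np.argmax(np.abs(colsums - 1.0)))
        raise NotStochastic(
            f"column {j} sums to {colsums[j]:.12g} (tolerance {tol:g})"
        )
    if np.any(M < -tol):
        i, j = np.unravel_index(np.argmin(M), M.shape)
        raise NegativeEntry(f"entry ({i},{j}) = {M[i, j]:.3g} below -{tol:g}")
    if np.any(M > 1 + tol):
        raise NotStochastic("entry above 1 beyond tolerance")
    return StochasticMatrix(np.clip(M, 0.0, 1.0), lag=lag, labels=labels, method=method)


def _closed_classes(T: np.ndarray) -> int:
    """Number of closed (absorbing) strongly connected classes of T > 0."""
    n = T.shape[0]
    graph = csr_matrix((T > 0).astype(np.int8))
    n_comp, assign = connected_components(graph, directed=True, connection="strong")
    closed = 0
    for c in range(n_comp):
        members = np.flatnonzero(assign == c)
        outside = np.setdiff1d(np.arange(n), members, assume_unique=True)
        # class is closed iff no probability flows out of it
        if outside.size == 0 or T[np.ix_(outside, members)].sum() == 0:
            closed += 1
    return closed


def stationary_distribution(T: StochasticMatrix) -> PopulationVector:
    """Equilibrium populations: the eigenvector of eigenvalue 1.

    Raises :class:`Disconnected` if the chain has several closed
    communicating classes (stationary distribution not unique).
    """
    P = T.probs
    if _closed_classes(P) > 1:
        raise Disconnected("multiple closed communicating classes")
    w, v = np.linalg.eig(P)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = pi / pi.sum()
    # numerical cleanup: tiny negative components are clipped
    pi = np.where(np.abs(pi) < 1e-14, 0.0, pi)
    if np.any(pi < 0):
        raise Disconnected("stationary eigenvector has mixed signs")
    return PopulationVector(pi / pi.sum(), time=np.inf)


def propagate_power(T: StochasticMatrix, m: int) -> StochasticMatrix:
    """Chapman-Kolmogorov power ``T(m*tau) ~= T(tau)**m``."""
    if m < 1:
        raise ValueError(f"power must be >= 1, got {m}")
    return T.with_(probs=np.linalg.matrix_power(T.probs, m), lag=m * T.lag)


def implied_timescales(T: StochasticMatrix) -> TimescaleSpectrum:
    """Implied timescales ``-lag / ln|lambda|`` of all nonstationary eigenvalues.

    Eigenvalues are sorted by descending modulus (ties: descending real
    part).  The single eigenvalue closest to 1 is dropped as stationary.
    Remaining eigenvalues with ``|lambda| >= 1 - 1e-12`` give infinite
    timescales and are flagged (a disconnected model); ``|lambda| = 0``
    maps to timescale 0.  Complex pairs contribute through their modulus
    (a warning is emitted).
    """
    w = np.linalg.eigvals(T.probs)
    order = np.lexsort((-w.real, -np.abs(w)))
    w = w[order]
    stat = int(np.argmin(np.abs(w - 1.0)))
    rest = np.delete(w, stat)
    if np.any(np.abs(rest.imag) > 1e-12):
        warnings.warn(
            "complex eigenvalue pair encountered; using modulus", RuntimeWarning
        )
    mod = np.abs(rest)
    flagged = mod >= 1.0 - 1e-12
    if np.any(flagged):
        warnings.warn(
            "nonstationary eigenvalue of modulus ~1: infinite implied "
            "timescale (disconnected model?)",
            RuntimeWarning,
        )
    ts = np.empty(mod.shape)
    with np.errstate(divide="ignore"):
        zero = mod <= 1e-14  # numerically vanishing eigenvalue
        nz = ~zero & ~flagged
        ts[nz] = -T.lag / np.log(mod[nz])
        ts[zero] = 0.0
        ts[flagged] = np.inf
    return TimescaleSpectrum(timescales=ts, eigenvalues=rest, lag=T.lag, flagged=flagged)


# ---------------------------------------------------------------------------
# serialization: headerless full-precision CSV + JSON key-value sidecar


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_matrix(T: StochasticMatrix, path, row_stochastic: bool = False) -> None:
    """Write the matrix as headerless CSV plus a ``.meta.json`` sidecar."""
    M = T.probs.T if row_stochastic else T.probs
    np.savetxt(path, M, delimiter=",", fmt="%.17g")
    meta = {
        "lag": T.lag,
        "labels": list(T.labels) if T.labels is not None else None,
        "method": T.method,
        "row_stochastic": bool(row_stochastic),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_matrix(path, row_stochastic: bool | None = None) -> StochasticMatrix:
    """Read a matrix written by :func:`write_matrix`.

    If ``row_stochastic`` is None the sidecar's flag is used (default
    column-stochastic when no sidecar is present).
    """
    M = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = {}
    sp = _sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    if row_stochastic is None:
        row_stochastic = bool(meta.get("row_stochastic", False))
    labels = meta.get("labels")
    return validate_stochastic(
        M,
        lag=float(meta.get("lag", 1.0)),
        labels=tuple(labels) if labels else None,
        row_stochastic=row_stochastic,
        method=meta.get("method"),
    )
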
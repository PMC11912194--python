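"""Micro-to-macrostate aggregation and the three projection estimators.

Given a Markovian microstate transition matrix ``t`` (n states,
column-stochastic, stationary distribution ``pi``) and a partition of the
microstates into N macrostates, the aggregation machinery consists of

* the 0/1 aggregation matrix ``A`` (n x N), ``A[i, J] = 1`` iff microstate
  ``i`` belongs to macrostate ``J``;
* the diagonal matrices ``D_n = diag(pi)`` and ``D_N = diag(Pi)`` with
  ``Pi = A.T @ pi`` the macrostate equilibrium populations;
* the normalized aggregation ``A_hat = D_n A D_N^-1``, whose column ``J``
  is the equilibrium distribution *within* macrostate ``J``.

Macrostate populations project as ``P = A.T @ p``.  Three estimators of the
macrostate transition matrix follow:

* local equilibrium: ``T_LE(tau) = A.T t(tau) A_hat`` — one-step flux
  matching, assuming instant equilibration within each macrostate;
* microstate-based: ``T_Mic(m tau) = A.T t(tau)^m A_hat`` — propagate the
  microstates, project afterwards; exact macrostate populations by
  construction, but time-dependent;
* Hummer-Szabo: ``T_HS = 1 + Pi 1^T - [A.T (1 - t + pi 1^T)^-1 A_hat]^-1``
  — the Laplace-transform (long-time pole-matching) optimal projection; a
  constant matrix requiring n- and N-dimensional inversions.

All three preserve the macrostate equilibrium ``Pi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import PopulationVector, StochasticMatrix, stationary_distribution, validate_stochastic
from .errors import DimensionMismatch, EmptyMacrostate, NotStochastic, SingularMatrix

__all__ = [
    "Aggregation",
    "build_aggregation",
    "read_assignment",
    "project_populations",
    "lump_le",
    "lump_mic",
    "lump_hs",
]


@dataclass(frozen=True)
class Aggregation:
    """Micro -> macro assignment with all derived projection matrices."""

    assignment: np.ndarray  # length n, values in 0..N-1
    A: np.ndarray           # n x N, 0/1
    micro_pi: np.ndarray    # pi, length n
    macro_Pi: np.ndarray    # Pi = A.T pi, length N
    A_hat: np.ndarray       # D_n A D_N^-1, n x N

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def N(self) -> int:
        return self.A.shape[1]

    @property
    def Dn(self) -> np.ndarray:
        return np.diag(self.micro_pi)

    @property
    def DN(self) -> np.ndarray:
        return np.diag(self.macro_Pi)


def build_aggregation(
    t_micro: StochasticMatrix, assignment, micro_pi=None
) -> Aggregation:
    """Construct the aggregation machinery for a microstate matrix.

    ``assignment`` maps each microstate index to a macrostate index (array
    of length n, or a dict).  ``micro_pi`` defaults to the stationary
    distribution of ``t_micro`` (equilibrium sampling assumed); empirical
    frame-count weights may be supplied instead.
    """
    n = t_micro.n_states
    if isinstance(assignment, dict):
        if set(assignment) != set(range(n)):
            raise DimensionMismatch("assignment must cover microstates 0..n-1")
        assignment = [assignment[i] for i in range(n)]
    assignment = np.asarray(assignment, dtype=np.int64)
    if assignment.shape != (n,):
        raise DimensionMismatch(
            f"assignment length {assignment.size} != number of microstates {n}"
        )
    macros = np.unique(assignment)
    N = int(assignment.max()) + 1
    if not np.array_equal(macros, np.arange(N)):
        missing = sorted(set(range(N)) - set(macros.tolist()))
        raise EmptyMacrostate(f"macrostate(s) {missing} contain no microstates")
    if micro_pi is None:
        pi = stationary_distribution(t_micro).values
    else:
        pi = np.asarray(micro_pi, dtype=float)
        if pi.shape != (n,) or np.any(pi <= 0):
            raise DimensionMismatch("micro_pi must be length n and positive")
        pi = pi / pi.sum()
    A = np.zeros((n, N))
    A[np.arange(n), assignment] = 1.0
    Pi = A.T @ pi
    A_hat = (pi[:, None] * A) / Pi[None, :]
    return Aggregation(assignment=assignment, A=A, micro_pi=pi, macro_Pi=Pi, A_hat=A_hat)


def read_assignment(path) -> np.ndarray:
    """Read a two-column CSV ``microstate,macrostate`` into an assignment array."""
    table = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    order = np.argsort(table[:, 0])
    micro, macro = table[order, 0], table[order, 1]
    if not np.array_equal(micro, np.arange(micro.size)):
        raise DimensionMismatch("first column must enumerate microstates 0..n-1")
    return macro


def project_populations(agg: Aggregation, p: PopulationVector) -> PopulationVector:
    """Project microstate populations onto macrostates: ``P = A.T p``."""
    if p.values.size != agg.n:
        raise DimensionMismatch("population vector does not match microstate count")
    return PopulationVector(agg.A.T @ p.values, time=p.time)


def _check_agg(agg: Aggregation, t_micro: StochasticMatrix) -> None:
    if agg.n != t_micro.n_states:
        raise DimensionMismatch("aggregation does not match microstate matrix")


def lump_le(agg: Aggregation, t_micro: StochasticMatrix) -> StochasticMatrix:
    """Local-equilibrium macrostate matrix ``T_LE(tau) = A.T t(tau) A_hat``.

    Equivalent to one-step flux matching,
    ``T_IJ Pi_J = sum_{i in I, j in J} t_ij pi_j``.
    """
    _check_agg(agg, t_micro)
    M = agg.A.T @ t_micro.probs @ agg.A_hat
    return validate_stochastic(M, tol=1e-10, lag=t_micro.lag, method="LE")


def lump_mic(agg: Aggregation, t_micro: StochasticMatrix, m: int) -> StochasticMatrix:
    """Microstate-based macrostate matrix ``T_Mic(m tau) = A.T t^m A_hat``.

    Time-dependent: in general ``T_Mic(m tau) != T_Mic(tau)^m``.  Yields
    exact macrostate population dynamics for any start that is equilibrated
    within each macrostate (``p0 = A_hat P0``).
    """
    _check_agg(agg, t_micro)
    if m < 1:
        raise ValueError("power must be >= 1")
    M = agg.A.T @ np.linalg.matrix_power(t_micro.probs, m) @ agg.A_hat
    return validate_stochastic(M, tol=1e-10, lag=m * t_micro.lag, method="Mic")


def lump_hs(agg: Aggregation, t_micro: StochasticMatrix) -> StochasticMatrix:
    """Hummer-Szabo optimal long-time projection (constant matrix).

    ``T_HS = 1_N + Pi 1_N^T - G^-1`` with
    ``G = A.T (1_n - t + pi 1_n^T)^-1 A_hat``.  Analytically this is
    exactly column-stochastic with stationary distribution ``Pi``; the
    floating-point result is renormalized when the column-sum drift lies
    in (1e-12, 1e-8) and rejected beyond.
    """
    _check_agg(agg, t_micro)
    n, N = agg.n, agg.N
    pi, Pi = agg.micro_pi, agg.macro_Pi
    inner = np.eye(n) - t_micro.probs + np.outer(pi, np.ones(n))
    cond = np.linalg.cond(inner)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularMatrix(f"n-dimensional inversion ill-conditioned (cond={cond:.3g})")
    G = agg.A.T @ np.linalg.solve(inner, agg.A_hat)
    condG = np.linalg.cond(G)
    if not np.isfinite(condG) or condG > 1e12:
        raise SingularMatrix(f"N-dimensional inversion ill-conditioned (cond={condG:.3g})")
    M = np.eye(N) + np.outer(Pi, np.ones(N)) - np.linalg.inv(G)
    drift = np.max(np.abs(M.sum(axis=0) - 1.0))
    if drift > 1e-8:
        raise NotStochastic(f"Hummer-Szabo column-sum drift {drift:.3g} > 1e-8")
    if drift > 1e-12:
        warnings.warn(
            f"renormalizing Hummer-Szabo columns (drift {drift:.3g})", RuntimeWarning
        )
        M = M / M.sum(axis=0)
    return validate_stochastic(M, tol=1e-8, lag=t_micro.lag, method="HS")
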
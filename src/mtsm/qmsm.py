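"""Quasi-MSM: memory-kernel extraction and generalized-master-equation propagation.

The generalized master equation (GME) for the transition matrix reads

    dT/dt = Tdot(0) T(t) - int_0^tau_K K(t') T(t - t') dt'

where ``K(t)`` is the matrix-valued memory kernel and ``tau_K`` the time
after which it is treated as zero.  Discretized on the sampling grid
``t_n = n dt`` with the forward difference ``Tdot(0) = (T(dt) - 1)/dt``
and a left-endpoint rectangle rule for the memory integral:

    T_{n+1} = T_n + dt Tdot(0) T_n - dt^2 sum_{m=0}^{min(n, n_K - 1)} K_m T_{n-m}

with ``tau_K = n_K dt``.  Kernel extraction inverts the same relation
iteratively on a short, directly counted series ``T_MD(n dt)`` (with the
untruncated sum), so the extract -> propagate round trip reproduces the
training window exactly.  A consequence of the chosen discretization is
that ``K_0 = 0`` identically: the ``Tdot(0) T(t)`` term cancels the kernel
at t = 0, and for exactly Markovian input the entire kernel vanishes and
the propagation reduces to Chapman-Kolmogorov powers.

When ``keep_Tdot0_term=False``, the ``Tdot(0) T(t)`` term is dropped from
extraction *and* propagation consistently (then ``K_0 = (1 - T_1)/dt^2``
carries the Markovian dynamics instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import StochasticMatrix
from .errors import (
    Blowup,
    NonInvertible,
    SeriesTooShort,
    ThresholdNeverMet,
    ZeroNormalizer,
)

__all__ = [
    "MemoryKernelSeries",
    "initial_derivative",
    "extract_kernel",
    "normalized_kernel",
    "select_kernel_time",
    "propagate_gme",
    "qmsm_propagate",
]


@dataclass(frozen=True)
class MemoryKernelSeries:
    """Discretized memory kernel ``K_n = K(n dt)`` plus ``Tdot(0)``."""

    kernels: np.ndarray      # (L, N, N)
    dt: float
    Tdot0: np.ndarray        # (N, N)
    keep_Tdot0_term: bool = True

    def __post_init__(self):
        k = np.asarray(self.kernels, dtype=float)
        object.__setattr__(self, "kernels", k)
        if k.ndim != 3 or k.shape[1] != k.shape[2] or k.shape[0] < 1:
            raise SeriesTooShort("kernel series must be (L >= 1, N, N)")
        if not np.all(np.isfinite(k)):
            raise NonInvertible("non-finite kernel entries")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.kernels.shape[0]


def _as_array_series(T_series) -> np.ndarray:
    mats = [T.probs if isinstance(T, StochasticMatrix) else np.asarray(T, float)
            for T in T_series]
    return np.stack(mats)


def initial_derivative(T_series, dt: float) -> np.ndarray:
    """Forward-difference ``Tdot(0) = (T(dt) - 1) / dt``.

    The series must start with the identity at t = 0.  Columns of the
    result sum to zero (probability conservation).
    """
    Ts = _as_array_series(T_series)
    if Ts.shape[0] < 2:
        raise SeriesTooShort("need at least T(0) and T(dt)")
    N = Ts.shape[1]
    if not np.allclose(Ts[0], np.eye(N), atol=1e-10):
        raise ValueError("series must start with T(0) = identity")
    return (Ts[1] - np.eye(N)) / dt


def extract_kernel(
    T_series, dt: float, keep_Tdot0_term: bool = True
) -> MemoryKernelSeries:
    """Iteratively solve the discretized GME for the memory kernel.

    Given ``T_MD(n dt)`` for n = 0..n_max, returns ``K_n`` for
    n = 0..n_max-1 satisfying

        K_n T_0 = (T_n - T_{n+1})/dt^2 [+ Tdot(0) T_n / dt]
                  - sum_{m=0}^{n-1} K_m T_{n-m}

    (bracketed term present iff ``keep_Tdot0_term``).  ``T_0`` is the
    identity for a proper series, but the solve is kept general and raises
    :class:`NonInvertible` if it is singular.
    """
    Ts = _as_array_series(T_series)
    if Ts.shape[0] < 2:
        raise SeriesTooShort("need at least 2 matrices to extract a kernel")
    N = Ts.shape[1]
    Td0 = initial_derivative(Ts, dt)
    T0 = Ts[0]
    try:
        T0_inv = np.linalg.inv(T0)
    except np.linalg.LinAlgError as exc:
        raise NonInvertible("T(0) is singular") from exc
    K = np.zeros((Ts.shape[0] - 1, N, N))
    for n in range(Ts.shape[0] - 1):
        rhs = (Ts[n] - Ts[n + 1]) / dt**2
        if keep_Tdot0_term:
            rhs = rhs + (Td0 @ Ts[n]) / dt
        for m in range(n):
            rhs = rhs - K[m] @ Ts[n - m]
        K[n] = rhs @ T0_inv
    return MemoryKernelSeries(K, dt=dt, Tdot0=Td0, keep_Tdot0_term=keep_Tdot0_term)


def normalized_kernel(K: MemoryKernelSeries, element=(0, 0)) -> np.ndarray:
    """Element series ``K_IJ(n dt) / K_IJ(dt)`` — value 1 at n = 1."""
    I, J = element
    ref = K.kernels[1, I, J] if len(K) > 1 else 0.0
    if ref == 0.0:
        raise ZeroNormalizer(f"K_{I}{J}(dt) = 0")
    return K.kernels[:, I, J] / ref


def _max_normalized(K: MemoryKernelSeries) -> np.ndarray:
    """Per-step max-over-elements |K_n| normalized by the same norm of K_1."""
    norms = np.max(np.abs(K.kernels), axis=(1, 2))
    ref = norms[1] if len(K) > 1 else 0.0
    return norms, ref


def select_kernel_time(
    K: MemoryKernelSeries,
    threshold: float = 0.1,
    persistence: int = 3,
    zero_atol: float = 1e-12,
) -> float:
    """Kernel decay time: first ``n dt`` where the normalized kernel stays <= threshold.

    The criterion uses the element-wise maximum of the normalized kernel
    and requires it to remain below ``threshold`` for ``persistence``
    consecutive recorded steps (or to the end of the series), tolerating
    residual fluctuations around zero.  A kernel that is zero throughout
    (below ``zero_atol``, e.g. exactly Markovian input) gives the earliest
    possible time ``dt``.
    """
    norms, ref = _max_normalized(K)
    if np.all(norms <= zero_atol):
        return K.dt
    if ref <= zero_atol:
        raise ZeroNormalizer("K(dt) ~ 0 but the kernel is not identically zero")
    rel = norms / ref
    L = len(rel)
    for n in range(1, L):
        window = rel[n : min(n + persistence, L)]
        if np.all(window <= threshold):
            return n * K.dt
    raise ThresholdNeverMet(
        f"normalized kernel never <= {threshold}; minimum reached: {rel[1:].min():.3g}"
    )


def propagate_gme(
    T_short,
    K: MemoryKernelSeries,
    tau_K: float,
    horizon: float,
    renorm_tol: float = 1e-6,
) -> list[StochasticMatrix]:
    """Propagate the GME to ``horizon`` using kernels with ``t < tau_K``.

    ``T_short`` must cover t = 0..tau_K on the kernel grid.  Returns the
    full series ``T(n dt)`` for n = 0..horizon/dt; entries up to ``tau_K``
    reproduce the input exactly (the extraction is the exact inverse of
    this recursion there).  Columns drifting from one by less than
    ``renorm_tol`` are renormalized with a warning; larger drift, or any
    entry outside [-0.1, 1.1], aborts with :class:`Blowup` (a symptom of a
    noise-amplified kernel).
    """
    dt = K.dt
    n_K = int(round(tau_K / dt))
    if abs(n_K * dt - tau_K) > 1e-9 * max(1.0, dt) or n_K < 1:
        raise ValueError(f"tau_K={tau_K} is not a positive multiple of dt={dt}")
    n_hor = int(round(horizon / dt))
    if n_hor * dt < tau_K:
        raise ValueError("horizon must exceed tau_K")
    Ts = _as_array_series(T_short)
    if Ts.shape[0] < 2:
        raise SeriesTooShort("T_short must cover at least t = 0 and t = dt")
    N = Ts.shape[1]
    n_seed = min(Ts.shape[0] - 1, n_K)
    P = [Ts[i].copy() for i in range(n_seed + 1)]
    Td0 = K.Tdot0
    warned = False
    for n in range(n_seed, n_hor):
        rhs = P[n].copy()
        if K.keep_Tdot0_term:
            rhs = rhs + dt * (Td0 @ P[n])
        mmax = min(n, n_K - 1, len(K) - 1)
        for m in range(mmax + 1):
            rhs = rhs - dt**2 * (K.kernels[m] @ P[n - m])
        if np.any(rhs < -0.1) or np.any(rhs > 1.1):
            raise Blowup(
                f"entry outside [-0.1, 1.1] at step {n + 1}; kernel too noisy"
            )
        drift = np.max(np.abs(rhs.sum(axis=0) - 1.0))
        if drift >= renorm_tol:
            raise Blowup(f"column-sum drift {drift:.3g} >= {renorm_tol} at step {n + 1}")
        if drift > 1e-12:
            if not warned:
                warnings.warn(
                    f"renormalizing propagated columns (drift {drift:.3g})",
                    RuntimeWarning,
                )
                warned = True
            rhs = rhs / rhs.sum(axis=0)
        P.append(rhs)
    return [
        StochasticMatrix(M, lag=max(i, 1) * dt, method="qMSM")
        for i, M in enumerate(P)
    ]


def qmsm_propagate(
    T_series,
    dt: float,
    horizon: float,
    threshold: float = 0.1,
    keep_Tdot0_term: bool = True,
) -> tuple[list[StochasticMatrix], float, MemoryKernelSeries]:
    """Full qMSM workflow: extract kernel, pick tau_K, propagate.

    Convenience wrapper returning the propagated series, the selected
    kernel decay time and the kernel itself.
    """
    K = extract_kernel(T_series, dt, keep_Tdot0_term=keep_Tdot0_term)
    tau_K = select_kernel_time(K, threshold=threshold)
    series = propagate_gme(T_series, K, tau_K, horizon)
    return series, tau_K, K
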
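"""Hybrid MD/MSM propagator: exact T_MD(t) at short times, MSM powers beyond.

For ``t <= t_max`` the directly counted, approximation-free ``T_MD(t)`` is
returned at full time resolution.  For ``t = m t_max + s`` with
``0 <= s < t_max`` the model composes ``T_MD(s) @ T_long^m`` — the
long-lag Markov blocks applied chronologically first, the short-time
remainder last — which keeps the populations continuous in ``s`` across
each seam.  ``T_long`` is any macrostate matrix at lag ``t_max`` (direct
count, local equilibrium, Hummer-Szabo or microstate-based).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StochasticMatrix
from .errors import LagMismatch, TimeNotOnGrid

__all__ = ["HybridModel", "build_hybrid", "hybrid_transition"]


@dataclass(frozen=True)
class HybridModel:
    """Short-time MD series plus a long-lag MSM matrix at ``t_max``."""

    T_MD_series: tuple      # StochasticMatrix for t = 0, dt, ..., t_max
    T_long: StochasticMatrix
    t_max: float
    dt: float
    #: If False, t = m*t_max + s composes T_long^m @ T_MD(s) instead
    #: (remainder applied first).  Both orders agree at multiples of t_max.
    remainder_last: bool = True


def build_hybrid(
    T_MD_series,
    t_max: float,
    dt: float,
    T_long: StochasticMatrix | None = None,
    remainder_last: bool = True,
) -> HybridModel:
    """Assemble a hybrid model from a T_MD series on the grid n*dt.

    ``T_MD_series`` must cover t = 0..t_max.  When ``T_long`` is omitted
    the direct count estimate at lag ``t_max`` (the last covered series
    entry) is used, which makes the model exactly continuous at the seam.
    """
    n_max = int(round(t_max / dt))
    if abs(n_max * dt - t_max) > 1e-9 * max(1.0, dt) or n_max < 1:
        raise TimeNotOnGrid(f"t_max={t_max} is not a positive multiple of dt={dt}")
    series = tuple(T_MD_series)
    if len(series) < n_max + 1:
        raise LagMismatch(
            f"series covers {len(series) - 1} steps, t_max needs {n_max}"
        )
    N = series[0].n_states
    if not np.allclose(series[0].probs, np.eye(N), atol=1e-10):
        raise LagMismatch("T_MD series must start with the identity at t = 0")
    if T_long is None:
        T_long = series[n_max]
    elif abs(T_long.lag - t_max) > 1e-9 * max(1.0, dt):
        raise LagMismatch(
            f"T_long lag {T_long.lag} does not equal t_max {t_max}"
        )
    if T_long.n_states != N:
        raise LagMismatch("T_long state space differs from the MD series")
    return HybridModel(
        T_MD_series=series[: n_max + 1],
        T_long=T_long,
        t_max=t_max,
        dt=dt,
        remainder_last=remainder_last,
    )


def hybrid_transition(model: HybridModel, t: float) -> StochasticMatrix:
    """Evaluate the hybrid propagator at time ``t`` (a multiple of dt)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    n = int(round(t / model.dt))
    if abs(n * model.dt - t) > 1e-9 * max(1.0, model.dt):
        raise TimeNotOnGrid(f"t={t} is not on the dt={model.dt} grid")
    n_max = int(round(model.t_max / model.dt))
    if n <= n_max:
        return model.T_MD_series[n]
    m, r = divmod(n, n_max)
    short = model.T_MD_series[r].probs
    long_part = np.linalg.matrix_power(model.T_long.probs, m)
    M = short @ long_part if model.remainder_last else long_part @ short
    return StochasticMatrix(M, lag=max(t, model.dt), method="hybrid")
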
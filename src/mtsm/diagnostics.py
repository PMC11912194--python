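"""Model assessment: Chapman-Kolmogorov tests, population decays, method sweeps.

The Chapman-Kolmogorov (CK) test compares the self-transition
probabilities ``T_II(t)`` predicted by a model (matrix powers, the
microstate projection, the GME propagation, ...) against the directly
counted reference from the state trajectory, over a time grid within the
countable range.  The estimator sweep reproduces the toy-model comparison
of all estimators as a function of the Markovianity parameter h/k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StochasticMatrix, implied_timescales
from .errors import GridTooLong, InsufficientOrigins
from .lumping import lump_hs, lump_le, lump_mic
from .qmsm import qmsm_propagate
from .synthetic import ToyParams, toy_macro_aggregation, toy_micro_matrix
from .trajio import TrajectorySet, transition_matrix_series

__all__ = [
    "CKReport",
    "ck_test",
    "population_decay",
    "estimator_sweep",
    "toy_macro_md_series",
]


@dataclass(frozen=True)
class CKReport:
    """Per-state CK curves (tidy table) and per-method deviation summary."""

    table: pd.DataFrame    # columns: method, state, t, value
    summary: pd.DataFrame  # columns: method, state, max_abs_dev, rms_dev

    def max_deviation(self, method: str) -> float:
        sel = self.summary[self.summary["method"] == method]
        return float(sel["max_abs_dev"].max())

    def text_summary(self) -> str:
        lines = ["CK test summary (deviation from direct-count reference):"]
        for _, row in self.summary.iterrows():
            lines.append(
                f"  {row['method']:>10s} state {int(row['state'])}: "
                f"max|dev| = {row['max_abs_dev']:.4g}, rms = {row['rms_dev']:.4g}"
            )
        return "\n".join(lines)


def _provider_matrix(provider, t: float) -> np.ndarray:
    out = provider(t)
    return out.probs if isinstance(out, StochasticMatrix) else np.asarray(out, float)


def ck_test(
    trajs: TrajectorySet,
    predictions: dict,
    grid,
    min_origins: int = 100,
    full_matrix: bool = False,
) -> CKReport:
    """Chapman-Kolmogorov test against the directly counted reference.

    ``predictions`` maps method names to providers, each a callable
    ``t -> StochasticMatrix`` on the shared state space.  The reference
    curve is the diagonal of ``T_MD(t)`` (full-matrix deviations behind
    the ``full_matrix`` flag).
    """
    grid = [float(t) for t in grid]
    max_len = min(len(tr) for tr in trajs.trajectories)
    if max(grid) / trajs.dt >= max_len:
        raise GridTooLong("grid exceeds the directly countable range")
    try:
        reference = transition_matrix_series(trajs, grid, min_origins=min_origins)
    except InsufficientOrigins:
        raise GridTooLong("too few sliding origins at the longest grid times")
    n = trajs.n_states
    rows, dev_acc = [], {name: [] for name in predictions}
    for t, ref in zip(grid, reference):
        for s in range(n):
            rows.append(("reference", s, t, ref.probs[s, s]))
        for name, provider in predictions.items():
            M = _provider_matrix(provider, t)
            dev = M - ref.probs if full_matrix else np.diag(M) - np.diag(ref.probs)
            dev_acc[name].append(np.atleast_1d(dev))
            for s in range(n):
                rows.append((name, s, t, M[s, s]))
    table = pd.DataFrame(rows, columns=["method", "state", "t", "value"])
    summary_rows = []
    for name, devs in dev_acc.items():
        D = np.stack(devs)  # (n_times, n) or (n_times, n, n)
        per_state = D.reshape(D.shape[0], n, -1) if full_matrix else D[..., None]
        for s in range(n):
            d = per_state[:, s, :].ravel()
            summary_rows.append((name, s, np.abs(d).max(), np.sqrt(np.mean(d**2))))
    summary = pd.DataFrame(
        summary_rows, columns=["method", "state", "max_abs_dev", "rms_dev"]
    )
    return CKReport(table=table, summary=summary)


def population_decay(provider, start_state: int, grid) -> np.ndarray:
    """Survival curve ``P(t) = [T(t) e_start]_start`` on the grid.

    ``provider`` is a callable ``t -> StochasticMatrix``; ``t = 0`` always
    yields 1.
    """
    out = np.empty(len(grid))
    for i, t in enumerate(grid):
        if t == 0:
            out[i] = 1.0
        else:
            out[i] = _provider_matrix(provider, float(t))[start_state, start_state]
    return out


def toy_macro_md_series(
    p: ToyParams, n_max: int
) -> tuple[list[StochasticMatrix], float]:
    """Exact macrostate T_MD(n tau0) series for the toy model.

    Because the microstates are Markovian by construction, the directly
    counted macrostate matrix equals the microstate projection
    ``A.T t^n A_hat`` in the limit of infinite sampling; this exact series
    stands in for noiseless MD data.
    """
    t = toy_micro_matrix(p)
    agg = toy_macro_aggregation(p)
    series = [StochasticMatrix(np.eye(2), lag=p.tau0, method="MD")]
    series += [lump_mic(agg, t, m).with_(method="MD") for m in range(1, n_max + 1)]
    return series, p.tau0


def _timescale_at(series: list[StochasticMatrix], dt: float, t_eval: float) -> float:
    n = int(round(t_eval / dt))
    T = series[n].with_(lag=n * dt)
    return implied_timescales(T).slowest


def estimator_sweep(
    params_grid,
    eval_time: float = 100.0,
    kernel_threshold: float = 0.1,
    series_length: int = 60,
    plateau_check: bool = True,
) -> pd.DataFrame:
    """Timescale ratios t_method / t_micro per toy parameter set.

    For each (h, k): the constant LE and HS ratios, plus the
    time-dependent microstate-based and qMSM ratios evaluated at
    ``eval_time`` (where both should have plateaued; a warning is emitted
    if the value at 2x eval_time differs by more than 1%).
    """
    rows = []
    for p in params_grid:
        t = toy_micro_matrix(p)
        agg = toy_macro_aggregation(p)
        t_micro = implied_timescales(t).slowest
        t_le = implied_timescales(lump_le(agg, t)).slowest
        t_hs = implied_timescales(lump_hs(agg, t)).slowest
        m_eval = int(round(eval_time / p.tau0))
        t_mic = implied_timescales(lump_mic(agg, t, m_eval)).slowest
        md_series, dt = toy_macro_md_series(p, series_length)
        q_series, tau_K, _ = qmsm_propagate(
            md_series, dt, horizon=2 * eval_time, threshold=kernel_threshold
        )
        t_q = _timescale_at(q_series, dt, eval_time)
        if plateau_check:
            t_mic2 = implied_timescales(lump_mic(agg, t, 2 * m_eval)).slowest
            t_q2 = _timescale_at(q_series, dt, 2 * eval_time)
            for name, a, b in (("Mic", t_mic, t_mic2), ("qMSM", t_q, t_q2)):
                if abs(b - a) > 0.01 * abs(a):
                    warnings.warn(
                        f"{name} timescale not plateaued at t={eval_time} "
                        f"(changes by {100 * abs(b - a) / abs(a):.2f}% at 2x)",
                        RuntimeWarning,
                    )
        rows.append(
            {
                "h": p.h,
                "k": p.k,
                "h_over_k": p.h / p.k,
                "t_micro": t_micro,
                "ratio_LE": t_le / t_micro,
                "ratio_HS": t_hs / t_micro,
                "ratio_Mic": t_mic / t_micro,
                "ratio_qMSM": t_q / t_micro,
                "tau_K": tau_K,
            }
        )
    return pd.DataFrame(rows)
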
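"""Analytic four-well toy model and a seeded Markov-chain sampler.

The toy model is a one-dimensional landscape with four microstates
(1, 2, 3, 4 in the physical numbering; 0-based indices internally) lumped
into two macrostates L = {1, 2} and R = {3, 4}.  Per time step tau0,
neighboring microstates within a macrostate exchange with probability
``k`` (intrastate) and the two central microstates exchange with
probability ``h`` (interstate):

    t = [[1-k,   k,     0,     0  ],
         [k,     1-h-k, h,     0  ],
         [0,     h,     1-h-k, k  ],
         [0,     0,     k,     1-k]]

The matrix is symmetric, so detailed balance holds with uniform
equilibrium populations pi_i = 1/4.  Its eigenvalues are

    lambda_0 = 1,  lambda_{1,3} = 1 - h - k +/- sqrt(h^2 + k^2),
    lambda_2 = 1 - 2k,

and the ratio h/k is the Markovianity parameter: h/k << 1 gives a clean
timescale separation (good lumping), h/k >~ 1 strongly non-Markovian
macrostate dynamics.  Closed forms for the slowest implied timescales of
the microstate model, the local-equilibrium lump and the Hummer-Szabo
projection are provided for cross-checking the numerical estimators.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .core import StochasticMatrix
from .errors import DimensionMismatch, InvalidParams
from .lumping import Aggregation, build_aggregation
from .trajio import DiscreteTrajectory

__all__ = [
    "ToyParams",
    "toy_micro_matrix",
    "toy_macro_aggregation",
    "toy_analytic_timescales",
    "toy_eigenvalues",
    "sample_chain",
    "macro_waiting_times",
    "DwellRecord",
]


@dataclass(frozen=True)
class ToyParams:
    """Toy-model parameters: interstate ``h``, intrastate ``k``, unit time tau0.

    The constraint ``h + k <= 1`` keeps every matrix entry in [0, 1]: the
    central diagonal entries are ``1 - h - k``, the outer ones ``1 - k``.
    """

    h: float
    k: float
    tau0: float = 1.0

    def __post_init__(self):
        if not (self.h > 0 and self.k > 0 and self.h + self.k <= 1.0):
            raise InvalidParams(
                f"require h > 0, k > 0, h + k <= 1; got h={self.h}, k={self.k}"
            )
        if self.tau0 <= 0:
            raise InvalidParams("tau0 must be positive")

    @property
    def markovianity(self) -> float:
        """The ratio h/k; >~ 1 means non-Markovian macrostate dynamics."""
        return self.h / self.k


def toy_micro_matrix(p: ToyParams) -> StochasticMatrix:
    """The 4x4 symmetric tridiagonal microstate transition matrix."""
    h, k = p.h, p.k
    M = np.array(
        [
            [1 - k, k, 0, 0],
            [k, 1 - h - k, h, 0],
            [0, h, 1 - h - k, k],
            [0, 0, k, 1 - k],
        ]
    )
    return StochasticMatrix(M, lag=p.tau0, labels=(1, 2, 3, 4), method="toy")


def toy_macro_aggregation(p: ToyParams) -> Aggregation:
    """Lump microstates {1, 2} into L (index 0) and {3, 4} into R (index 1)."""
    return build_aggregation(toy_micro_matrix(p), [0, 0, 1, 1])


def toy_eigenvalues(p: ToyParams) -> np.ndarray:
    """Closed-form eigenvalues, descending by modulus."""
    h, k = p.h, p.k
    root = np.sqrt(h**2 + k**2)
    lams = np.array([1.0, 1 - h - k + root, 1 - 2 * k, 1 - h - k - root])
    return lams[np.argsort([-abs(x) for x in lams], kind="stable")]


def toy_analytic_timescales(p: ToyParams) -> dict:
    """Closed-form implied timescales (units of tau0).

    * ``t_micro``: slowest microstate timescale,
      ``-tau0 / ln(1 - h - k + sqrt(h^2 + k^2))``;
    * ``t_LE``: local-equilibrium macrostate timescale,
      ``-tau0 / ln(1 - h)`` (independent of k);
    * ``t_HS``: Hummer-Szabo macrostate timescale,
      ``-tau0 / ln(1 - 2hk / (h + 2k))``.
    """
    h, k = p.h, p.k
    lam_micro = 1 - h - k + np.sqrt(h**2 + k**2)
    lam_le = 1 - h
    lam_hs = 1 - 2 * h * k / (h + 2 * k)
    return {
        "t_micro": -p.tau0 / np.log(lam_micro),
        "t_LE": -p.tau0 / np.log(lam_le),
        "t_HS": -p.tau0 / np.log(lam_hs),
    }


def sample_chain(
    T: StochasticMatrix,
    length: int,
    start="stationary",
    seed: int | None = None,
) -> DiscreteTrajectory:
    """Sample a seeded Markov chain from a column-stochastic matrix.

    ``start`` is a state index or ``"stationary"`` (draw the initial state
    from the stationary distribution).  Same seed, same trajectory.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    n = T.n_states
    # cumulative next-state distributions per current state (columns)
    cum = [T.probs[:, j].cumsum().tolist() for j in range(n)]
    if start == "stationary":
        from .core import stationary_distribution

        pi = stationary_distribution(T).values
        state = int(rng.choice(n, p=pi))
    else:
        state = int(start)
        if not 0 <= state < n:
            raise ValueError(f"start state {state} out of range")
    u = rng.random(length - 1)
    out = np.empty(length, dtype=np.int64)
    out[0] = state
    for i in range(length - 1):
        state = bisect_right(cum[state], u[i])
        if state >= n:  # cumsum rounding at the top end
            state = n - 1
        out[i + 1] = state
    return DiscreteTrajectory(out, dt=T.lag)


@dataclass(frozen=True)
class DwellRecord:
    """One maximal run in a macrostate: duration and boundary censoring."""

    state: int
    duration: float   # run length in time units (frames * dt)
    censored: bool    # touches the start or end of the trajectory


def macro_waiting_times(
    traj: DiscreteTrajectory, agg: Aggregation
) -> tuple[list[DwellRecord], np.ndarray]:
    """Project a microstate trajectory onto macrostates and collect dwells.

    Returns the list of maximal-run dwell records (first and last runs
    flagged censored) and the macro-to-macro visit sequence (one entry per
    run).  Mean dwell estimates should exclude censored records.
    """
    if traj.labels.max() >= agg.n:
        raise DimensionMismatch("trajectory labels exceed the microstate alphabet")
    macro = agg.assignment[traj.labels]
    change = np.flatnonzero(np.diff(macro)) + 1
    bounds = np.concatenate(([0], change, [macro.size]))
    records = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        records.append(
            DwellRecord(
                state=int(macro[b0]),
                duration=(b1 - b0) * traj.dt,
                censored=(b0 == 0) or (b1 == macro.size),
            )
        )
    sequence = macro[bounds[:-1]]
    return records, sequence
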
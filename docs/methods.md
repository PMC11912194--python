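# Methods

## Model setting and conventions

The package works on discrete state trajectories: one integer state label
per frame at uniform spacing `dt`, assumed to sample a stationary,
time-homogeneous, ergodic process at equilibrium.  All transition
matrices are **column-stochastic**: `T[i, j]` is the probability of the
jump `j → i` within the lag time, and populations evolve as
`P(t) = T(t) P(0)`.  Row-stochastic matrices appear only at I/O
boundaries via an explicit flag.  Implied timescales are
`t_i = −τ / ln|λ_i|` for the nonstationary eigenvalues of `T(τ)`, sorted
by descending modulus with ties broken by descending real part.  The
modulus makes negative and complex eigenvalues (possible for
non-reversible estimates) yield finite timescales; a complex pair
triggers a warning.  Nonstationary eigenvalues within 1e-12 of modulus
one are flagged as infinite (a symptom of a disconnected model), and
moduli below 1e-14 map to timescale zero.

The central assumption throughout is that Markovianity holds at the
*microstate* level at the chosen lag, i.e. the microstate matrix
`t(τ)` satisfies the Chapman–Kolmogorov relation `t(mτ) = t(τ)ᵐ`.
Macrostates, which group many microstates, generally do not.

## Aggregation machinery

For a partition of n microstates into N macrostates, `A` (n×N, 0/1) is
the aggregation matrix, `π` the microstate and `Π = Aᵀπ` the macrostate
equilibrium populations, `D_n = diag(π)`, `D_N = diag(Π)`, and
`Â = D_n A D_N⁻¹` the normalized aggregation whose column J is the
equilibrium distribution *within* macrostate J.  Populations project as
`P = Aᵀ p`.  `π` defaults to the stationary distribution of the supplied
microstate matrix (self-consistent with the equilibrium-sampling
assumption); empirical frame-count weights may be passed instead.

The operator ordering `Aᵀ t Â` is pinned by the flux-matching identity
`T_IJ Π_J = Σ_{i∈I, j∈J} t_ij π_j`, which is asserted as a test
invariant.  All three projection estimators preserve `Π` exactly
(analytically; within 1e-10 numerically).

## The three projection estimators

* **Local equilibrium**: `T_LE(τ) = Aᵀ t(τ) Â`.  Equivalent to counting
  macrostate transitions at lag τ on equilibrium data.  Constant matrix;
  correct only when intrastate relaxation is much faster than τ.
* **Microstate-based**: `T_Mic(mτ) = Aᵀ t(τ)ᵐ Â`.  Propagate first,
  project afterwards.  For any initial condition that is equilibrated
  within each macrostate (`p₀ = Â P₀`) the macrostate populations are
  exact for all times.  The price: `T_Mic(mτ) ≠ T_Mic(τ)ᵐ`, so the
  matrix is time-dependent and its implied timescale converges to the
  microstate reference only as `t → ∞`.
* **Hummer–Szabo**: `T_HS = 1_N + Π 1ᵀ − G⁻¹` with
  `G = Aᵀ (1_n − t + π 1ᵀ)⁻¹ Â`.  Derived by matching the regular part
  of the resolvent (z-transform) of the projected dynamics at the
  stationary pole, i.e. a long-time optimal constant matrix.  It is
  analytically column-stochastic and fixes `Π`; with the identity
  aggregation it returns `t` exactly.  Numerically the column sums can
  drift through the two inversions: drift in (1e-12, 1e-8] is
  renormalized with a warning, larger drift is an error, and
  ill-conditioned inversions (condition number > 1e12) raise with the
  condition number reported.

For the four-well toy model (below) the HS matrix has the closed form
off-diagonal `hk/(h + 2k)`, which the numerical resolvent evaluation
reproduces to 1e-12 over a parameter grid.

## quasi-MSM memory-kernel scheme

The generalized master equation for the transition matrix,

    Ṫ(t) = Ṫ(0) T(t) − ∫₀^{τ_K} K(t′) T(t − t′) dt′,

is discretized on the sampling grid `t_n = n Δt` with the forward
difference `Ṫ(0) = (T(Δt) − 1)/Δt` (exact at t = 0 where `T(0) = 1`) and
a left-endpoint rectangle rule for the memory integral:

    T_{n+1} = T_n + Δt Ṫ(0) T_n − Δt² Σ_{m=0}^{min(n, n_K−1)} K_m T_{n−m}.

Extraction inverts this relation iteratively on a short, directly
counted series `T_MD(nΔt)` (with the untruncated sum), so:

* `K_0 = 0` identically — the `Ṫ(0)T(t)` term cancels the kernel at
  t = 0 in this discretization; when the term is dropped
  (`keep_Tdot0_term=False`, applied consistently in extraction and
  propagation), `K_0 = (1 − T_1)/Δt²` instead carries the Markovian
  dynamics.  On the toy model the two variants differ by well under 1 %.
* For exactly Markovian input the kernel vanishes and the propagation
  reduces to Chapman–Kolmogorov powers.
* The extract → propagate round trip reproduces the training window
  exactly, and re-extracting from the propagated series is idempotent.

The kernel decay time `τ_K` is the first `nΔt` at which the
element-wise-maximum normalized kernel (`max_IJ |K_n| / max_IJ |K_1|`)
drops to ≤ 0.1 and stays there for a persistence window of 3 recorded
steps — the persistence tolerates residual fluctuations around zero in
noisy kernels.  A kernel that is zero throughout (below 1e-12) selects
the earliest time `Δt`.  Per-element normalized series
(`K_IJ(nΔt)/K_IJ(Δt)`, value 1 at n = 1) are available for inspection.
Propagation uses only kernels with `t < τ_K` (the left-endpoint
discretization of the integral `∫₀^{τ_K}`); this convention reproduces
the toy-model benchmark at h/k = 1.  Kernel extraction from
under-sampled data amplifies noise; propagation therefore aborts
(`Blowup`) when any entry leaves [−0.1, 1.1] or a column sum drifts by
≥ 1e-6, rather than silently renormalizing.  Smaller drift is
renormalized with a warning.  The kernel grid equals the `T_MD` sampling
step; no interpolation is attempted.

## Hybrid MD/MSM propagator

For `t ≤ t_max` the hybrid model returns the stored, directly counted
`T_MD(t)` bit-identically.  For `t = m·t_max + s` (`0 ≤ s < t_max`) it
returns `T_MD(s) · T_longᵐ` — long-lag Markov blocks applied
chronologically first, the short-time remainder last, which keeps `P(t)`
continuous in `s` across each seam; the opposite order is available via
a flag (`remainder_last=False`), and the two coincide whenever the
factors commute (e.g. the symmetric two-macrostate toy).  `T_long`
defaults to the count estimate at lag `t_max` (making the seam at
`t = t_max` exact) and may instead be an LE/HS power or `T_Mic(t_max)`.
Off-grid times are an error, not interpolated: the MD series defines the
time resolution.

A known limitation, visible in exact arithmetic on the toy model at
h/k = 5 with `t_max = 10`: composing `T_MD(s)` with `T_longᵐ` implicitly
re-equilibrates the system within macrostates at each seam, so the
population curve dips below the exact reference just after `t_max`
(max deviation ≈ 0.048 at t = 11, ≈ 0.018 at multiples of `t_max`,
decaying to zero by t ≈ 50).  The hybrid still tracks the exact
populations far closer than the plain short-lag MSM, which is the
comparison that matters in practice; the tests assert that ordering
rather than a hard closeness bound.

## The four-well toy model

`ToyParams(h, k, tau0)` defines the 4×4 symmetric tridiagonal microstate
matrix: microstates 1↔2 and 3↔4 couple with the intrastate probability
`k`, 2↔3 with the interstate probability `h`, diagonals fill columns to
one.  Validity requires `h, k > 0` and `h + k ≤ 1` (all entries in
[0, 1]).  Detailed balance holds with uniform `π = 1/4`.  Eigenvalues:
`1`, `1 − h − k ± √(h² + k²)`, `1 − 2k`.  Closed-form timescales
(units of τ₀, the unit time):

* `t_micro = −1/ln(1 − h − k + √(h² + k²))`,
* `t_LE    = −1/ln(1 − h)` (independent of k),
* `t_HS    = −1/ln(1 − 2hk/(h + 2k))`.

The ratio `h/k` is the Markovianity parameter: lumping {1,2} → L,
{3,4} → R is good for `h/k ≪ 1` and bad for `h/k ≳ 1`.  Because the
microstates are Markovian by construction, the exact macrostate
`T_MD(t)` series equals `Aᵀ tⁿ Â`; `toy_macro_md_series` uses this as a
noiseless stand-in for counted MD data when feeding the qMSM and hybrid
pipelines.  The default benchmark settings are a 60-step short-time
window for kernel extraction and evaluation of the time-dependent
estimators at t = 100, where they have plateaued (the sweep warns when
the value at 2× the evaluation time still moves by more than 1 %).

The chain sampler draws seeded Markov-chain realizations (explicit seed
argument everywhere, no global random state) for the estimator-
consistency, splitting and dwell-time tests.  What the synthetic data do
*not* emulate: clustering error in the state definitions, non-equilibrium
initial conditions, and the slow sampling noise of finite MD — so
passing tests demonstrate correctness of the estimators given states,
not robustness of a full MSM workflow.

## Counting and estimation choices

Sliding-window counting is the default (every frame pair `(t, t+τ)`;
matches the time-average character of the estimators); strided counting
is available for independence studies.  Counts never cross trajectory
boundaries.  Estimates are restricted to the largest strongly connected
component of the directed count graph — ergodicity is assumed, so
violations are data artifacts that are trimmed and reported.  Optional
count symmetrization `(C + Cᵀ)/2` enforces detailed balance; it is off
by default for time-dependent `T_MD(t)` series (it biases them) and
available for microstate MSM building.  Each `T_MD(t)` estimate requires
at least 100 sliding time origins by default, so the underlying time
average is meaningful.  Trajectory splitting drops and reports trailing
remainders.  Dwell times at trajectory boundaries are flagged censored
and excluded from means.

## Numerical parameters at a glance

| parameter | default | meaning |
|---|---|---|
| column-sum tolerance | 1e-10 | stochasticity validation |
| HS renormalization band | (1e-12, 1e-8] | drift renormalized / rejected |
| kernel threshold | 0.1 | normalized-kernel level defining τ_K |
| persistence window | 3 steps | threshold must hold this long |
| GME drift guard | 1e-6 | propagation aborts beyond |
| min sliding origins | 100 | per `T_MD(t)` estimate |
| condition-number guard | 1e12 | HS inversions |

## Known limitations

* No reversible maximum-likelihood estimation beyond count
  symmetrization; no automatic lumping (PCCA+/MPP) or coring —
  assignments are inputs.
* The qMSM kernel is extracted from data only; no smoothing or
  regularization beyond the threshold-persistence rule.
* Implied timescales of heavily time-propagated matrices underflow once
  the subleading eigenvalue drops below ~1e-15 of the stationary one.
* Single-threaded deterministic numerics; no bootstrap error bars.
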
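# Methods

## Model family and assumptions

All models describe deterministic self-replicating systems with strong
inheritance: a strategy absent at the start (zero density, zero history)
can never appear.  The strategy space is `[0, 1]` by default, discretised
on a uniform grid with trapezoidal quadrature weights; finite strategy sets
are represented as atom grids with counting-measure weights.  Measurable
subsets are boolean node masks — the finite sigma-algebra of the
discretisation.  Set measures are therefore exactly additive over disjoint
masks, while the grid trace of a continuum interval is accurate only to one
grid cell at its endpoints; tests of interval measures use a one-spacing
tolerance for this reason.

Three dynamic families are implemented.

* **Cyclic replicator** (three strategies on the simplex).  The faces of
  the simplex are invariant and are pinned exactly in the integrator, so
  the model's initial-condition-dependent ranking structure (each face run
  selects a different strategy; the combined verdicts are cyclic) is
  reproduced without floating-point leakage resurrecting absent strategies.
  Substituting a zero first component into the replicator equations gives
  the reduced face system `d mu2/dt = mu2 mu3^2`, under which the losing
  strategy decays algebraically (like `1/t`); the face simulations use this
  faithful reduction, which still reaches the selected state to `1e-3` by
  `t = 2000`.
* **Nonlocal logistic competition**
  `d rho/dt = k rho − r rho C(rho, t)` with the coupling `C` a quadrature
  over the whole grid (`∫ k rho`, `∫ rho`, or `∫ eta^r` in the generalised
  density).  The coupling uses the *same* quadrature weights as set
  measures, so the continuum conservation identity of the
  `∫ k rho` coupling (total measure constant when started at unit mass)
  holds discretely up to solver error.
* **Stage and delay structured populations**, linear life-history dynamics
  damped by a shared scalar limitation `f(z, t)` scaled per strategy by
  `R(v) > 0`.  The presence characteristic is `eta = Z^(1/R)` with `Z` the
  stage/variable total, which turns the limitation into a strategy-
  independent additive term of the per-capita growth rate, making the
  analytic fitness `lambda_1/R` (stage) and `max Re(lambda_i)/R` (delay)
  ranking-preserving and independent of initial data.

## Finite-horizon operationalisation of the limits

The theory's objects are `t → ∞` limits, which a simulation can only
witness.  A directed ranking verdict requires the supremum density ratio
over the two neighbourhoods to fall below a tolerance (default `1e-4`)
*and* to be non-increasing across the last three dyadic checkpoints
(`T/8, T/4, T/2, T`); anything else is reported `incomparable` with a
convergence flag, never a number — the limit may genuinely not exist (e.g.
periodic succession).  The default neighbourhood radius is two grid
spacings; a radius below the local spacing degenerates to a single node and
warns, because single-node ratios lose the uniform-convergence safeguard
that distinguishes measure-level from pointwise comparisons.  Empirical
fitness estimates carry a drift diagnostic (difference of the two
half-window averages, flag threshold `1e-2`) instead of silently reporting
non-converged windows.  Argmax ties within `1e-6` are reported as a set
(polymorphic maximum).

## Numerical choices

* **Log-space integration.**  The nonlocal logistic family is integrated in
  log density for all strategies with positive initial density (DOP853,
  `rtol = atol = 1e-10` by default).  Ranking limits probe ratios across
  hundreds of decades; linear-space integration would silently floor losing
  strategies at the absolute tolerance.  Density fields carry the log
  values alongside the clipped linear values, and ranking/fitness
  diagnostics prefer them.
* **Boundary singularity.**  The closed-form auxiliary function
  `g(v,t) = exp(−t e^{−vt} + (1 − e^{−vt})/v)` is evaluated at `v = 0`
  through the series limit of `(1 − e^{−vt})/v → t` (giving exactly
  `g(0,t) = 1`), not an epsilon offset; the normalising integral uses a
  log-sum-exp shift so the density stays finite when `g` overflows.
* **Characteristic roots.**  Any root is an eigenvalue of `H(lambda)`, so
  the fixed point of the Gershgorin row bound (diagonal kept with sign)
  certifies an upper bound on real parts, and the infinity-norm row-sum
  bound at the search floor bounds imaginary parts.  The default floor is
  the upper bound minus 10.  Real roots are bracketed on the real axis
  first (the dominant root of nonnegative systems is real); complex roots
  are enumerated by winding-number counting on rectangles with recursive
  subdivision, and every candidate is polished by Newton iteration on the
  log-determinant (`step = −1/tr(M^{-1} M')`, Jacobi's formula).  A count
  mismatch raises rather than returning a silently wrong answer.  Reported
  residuals are determinant values normalised by
  `max(1, ||H − lambda E||_inf)^(n−1)`: for order-1 roots this is the raw
  determinant, while for far-imaginary roots it removes the `|lambda|^n`
  determinant growth that double precision cannot evaluate below ~`1e-10`.
  When the imaginary search window is capped the root set is flagged
  `truncated`.
* **Method of steps.**  Delay systems advance in macro-steps equal to the
  smallest delay, so delayed evaluations always fall in already-stored
  dense output (RK45 interpolants) or the supplied history.  The running
  limitation integral `Phi(t) = ∫_0^t f` is an auxiliary state; the delayed
  survival factor is `exp(−R (Phi(t) − Phi(t−tau)))` from stored values,
  never re-quadratured.  `Phi` is extended by zero before `t = 0`: the
  limitation history prior to the simulation start is taken as absent, a
  modelling choice recorded here because the delayed survival factor is
  otherwise underdetermined on the first interval.
* **Degenerate spectra.**  A complex or (nearly) repeated dominant
  eigenvalue is flagged and warned about — the `F → lambda_1` asymptotics
  assume a simple real dominant eigenvalue — and fitness falls back to the
  maximal real part.  Eigenvector normalisation to unit component sum is
  applied to the dominant vector (meaningful for Perron vectors of
  irreducible Metzler matrices); other eigenvectors use a maximum-modulus
  convention.

## The von Foerster reduction

A piecewise-constant age-structured population reduces to a delay system
for the stage totals `S_i`, with delays at the age thresholds and cohort
survival factors `exp(−Σ_k a_k (tau_k − tau_{k−1}))`.  The first stage's
inflow is produced at age zero, i.e. with no delay; that term lives in the
first row of the undelayed matrix `r` (alongside the diagonal mortalities
`−a_l`), since the delayed tensor has no zero-delay slot.  The entry is off
the growth feedback loop, so the characteristic roots — verified in the
tests against an independent Euler–Lotka integral oracle — are unchanged by
it, but omitting it would drive stage-1 densities negative.  The last stage
has no outflow term.

## Synthetic models

The generators draw life-history coefficients as low-order polynomials of
`v` with positive lower bounds (continuity in `v` is required by the
ranking theory), guarantee irreducibility of stage matrices via strictly
positive transitions plus last-stage reproduction, and certify delay-model
root caps through the Gershgorin bound rather than by root finding.
Two-strategy delay contests redraw until the analytic fitness gap is at
least 0.05 and the winner grows, so the nonlinear contest has a well-defined
survivor within the simulated horizon (200 time units: a gap of 0.05 drives
the loser/winner density ratio below `e^{−10} ≈ 5·10^{−5}`).

What the generators deliberately do not emulate: mutation (inheritance is
strong by assumption), stochasticity (demographic or environmental noise,
extinction thresholds), density-dependent life-history coefficients, and
non-scalar limitation factors.  Passing tests therefore show that the
ranking/fitness machinery is internally consistent on smooth deterministic
models of this class — not that it is robust to noise or to model
misspecification on empirical data.

## Problem sizes

Default study sizes were chosen as the smallest that resolve the phenomena
cleanly: 101 grid nodes (201 for the measure-conservation run, where the
closed-form comparison benefits from the finer grid), horizons 500 for
logistic selection equilibria, 2000 for the algebraically-converging
replicator face, 200 for exponentially separating two-strategy contests,
and 20 seeded fixtures for the stage growth-statistic contract.

## Known limitations

* Interval subsets are grid traces; boundary accuracy is `O(h)`.
* The winding-number enumeration assumes roots stay off the contour; the
  contour is jittered on failure, but pathological root clusters denser
  than `~1e-7` are merged.
* `simulate_dde` cost scales with `horizon / min(tau)`; very small delays
  with long horizons are slow (dense-output segments per macro-step).
* The empirical `J1` window statistic inherits the trajectory's transient:
  slowly converging competition (small fitness gaps, fine grids) needs
  longer horizons before the drift flag clears.
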
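# Methods

## Scales and conventions

All computations run on the standardized single-observation scale: outcomes
have unit variance, effects `θ` are means, and `Z_k ~ N(√k θ, 1)`. Sample
sizes are treated as continuous throughout derivation and evaluation;
rounding (ceiling) happens only when a concrete interim decision is issued
(`designs.decide`). Two-arm trials with equal allocation and a
mean-difference effect are mapped to this scale through the effective size
`n_eff = n_total / 4`; the scenario runner reports two-arm totals.

The critical value of a single-stage design is the `1 − α` normal quantile
(`α = 0.025` one-sided by default, target power 0.8). Expected power always
conditions on a positive effect, `EP = Pr[Z_n > c | Θ > 0]`; the expected
*sample size* of a two-stage design deliberately does not — design cost is
incurred whether or not the effect is positive — so the two functionals use
different measures, and `evaluate_oc` keeps them separate.

## Priors and posteriors

Truncated-normal priors are conjugate here: the posterior after `Z_m = z_m`
is truncated normal on the same support with precision `1/σ² + m` and
location `(μ/σ² + √m z_m)/(1/σ² + m)`. Conditioning on `Θ > 0` truncates
the support at 0 and renormalizes; point priors are invariant under both
operations (and conditioning a nonpositive point mass is an error). The
prior predictive of `Z_m` has the closed form
`N(z; √m μ, 1 + mσ²) × (posterior truncation mass / prior truncation mass)`,
cross-checked in the tests against direct `θ`-integration and a Monte-Carlo
histogram.

Integrals against a (truncated-normal) prior or posterior use 64-node
Gauss–Legendre quadrature on the effective support — the truncation
interval intersected with `μ ± 9σ`, so that very tight distributions stay
resolved — with weights proportional to the density and renormalized to sum
to one. The integrands (normal tails) are smooth, making the rule accurate
to well below 1e-10 at the scales used here.

## Default worked-example configuration

The package's reference configuration, used by the tests and
`scripts/acceptance.py`:

| quantity | value | why |
| --- | --- | --- |
| prior | `N(0.4, 0.2²)` on `[−0.5, 1]` | moderately informative planning prior; maximum-entropy on a compact interval given mean and spread |
| `α` | 0.025 one-sided | conventional confirmatory level |
| target EP | 0.80 | conventional power target |
| interim `m` | 26 (≈ n/3) | common heuristic interim fraction |
| naive rule | `β̃ = 0.2`, `n_min = 30`, `n_max = 160` | threshold matches the planning type II error; floor/cap keep recalculated sizes practical |
| ACP alternative `θ₁` | 0.4 | prior mean rounded to one decimal; supplied by the user, never derived automatically |

## Conditional power and its estimators

`conditional_power` evaluates the conditional-law tail directly and is
vectorized over all arguments; `m ≥ n` is rejected (the conditional law
degenerates; callers that need the `n → m` limit — an immediate final test
— evaluate at `n = m + 1e-6`, which is what `evaluate_oc` does when a
spline's stage-two size touches zero). ACP/OCP are plug-ins; PP integrates
CP against the positively conditioned posterior. `predictive_power_curve`
is the vectorized form used in hot loops: fixed Gauss–Legendre nodes on the
positive support with `z_m`-dependent posterior weights.

Estimator risk (bias/MAE/MSE as functions of the true `θ`) integrates the
estimator's error over the *unconditional* sampling law
`Z_m ~ N(√m θ, 1)` with 50-node Gauss–Hermite quadrature. The estimators
differ in how they condition on `Θ`; the risk measure itself does not
condition, which is what makes OCP's left-skew and its characteristic
U-shaped variance visible in the comparison. The default `θ` grid for such
comparisons is `[−0.3, 0.8]`, covering the prior's region of interest.

## Operating characteristics of two-stage designs

`TwoStageDesign` stores stage-two size and critical-value values on pivots
inside the continuation region, interpolated with cubic splines (the
smooth parameterization used for optimal designs) or linearly (used for the
pointwise-induced naive design, 400 grid points). Spline undershoot in `n2`
is clipped at zero. An infinite efficacy boundary encodes "no early
rejection"; beyond the last pivot the stage-two functions continue as
constants.

`evaluate_oc` integrates over the continuation region with 600-node
Gauss–Legendre (truncated at |z| = 12 when a boundary is infinite; the
neglected mass is ~1e-12 at these interim sizes), adds the early-stopping
masses in closed form, and mixes over the prior with the 64-node `θ` rule.
Binding boundaries: efficacy mass counts fully toward rejection, futility
mass never rejects. `simulate_oc` is the independent oracle — it draws
`θ` from the prior, simulates interim and stage-two statistics on the
sufficient-statistic scale, and applies the design — and the test suite
requires 3-standard-error agreement at 1e6 replications.

## Naive recalculation and the induced design

For an interim `z_m` of a single-stage design `(n, c)`, the rule seeks the
smallest `n' ∈ [n_min, n_max]` whose predictive power reaches
`1 − β̃(z_m)`, subject to the conditional error principle. The
conditional-error constraint is treated as binding, which pins
`c'(n') = √(m/n') z_m + √(1−m/n') Φ⁻¹(1−CE)`; substituting it into CP gives
`CP = Φ(θ √(n'−m) − Φ⁻¹(1−CE))`, so PP is strictly increasing in `n'` and
Brent root-finding suffices. If even `n_max` misses the threshold the trial
stops for futility; applied mandatorily, these futility outcomes define an
implicit binding futility boundary (located by root-finding on the cap's
power deficit, feasibility being monotone in `z_m`). The rule never stops
early for efficacy — for large `z_m` the floor `n_min > m` binds instead.

## Optimal design solver

Decision variables: interim size `m`, boundaries `z_fut < z_eff`, and the
stage-two pivot values (7 Gauss–Legendre pivots rescaled to the
continuation region; constants for group-sequential designs) — 17 variables
in the free problem. Objective and constraints integrate the *interpolated*
functions on a 5×-finer Gauss–Legendre grid. This decoupling matters: with
integration nodes coinciding with the pivots, the optimizer exploits the
gaps between nodes (a first pivot driven to zero stage-two size acts as an
invisible extra futility region), producing designs whose dense-grid type I
error exceeds `α`. Solver: SLSQP with bounds, multi-start (seeded jitter
around a warm start, which itself always remains a candidate), constraint
tolerance 2e-4 for feasibility filtering; `m` is optimized continuously,
rounded, and the remaining variables re-polished with `m` fixed. Both
constraints are active at the optimum (slack < 1e-4), as expected — an
optimal design exhausts its type I budget.

### Known discrepancy

For the reference configuration this solver converges robustly (across
orders 5–11, quadrature schemes, warm starts and seeds) to
`E[n] = 54.9`, `SD[n] = 26.9`, `max n = 105.3`, with feasibility confirmed
by 4e6-replication simulation (type I 0.02505 ± 0.00008, EP
0.7999 ± 0.0002). Published values for this configuration obtained with a
derivative-free (COBYLA-type) solver are `56.4 / 28.5 / 110.3` — dominated
by the optimum found here, and not reachable as a converged optimum under
any problem variant we examined; replicating COBYLA from heuristic starting
designs terminates in the `55.6–56.5` range with strongly start-dependent
sample-size spread, consistent with an under-converged iterate. The
qualitative structure agrees in full: constraints binding, sample-size mode
close to the futility boundary (non-convex, unlike the always-convex
threshold-rule curve), predictive power monotonically increasing along the
design and dipping to ≈0.40 at the futility boundary.

## Consistent recalculation

Both rules solve the matched system: conditional error equal to the
original design's, predictive power (under the revised prior `ψ`) equal to
a target. `solve_matched` reuses the pinned-`c'` reduction, so each solve
is a scalar monotone root-find.

* **not-worse**: target = original design's PP under the *old* prior. The
  original `(n(z_m), c(z_m))` is a root when `ψ = φ`, giving exact
  consistency. The rule does not preserve unconditional expected power
  under `ψ ≠ φ` (the matched thresholds integrate to the old design's EP
  under the wrong measure).
* **reoptimize**: step 1 re-solves the optimal design problem under `ψ`
  with the interim fixed at the observed look and the original conditional
  error imposed as a pointwise cap on the integration grid. Because early
  rejection carries conditional error 1, the cap also forbids lowering the
  efficacy boundary; this is enforced as a bound (`z_eff″ ≥ z_eff`), not
  just at grid points. Step 2 matches the reoptimized design's PP at the
  observed `z_m`, releasing conditional-error slack; if the matched system
  is infeasible or the reoptimized design stops early there, the step-1
  values are returned. Warm start: the original design with stage-two
  sizes rescaled by the squared effect-size ratio; a cold multi-start is
  the fallback. For data-independent `ψ` the procedure's unconditional
  expected power equals the 0.8 target up to the (tiny) mass where the
  original design rejects early but the reoptimized design would have
  continued; the scenario tests verify ±0.005.

Off-schedule looks (`m' < m`): the original design's conditional rejection
probability given `Z_{m'}` is computed by integrating the planned interim
statistic over its conditional normal law; conditional error and PP targets
follow, and the matched solve is unchanged.

`run_scenario` applies a rule on a 41-point grid over the continuation
region of a (two-arm, effective-scale) base design, clips recalculated
totals to a configured range (default 120–400, re-pinning `c'` to the
conditional error after clipping), and evaluates the procedure's
unconditional power and expected total sample size at a stated true effect
by 400-node quadrature. For the response-adaptive policy the revised point
alternative `(θ̂_m + θ₁)/2` varies with `z_m`, so the reoptimize rule
re-solves step 1 per grid point (cheap for group-sequential designs).

## Synthetic-data / oracle layer

There is no external data; inputs are design parameters and interim states.
The Monte-Carlo oracles (`simulate_oc`, the stage-two increment simulators
in the tests) emulate exactly the model the analytic formulas assume —
normal increments with known unit variance, exact interim timing. They
validate the quadrature, not the model: passing tests say nothing about
robustness to non-normal outcomes, unknown variance, overrunning patients
at the interim, or estimation of nuisance parameters, all of which are out
of scope.

## Numerical choices and degenerate inputs

* Quadrature orders: 64 (θ), 600 (interim statistic in `evaluate_oc`),
  35 = 5×7 (optimizer grid), 50 (Gauss–Hermite risk integrals); chosen so
  that doubling any of them moves the reference quantities by ≪ the test
  tolerances (the induced-design grid-refinement test checks this for the
  coarsest object, the 400-point induced design: < 0.05 in E[n]).
* `β̃` may be a constant or a callable in `z_m`; values outside (0,1) are
  rejected.
* `n_min ≤ m` is rejected: stopping at the interim without accepting would
  carry conditional error 1.
* Brent tolerances: 1e-8 (naive n'), 1e-9 (matched n'), 1e-10 (futility
  boundary); SLSQP `ftol` 1e-8.
* Ties at boundaries are resolved conservatively: `z_m` exactly on the
  futility (efficacy) boundary accepts (rejects).

## Limitations

One interim analysis; known variance; binding boundaries only; no
inverse-normal/combination-test alternative to the conditional error
principle; no prior elicitation (priors are user input); η > 0 enters
design *evaluation* (`E[n] + η·SD[n]`) but not the optimizer's objective,
which minimizes expected sample size alone.
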
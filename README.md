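# twostage

Interim power monitoring, sample-size recalculation, and optimal two-stage
designs for confirmatory clinical trials with a normally distributed
endpoint.

`twostage` is aimed at trial statisticians and methodologists who need to

* monitor the probability that an ongoing trial will succeed, given interim
  data (conditional power and its estimators),
* recalculate a trial's sample size mid-course with strict type I error
  control (conditional error principle), and
* derive fully preplanned optimal two-stage and group-sequential designs
  that make post hoc recalculation unnecessary unless the *external*
  planning assumptions change.

## Model

Outcomes `X_1, ..., X_n` are iid with mean `θ` (the standardized effect)
and unit variance; the test statistic after `k` observations is
`Z_k = Σ X_i / √k ~ N(√k θ, 1)`, and the one-sided test of `H0: θ ≤ 0`
rejects when `Z_n > c`. Given an interim look at `m < n` observations with
`Z_m = z_m`, the final statistic is conditionally normal,

    Z_n | Z_m = z_m  ~  N( √n θ + √τ (z_m − √m θ), 1 − τ ),   τ = m/n,

so the **conditional power** `CP(m, n, z_m, c, θ) = Pr_θ[Z_n > c | z_m]` is
an explicit normal tail probability. Because `θ` is unknown, CP must be
estimated:

* **ACP** — plug in the planning alternative `θ₁`;
* **OCP** — plug in the interim estimate `θ̂_m = z_m/√m`;
* **PP** — average CP over the posterior of `θ` given `z_m`, conditional on
  a positive effect (`Θ > 0`).

Planning uncertainty is encoded in a prior `φ` for `θ` (truncated normal or
point mass). **Expected power** `EP(n, c) = Pr_φ[Z_n > c | Θ > 0]`
generalizes classical power and drives the single-stage sample size.

A **two-stage design** maps the interim statistic to an early decision
(accept below a futility boundary, reject above an efficacy boundary) or to
a stage-two sample size `n(z_m)` and critical value `c(z_m)`. The package

* evaluates unconditional operating characteristics (`E[n(Z_m)]`,
  `SD[n(Z_m)]`, maximal `n`, expected power, maximal type I error rate) by
  quadrature, with a Monte-Carlo simulator as cross-check;
* constructs the design *induced* by a mandatory naive recalculation rule
  (smallest `n'` with `PP ≥ 1 − β̃`, conditional error pinned to the
  original design's);
* solves the optimal design problem
  `min E_φ[n(Z_m)]  s.t.  Pr_0[reject] ≤ α,  EP_φ ≥ 1 − β`
  over the interim size, both boundaries, and spline-parameterized
  `n(·), c(·)` (SLSQP with multi-start);
* implements two *consistent* unplanned recalculation rules for reacting to
  a revised prior `ψ` — **not-worse** (match the original design's
  conditional error and predictive power) and **reoptimize** (match the
  design that would have been optimal under `ψ`, releasing conditional
  error slack) — plus the inconsistent fixed-threshold rule `PP ≥ 0.8` for
  comparison.

## Worked example

The reference configuration used throughout the tests: prior
`θ ~ N(0.4, 0.2²)` truncated to `[−0.5, 1]`, one-sided `α = 0.025`, target
expected power 80%, interim at `m = 26`.

```sh
twostage reproduce --seed 1
```

prints (abridged):

```json
{
  "single_stage":   {"n": 79, "c": 1.959963984540054},
  "naive_induced":  {"expected_n": 48.33, "sd_n": 30.16,
                     "expected_power_pct": 67.15, "max_type1_pct": 1.78,
                     "eta_cutoff": 1.017},
  "optimal_two_stage": {"expected_n": 54.92, "sd_n": 26.90, "max_n": 105.29,
                        "expected_power": 0.80001, "max_type1": 0.024975},
  "consistent_recalc": {"reoptimize_power_theta_0.35": 0.79999,
                        "reoptimize_power_theta_0.45": 0.80002}
}
```

Reading: the single-stage design needs 79 participants. Mandatorily
recalculating at `m = 26` to 80% predictive power (floor 30, cap 160) cuts
the expected sample size to 48.3 at the price of a 30.2 standard deviation
— and silently degrades expected power to 67% and the maximal type I error
rate to 1.8%, because infeasible recalculations become binding futility
stops. Preferring it to the fixed design is justified only if a unit of
sample-size standard deviation costs less than `η ≈ 1.02` units of expected
sample size. Deriving the optimal two-stage design directly instead keeps
both constraints exactly binding (80.0% expected power, 2.5% type I) while
lowering the expected sample size to 54.9 with a maximal size of 105.3.
Finally, the two consistent recalculation rules leave an optimal design
untouched when the prior is unchanged, and the "reoptimize" rule holds the
80% unconditional power target exactly under data-independent revisions of
the point alternative (0.35 or 0.45).

The CLI subcommands `monitor`, `design single|optimal`, `evaluate`,
`recalc` and `scenario` expose the same functionality piecewise; designs
and priors are exchanged as JSON, scenario configurations as YAML.

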
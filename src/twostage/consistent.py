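"""Consistent unplanned sample-size recalculation rules.

When trial-external evidence revises the planning prior from phi to psi at
an (unplanned) interim look, a recalculation rule should leave an optimal
starting design untouched whenever psi = phi — otherwise the "rule" second-
guesses the design for every interim outcome.  Two consistent rules are
provided, both controlling type I error through the conditional error
principle (the new design's conditional type I error rate at the observed
interim must not exceed the original design's):

* "not-worse": the new (n', c') matches the original design's conditional
  error and its predictive power under the *old* prior, with predictive
  power now evaluated under the new prior.  Consistent, but the resulting
  procedure's unconditional expected power under psi drifts from the
  original target.
* "reoptimize": first re-derive the optimal design under psi with the
  conditional error cap imposed pointwise, then match its predictive power
  at the observed interim while releasing any conditional-error slack.
  For prior revisions made independently of the interim data this
  preserves the unconditional expected-power target.

A third, inconsistent rule ("pp_ge": recalculate to a fixed predictive
power threshold) is included for comparison in scenario evaluations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .designs import TwoStageDesign
from .monitoring import conditional_power, predictive_power_curve
from .naive import pinned_critical_value
from .priors import InterimState, Prior, posterior, theta_quadrature
from .optimal import OptimizationResult, optimize_design

logger = logging.getLogger(__name__)

__all__ = ["solve_matched", "recalc_not_worse", "recalc_reoptimize",
           "run_scenario", "InfeasibleError", "ScenarioResult"]


class InfeasibleError(RuntimeError):
    """No (n', c') satisfies the matched conditions within the sample-size cap."""

    def __init__(self, msg, pp_range=None):
        super().__init__(msg)
        self.pp_range = pp_range


def _pp_at_pinned(prior: Prior, m: int, z_m: float, ce: float, n_new) -> float:
    """Predictive power at (n', c'(n')) with c' pinned by the conditional error.

    With the conditional-error equality substituted in, the conditional
    power simplifies to ``Phi(theta sqrt(n' - m) - Phi^{-1}(1 - ce))``, so
    predictive power is a posterior average of that expression and is
    strictly increasing in n'.
    """
    q = ndtri(1.0 - ce)
    post = posterior(prior, InterimState(m, z_m), condition_positive=True)
    nodes, w = theta_quadrature(post)
    return float(np.sum(w * ndtr(nodes * np.sqrt(np.asarray(n_new) - m) - q)))


def solve_matched(
    m: int,
    z_m: float,
    ce_target: float,
    pp_target: float,
    new_prior: Prior,
    n_cap: float = 10_000.0,
) -> tuple[float, float]:
    """Solve the matched pair: conditional error = ce_target, PP = pp_target.

    The conditional-error equality pins c'(n'); predictive power under the
    new prior is then monotone in n', so the remaining equation has at most
    one root, found by bracketing and Brent's method.
    """
    if not 0.0 < ce_target < 1.0:
        raise ValueError("ce_target must lie in (0, 1)")
    if not 0.0 < pp_target < 1.0:
        raise ValueError("pp_target must lie in (0, 1)")

    def g(n_new: float) -> float:
        return _pp_at_pinned(new_prior, m, z_m, ce_target, n_new) - pp_target

    lo, hi = m + 1e-6, float(n_cap)
    g_lo, g_hi = g(lo), g(hi)
    if g_lo > 0 or g_hi < 0:
        raise InfeasibleError(
            f"no n' in ({m}, {n_cap}] reaches PP={pp_target:.4f}",
            pp_range=(g_lo + pp_target, g_hi + pp_target),
        )
    n_new = brentq(g, lo, hi, xtol=1e-9)
    c_new = float(pinned_critical_value(m, n_new, z_m, ce_target))
    return float(n_new), c_new


def _design_ce_pp(design: TwoStageDesign, prior: Prior, z_m: float) -> tuple[float, float, float, float]:
    """Original design's (n, c, conditional error, PP) at a continuation z_m."""
    if not design.z_futility < z_m < design.z_efficacy:
        raise ValueError("interim result outside the continuation region")
    n0 = float(design.n_of(z_m))
    c0 = float(design.c_of(z_m))
    ce = float(conditional_power(design.m, n0, z_m, c0, 0.0))
    pp = float(predictive_power_curve(prior, int(round(design.m)), np.array([z_m]), n0, c0)[0])
    return n0, c0, ce, pp


def recalc_not_worse(
    design: TwoStageDesign,
    interim: InterimState,
    old_prior: Prior,
    new_prior: Prior,
    n_cap: float = 10_000.0,
) -> tuple[float, float]:
    """"Not-worse" rule: at least the original design's predictive power.

    The threshold is the original design's PP under the old prior at the
    observed interim; the conditional error target is the original
    design's.  With ``new_prior == old_prior`` the original (n, c) solves
    the matched system, so the design is a fixed point of the rule.
    """
    if interim.m != round(design.m):
        return _recalc_not_worse_offschedule(design, interim, old_prior, new_prior, n_cap)
    _, _, ce, pp = _design_ce_pp(design, old_prior, interim.z_m)
    return solve_matched(interim.m, interim.z_m, ce, pp, new_prior, n_cap)


def design_conditional_rejection(
    design: TwoStageDesign, m_prime: int, z_prime: float, theta: float, n_z: int = 400
) -> float:
    """Rejection probability of the design given an earlier look Z_{m'} = z'.

    For ``m' < m`` the planned interim statistic is integrated over its
    conditional law given the early look before applying the design's
    decision rule; at ``m' = m`` this reduces to the design's own
    conditional rejection probability.
    """
    m = design.m
    if m_prime > m:
        raise ValueError("off-schedule look must not occur after the planned interim")
    if m_prime == m:
        if z_prime >= design.z_efficacy:
            return 1.0
        if z_prime <= design.z_futility:
            return 0.0
        return float(conditional_power(m, float(design.n_of(z_prime)), z_prime,
                                       float(design.c_of(z_prime)), theta))
    # conditional law of Z_m given Z_{m'} (same form as the final-stage law)
    rho = math.sqrt(m_prime / m)
    mu = math.sqrt(m) * theta + rho * (z_prime - math.sqrt(m_prime) * theta)
    sd = math.sqrt(1.0 - m_prime / m)
    lo = design.z_futility if np.isfinite(design.z_futility) else mu - 8 * sd
    hi = design.z_efficacy if np.isfinite(design.z_efficacy) else mu + 8 * sd
    x, w = np.polynomial.legendre.leggauss(n_z)
    z = lo + 0.5 * (hi - lo) * (x + 1.0)
    wz = 0.5 * (hi - lo) * w
    dens = np.exp(-0.5 * ((z - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
    nn = np.maximum(np.asarray(design.n_of(z), dtype=float), m + 1e-6)
    cp = conditional_power(m, nn, z, np.asarray(design.c_of(z)), theta)
    p_eff = ndtr((mu - design.z_efficacy) / sd) if np.isfinite(design.z_efficacy) else 0.0
    return float(p_eff + np.sum(wz * dens * cp))


def _recalc_not_worse_offschedule(design, interim, old_prior, new_prior, n_cap):
    ce = design_conditional_rejection(design, interim.m, interim.z_m, 0.0)
    post = posterior(old_prior, interim, condition_positive=True)
    nodes, w = theta_quadrature(post)
    pp = float(sum(
        wi * design_conditional_rejection(design, interim.m, interim.z_m, t)
        for t, wi in zip(nodes, w)
    ))
    return solve_matched(interim.m, interim.z_m, ce, pp, new_prior, n_cap)


def recalc_reoptimize(
    design: TwoStageDesign,
    interim: InterimState,
    old_prior: Prior,
    new_prior: Prior,
    alpha: float,
    target_ep: float,
    n_cap: float = 10_000.0,
    gsd: bool | None = None,
    return_step1: bool = False,
    _step1_cache: dict | None = None,
    **opt_kwargs,
):
    """"Reoptimize" rule: match the design that is optimal under the new prior.

    Step 1 re-solves the design problem under ``new_prior`` with the
    interim fixed at the observed look and the original design's
    conditional error imposed as a pointwise cap.  Step 2 releases any
    conditional-error slack by re-solving the matched system with the
    reoptimized design's predictive power as the target.  If the
    reoptimized design stops early at the observed interim, or the matched
    system is infeasible, the step-1 values are returned directly.
    """
    m = interim.m
    cap = lambda z: np.asarray(conditional_power(
        design.m, np.maximum(np.asarray(design.n_of(z), dtype=float), design.m + 1e-6),
        z, np.asarray(design.c_of(z)), 0.0))
    if gsd is None:
        gsd = len(set(np.round(design.n2, 9))) == 1
    if _step1_cache is not None and "res" in _step1_cache:
        res1 = _step1_cache["res"]
    else:
        # warm start from the original design, stage-two sizes rescaled by
        # the squared effect-size ratio (classical sample-size scaling)
        scale = (old_prior.mean() / max(new_prior.mean(), 1e-3)) ** 2
        common = dict(
            m_fixed=float(m),
            z_fut_fixed=design.z_futility if np.isfinite(design.z_futility) else None,
            gsd=gsd,
            ce_cap=cap,
            z_eff_min=float(design.z_efficacy) if np.isfinite(design.z_efficacy) else None,
        )
        try:
            res1 = optimize_design(
                new_prior, alpha, target_ep,
                x0=_warm_start_from(design, m, n2_scale=scale),
                n_starts=1, **common, **opt_kwargs,
            )
        except RuntimeError:
            res1 = optimize_design(new_prior, alpha, target_ep,
                                   n_starts=3, **common, **opt_kwargs)
        if _step1_cache is not None:
            _step1_cache["res"] = res1
    d1 = res1.design
    if return_step1:
        return res1
    z_m = interim.z_m
    if z_m >= d1.z_efficacy:  # reoptimized design already rejects here
        return float(d1.m), -np.inf
    if z_m <= d1.z_futility:
        return float(d1.m), np.inf
    n1 = float(d1.n_of(z_m))
    c1 = float(d1.c_of(z_m))
    pp1 = float(predictive_power_curve(new_prior, m, np.array([z_m]), n1, c1)[0])
    ce = float(cap(np.array([z_m]))[0])
    try:
        return solve_matched(m, z_m, ce, min(pp1, 1 - 1e-12), new_prior, n_cap)
    except InfeasibleError:
        return n1, c1


def _warm_start_from(design: TwoStageDesign, m: int, n2_scale: float = 1.0) -> np.ndarray:
    """Decision vector warm start from an existing design (m fixed, zf fixed)."""
    gsd = len(set(np.round(design.n2, 9))) == 1
    n2 = [design.n2[0]] if gsd else list(design.n2)
    c2 = [design.c2[0]] if gsd else list(design.c2)
    return np.array([design.z_efficacy] + [v * n2_scale for v in n2] + c2)


# ---------------------------------------------------------------------------
# scenario evaluation (two-arm group-sequential application)


@dataclass
class ScenarioResult:
    rule: str
    curves: pd.DataFrame  # per-z_m: n_total, c, achieved PP under the new prior
    expected_power: float  # unconditional, under the evaluation effect
    expected_n_total: float  # total two-arm sample size


def run_scenario(
    base_design: TwoStageDesign,
    rule: str,
    prior_update_policy: Callable[[float], Prior],
    eval_theta: float,
    old_prior: Prior,
    alpha: float = 0.025,
    target_ep: float = 0.8,
    n_total_range: tuple[float, float] = (120.0, 400.0),
    n_grid: int = 41,
    pp_threshold: float = 0.8,
) -> ScenarioResult:
    """Apply a recalculation rule at every continuation interim outcome.

    ``base_design`` lives on the effective (one-arm) scale; reported sample
    sizes are two-arm totals (4x the effective size).  The policy maps the
    observed interim z to the revised prior (a constant map for
    data-independent revisions; e.g. averaging the observed effect with the
    planning alternative for a response-adaptive heuristic).  Recalculated
    totals are clipped to ``n_total_range`` with the critical value
    re-pinned to the conditional error, and the procedure's unconditional
    power and expected total sample size are evaluated at ``eval_theta``.
    """
    m = int(round(base_design.m))
    zf, ze = base_design.z_futility, base_design.z_efficacy
    eps = 1e-6
    z_grid = np.linspace(zf + eps, ze - eps, n_grid)
    lo_eff, hi_eff = (effective for effective in
                      (n_total_range[0] / 4.0, n_total_range[1] / 4.0))
    n_new = np.empty(n_grid)
    c_new = np.empty(n_grid)
    step1_cache: dict = {}
    cached_prior: Prior | None = None
    for i, z in enumerate(z_grid):
        interim = InterimState(m, float(z))
        psi = prior_update_policy(float(z))
        n0, c0, ce, pp_old = _design_ce_pp(base_design, old_prior, float(z))
        if rule == "not_worse":
            target = pp_old
        elif rule == "pp_ge":
            target = pp_threshold
        elif rule == "reoptimize":
            if cached_prior != psi:
                step1_cache.clear()
                cached_prior = psi
            n_i, c_i = recalc_reoptimize(
                base_design, interim, old_prior, psi, alpha, target_ep,
                _step1_cache=step1_cache,
            )
            n_new[i], c_new[i] = _clip_pin(n_i, m, z, ce, lo_eff, hi_eff)
            continue
        else:
            raise ValueError(f"unknown rule {rule!r}")
        try:
            n_i, _ = solve_matched(m, float(z), ce, min(target, 1 - 1e-12), psi,
                                   n_cap=4.0 * hi_eff)
        except InfeasibleError:
            n_i = np.inf
        n_new[i], c_new[i] = _clip_pin(n_i, m, z, ce, lo_eff, hi_eff)

    # unconditional operating characteristics at the evaluation effect
    mu = math.sqrt(m) * eval_theta
    x, w = np.polynomial.legendre.leggauss(400)
    zq = zf + 0.5 * (ze - zf) * (x + 1.0)
    wq = 0.5 * (ze - zf) * w
    nq = np.interp(zq, z_grid, n_new)
    cq = np.interp(zq, z_grid, c_new)
    dens = np.exp(-0.5 * (zq - mu) ** 2) / math.sqrt(2 * math.pi)
    cp = conditional_power(m, nq, zq, cq, eval_theta)
    p_eff = ndtr(mu - ze) if np.isfinite(ze) else 0.0
    p_fut = ndtr(zf - mu) if np.isfinite(zf) else 0.0
    power = float(p_eff + np.sum(wq * dens * cp))
    e_n_eff = float((p_eff + p_fut) * m + np.sum(wq * dens * nq))

    ppsi = np.array([
        float(predictive_power_curve(prior_update_policy(float(z)), m,
                                     np.array([z]), n, c)[0])
        for z, n, c in zip(z_grid, n_new, c_new)
    ])
    curves = pd.DataFrame({
        "z_m": z_grid,
        "observed_effect": z_grid / math.sqrt(m),
        "n_total": 4.0 * n_new,
        "c": c_new,
        "pp_new_prior": ppsi,
    })
    return ScenarioResult(
        rule=rule,
        curves=curves,
        expected_power=power,
        expected_n_total=4.0 * e_n_eff,
    )


def _clip_pin(n_i, m, z, ce, lo_eff, hi_eff):
    """Clip the recalculated size to the allowed range, re-pin c to the CE."""
    n_c = float(np.clip(n_i, max(lo_eff, m + 1e-6), hi_eff))
    return n_c, float(pinned_critical_value(m, n_c, z, ce))
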
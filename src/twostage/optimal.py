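"""Numerical derivation of optimal two-stage designs.

The design problem: minimize the expected sample size ``E[n(Z_m)]`` under
the planning prior over the interim size ``m``, the early-stopping
boundaries, and the stage-two sample-size and critical-value functions,
subject to a maximal type I error rate constraint and a minimal expected
power constraint.  The stage-two functions are parameterized by their
values on Gauss-Legendre pivots inside the continuation region and
interpolated with cubic splines; objective and constraints integrate the
interpolated functions on a finer quadrature grid, so the optimizer cannot
exploit gaps between interpolation nodes.

A group-sequential variant restricts the stage-two functions to constants,
and a two-arm mapping reduces equal-allocation two-arm trials to the
single-arm machinery via the effective sample size n_total / 4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize
from scipy.special import ndtr

from .designs import OperatingCharacteristics, TwoStageDesign, evaluate_oc
from .monitoring import conditional_power, single_stage_sample_size
from .priors import Prior, theta_quadrature

logger = logging.getLogger(__name__)

__all__ = ["optimize_design", "optimize_gsd", "OptimizationResult",
           "two_arm_total", "effective_from_total"]


def two_arm_total(n_eff):
    """Total two-arm sample size corresponding to an effective (one-arm) size.

    With equal allocation, per-observation unit variance in each arm and a
    mean-difference effect, the z-statistic from k subjects per arm has the
    law of a one-arm statistic with n_eff = k / 2 observations, so
    n_total = 2 k = 4 n_eff.
    """
    return 4.0 * np.asarray(n_eff)


def effective_from_total(n_total):
    return np.asarray(n_total) / 4.0


@dataclass
class OptimizationResult:
    design: TwoStageDesign
    oc: OperatingCharacteristics
    objective: float
    n_iter: int
    success: bool
    message: str
    constraint_residuals: dict = field(default_factory=dict)


class _Problem:
    """Objective/constraint evaluation for a pivot-parameterized design."""

    def __init__(self, prior, alpha, target_ep, order, theta_nodes,
                 m_fixed=None, z_fut_fixed=None, z_eff_fixed=None,
                 gsd=False, ce_cap=None, quad_mult=5, z_eff_min=None):
        self.prior = prior
        self.alpha = alpha
        self.target_ep = target_ep
        self.order = order
        self.gsd = gsd
        self.m_fixed = m_fixed
        self.z_fut_fixed = z_fut_fixed
        self.z_eff_fixed = z_eff_fixed
        self.ce_cap = ce_cap  # callable z -> max conditional error, or None
        self.z_eff_min = z_eff_min
        self.gl_x, _ = np.polynomial.legendre.leggauss(order)
        self.q_x, self.q_w = np.polynomial.legendre.leggauss(quad_mult * order)
        self.th, self.wth = theta_quadrature(prior, theta_nodes)
        cond = prior.conditioned_positive()
        self.thp, self.wthp = theta_quadrature(cond, theta_nodes)
        self.k = 1 if gsd else order  # number of free pivot values

    # decision vector layout: [m?, z_fut?, z_eff?, n2 (k), c2 (k)]
    def unpack(self, x):
        i = 0
        if self.m_fixed is None:
            m, i = x[0], 1
        else:
            m = self.m_fixed
        if self.z_fut_fixed is None:
            zf, i = x[i], i + 1
        else:
            zf = self.z_fut_fixed
        if self.z_eff_fixed is None:
            ze, i = x[i], i + 1
        else:
            ze = self.z_eff_fixed
        n2 = np.asarray(x[i:i + self.k], dtype=float)
        c2 = np.asarray(x[i + self.k:i + 2 * self.k], dtype=float)
        return m, zf, ze, n2, c2

    def _grid(self, x):
        """Quadrature nodes/weights and interpolated n2, c2 on them."""
        m, zf, ze, n2, c2 = self.unpack(x)
        half = 0.5 * (ze - zf)
        z = zf + half * (self.q_x + 1.0)
        w = self.q_w * half
        if self.gsd:
            n2_z = np.full_like(z, n2[0])
            c2_z = np.full_like(z, c2[0])
        else:
            piv = zf + half * (self.gl_x + 1.0)
            n2_z = CubicSpline(piv, n2)(z)
            c2_z = CubicSpline(piv, c2)(z)
        return m, zf, ze, z, w, np.maximum(n2_z, 1e-3), c2_z

    def moments(self, x):
        m, zf, ze, z, w, n2_z, _ = self._grid(x)
        n_tot = m + n2_z
        mu = math.sqrt(m) * self.th[:, None]
        dens = np.exp(-0.5 * (z[None, :] - mu) ** 2) / math.sqrt(2 * math.pi)
        p_stop = ndtr(zf - mu[:, 0]) + ndtr(mu[:, 0] - ze)
        e_n = float(np.sum(self.wth * (p_stop * m + dens @ (w * n_tot))))
        e_n2 = float(np.sum(self.wth * (p_stop * m**2 + dens @ (w * n_tot**2))))
        return e_n, math.sqrt(max(e_n2 - e_n**2, 0.0))

    def objective(self, x):
        return self.moments(x)[0]

    def type1(self, x):
        m, zf, ze, z, w, n2_z, c2_z = self._grid(x)
        dens0 = np.exp(-0.5 * z**2) / math.sqrt(2 * math.pi)
        cp0 = conditional_power(m, m + n2_z, z, c2_z, 0.0)
        return float(ndtr(-ze) + np.sum(w * dens0 * cp0))

    def expected_power(self, x):
        m, zf, ze, z, w, n2_z, c2_z = self._grid(x)
        mu = math.sqrt(m) * self.thp[:, None]
        dens = np.exp(-0.5 * (z[None, :] - mu) ** 2) / math.sqrt(2 * math.pi)
        cp = conditional_power(m, m + n2_z, z[None, :], c2_z[None, :], self.thp[:, None])
        ep = np.sum(self.wthp * (ndtr(self.thp * math.sqrt(m) - ze)
                                 + (dens * cp) @ w))
        return float(ep)

    def ce_slack(self, x):
        """Pointwise conditional-error cap minus achieved, on the fine grid."""
        m, zf, ze, z, w, n2_z, c2_z = self._grid(x)
        ce = conditional_power(m, m + n2_z, z, c2_z, 0.0)
        cap = np.asarray(self.ce_cap(z), dtype=float)
        return cap - ce

    def build_design(self, x) -> TwoStageDesign:
        m, zf, ze, n2, c2 = self.unpack(x)
        half = 0.5 * (ze - zf)
        piv = zf + half * (self.gl_x + 1.0)
        if self.gsd:
            n2 = np.full_like(piv, n2[0])
            c2 = np.full_like(piv, c2[0])
        return TwoStageDesign(
            m=float(m),
            z_futility=float(zf),
            z_efficacy=float(ze),
            pivots=tuple(piv),
            n2=tuple(np.maximum(n2, 0.0)),
            c2=tuple(c2),
            interpolation="cubic_spline",
        )


def _solve(problem: _Problem, x0, bounds):
    cons = [
        {"type": "ineq", "fun": lambda x: problem.alpha - problem.type1(x)},
        {"type": "ineq", "fun": lambda x: problem.expected_power(x) - problem.target_ep},
    ]
    if problem.ce_cap is not None:
        cons.append({"type": "ineq", "fun": problem.ce_slack})
    return minimize(
        problem.objective,
        x0,
        method="SLSQP",
        bounds=bounds,
        constraints=cons,
        options={"maxiter": 500, "ftol": 1e-8},
    )


def _feasible(problem, x, tol=2e-4):
    ok = (problem.type1(x) <= problem.alpha + tol
          and problem.expected_power(x) >= problem.target_ep - tol)
    if ok and problem.ce_cap is not None:
        ok = bool(np.min(problem.ce_slack(x)) >= -tol)
    return ok


def _multistart(problem, x0, bounds, seed, n_starts, jitter=0.1):
    """Run SLSQP from the seed point and jittered restarts; keep the best.

    The warm-start point itself is always a candidate: if it is feasible
    and no restart improves on it, it is returned unchanged.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best_x, best_f = None, np.inf
    if _feasible(problem, x0):
        best_x, best_f = np.asarray(x0, dtype=float), problem.objective(x0)
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(max(n_starts - 1, 0)):
        pert = starts[0] * (1 + jitter * rng.standard_normal(len(x0))) \
            + 0.02 * (hi - lo) * rng.standard_normal(len(x0))
        starts.append(np.clip(pert, lo, hi))
    last = None
    for s in starts:
        res = _solve(problem, s, bounds)
        last = res
        if _feasible(problem, res.x) and res.fun < best_f - 1e-9:
            best_x, best_f = res.x, res.fun
        logger.info("SLSQP start: f=%.4f feasible=%s iters=%d msg=%s",
                    res.fun, _feasible(problem, res.x), res.nit, res.message)
    if best_x is None:
        raise RuntimeError(
            f"optimizer failed to find a feasible design: {last.message}; "
            f"type1={problem.type1(last.x):.5f}, EP={problem.expected_power(last.x):.5f}"
        )
    return best_x, last


def optimize_design(
    prior: Prior,
    alpha: float = 0.025,
    target_ep: float = 0.8,
    order: int = 7,
    theta_nodes: int = 64,
    m_fixed: float | None = None,
    z_fut_fixed: float | None = None,
    z_eff_fixed: float | None = None,
    gsd: bool = False,
    ce_cap=None,
    z_eff_min: float | None = None,
    seed: int | None = 0,
    n_starts: int = 3,
    x0: np.ndarray | None = None,
    round_m: bool = True,
) -> OptimizationResult:
    """Minimize E[n(Z_m)] subject to type-I and expected-power constraints.

    Decision variables: interim size m, futility/efficacy boundaries on the
    interim z-scale, and the stage-two size and critical-value pivot values
    (constants when ``gsd=True``).  Any of m and the boundaries may be
    fixed.  ``ce_cap`` optionally adds pointwise conditional-error caps on
    the integration grid (used by the consistent "reoptimize" rule).
    m is optimized as continuous and rounded at the end, re-polishing the
    remaining variables with m fixed so the constraints hold after rounding.
    """
    single = single_stage_sample_size(prior, alpha, target_ep)
    problem = _Problem(prior, alpha, target_ep, order, theta_nodes,
                       m_fixed, z_fut_fixed, z_eff_fixed, gsd, ce_cap,
                       z_eff_min=z_eff_min)

    if x0 is None:
        x0 = _default_start(problem, single)
    bounds = _bounds(problem, single)
    best_x, res = _multistart(problem, x0, bounds, seed, n_starts)

    if m_fixed is None and round_m:
        m_cont = best_x[0]
        problem2 = _Problem(prior, alpha, target_ep, order, theta_nodes,
                            float(round(m_cont)), z_fut_fixed, z_eff_fixed, gsd,
                            ce_cap, z_eff_min=z_eff_min)
        x0b = best_x[1:]
        bounds2 = _bounds(problem2, single)
        best_x2, res2 = _multistart(problem2, x0b, bounds2, seed, 1)
        problem, best_x, res = problem2, best_x2, res2

    design = problem.build_design(best_x)
    oc = evaluate_oc(design, prior)
    resid = {
        "type1_slack": alpha - problem.type1(best_x),
        "ep_slack": problem.expected_power(best_x) - target_ep,
    }
    logger.info("optimum: E[n]=%.3f, residuals=%s", problem.objective(best_x), resid)
    return OptimizationResult(
        design=design,
        oc=oc,
        objective=float(problem.objective(best_x)),
        n_iter=int(res.nit),
        success=True,
        message=str(res.message),
        constraint_residuals=resid,
    )


def _default_start(problem, single):
    n, c = single.n, single.c
    m0 = 0.4 * n
    zf0, ze0 = 0.2, 2.2
    x0 = []
    if problem.m_fixed is None:
        x0.append(m0)
    else:
        m0 = problem.m_fixed
    if problem.z_fut_fixed is None:
        x0.append(zf0)
    if problem.z_eff_fixed is None:
        x0.append(ze0)
    x0 += [0.7 * n - m0 if 0.7 * n > m0 + 5 else 5.0] * problem.k
    x0 += [c] * problem.k
    return np.asarray(x0, dtype=float)


def _bounds(problem, single):
    n = single.n
    b = []
    if problem.m_fixed is None:
        b.append((2.0, max(n - 2.0, 3.0)))
    if problem.z_fut_fixed is None:
        b.append((-2.0, 1.5))
    if problem.z_eff_fixed is None:
        lo_ze = 1.7 if problem.z_eff_min is None else max(1.7, problem.z_eff_min)
        b.append((lo_ze, max(5.0, lo_ze + 1.0)))
    b += [(0.0, 6.0 * n)] * problem.k
    b += [(0.0, 5.0)] * problem.k
    return b


def optimize_gsd(
    prior: Prior,
    alpha: float = 0.025,
    target_power: float = 0.8,
    z_fut_fixed: float | None = None,
    z_eff_fixed: float | None = None,
    m_fixed: float | None = None,
    seed: int | None = 0,
    n_starts: int = 3,
    **kwargs,
) -> OptimizationResult:
    """Optimal group-sequential design: constant stage-two size and boundary.

    Same constraints as the free-function problem with the search space
    restricted to constant stage-two functions; with a point prior the
    expected-power constraint is a classical power constraint.
    """
    return optimize_design(
        prior, alpha, target_power, gsd=True, m_fixed=m_fixed,
        z_fut_fixed=z_fut_fixed, z_eff_fixed=z_eff_fixed,
        seed=seed, n_starts=n_starts, **kwargs,
    )
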
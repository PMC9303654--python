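"""Conditional power, its estimators, and expected power.

After ``m`` of ``n`` planned observations with interim z-statistic ``z_m``,
the final statistic satisfies the conditional law

    Z_n | Z_m = z_m  ~  N( sqrt(n) theta + sqrt(tau) (z_m - sqrt(m) theta),
                           1 - tau ),        tau = m / n,

so the probability of eventually rejecting (conditional power, CP) is an
explicit normal tail probability in the unknown effect ``theta``.  Three
plug-in estimates of CP are provided: assumed conditional power (ACP, at a
fixed planning alternative), observed conditional power (OCP, at the
interim estimate), and predictive power (PP, the posterior mean of CP
conditional on a positive effect).  Expected power (EP) is the
prior-averaged unconditional power given a positive effect and drives the
single-stage sample-size rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .priors import InterimState, Prior, posterior, posterior_params, theta_quadrature

__all__ = [
    "conditional_power",
    "assumed_cp",
    "observed_cp",
    "predictive_power",
    "expected_power",
    "single_stage_sample_size",
    "estimator_risk",
    "PowerEstimate",
    "EstimatorRisk",
    "SingleStageDesign",
]


@dataclass(frozen=True)
class SingleStageDesign:
    """Fixed-sample design: reject if ``Z_n > c`` after ``n`` observations."""

    n: int
    c: float


@dataclass(frozen=True)
class PowerEstimate:
    estimator: str  # "ACP" | "OCP" | "PP"
    value: float
    interim: InterimState
    n: float
    c: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.value <= 1 + 1e-12:
            raise ValueError("power estimate outside [0, 1]")


def _check_fractions(m, n) -> None:
    m = np.asarray(m)
    n = np.asarray(n)
    if np.any(m <= 0):
        raise ValueError("interim size m must be positive")
    if np.any(n <= m):
        raise ValueError("final size n must exceed interim size m")


def conditional_power(m, n, z_m, c, theta):
    """CP(m, n, z_m, c, theta) = Pr_theta[Z_n > c | Z_m = z_m].

    Vectorized over all arguments (broadcasting).  Requires ``0 < m < n``;
    the degenerate case ``n == m`` (no second stage) is rejected because
    the conditional law collapses to a point mass.
    """
    _check_fractions(m, n)
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    tau = m / n
    mean = np.sqrt(n) * theta + np.sqrt(tau) * (np.asarray(z_m) - np.sqrt(m) * theta)
    out = ndtr(-(np.asarray(c) - mean) / np.sqrt(1.0 - tau))
    return out if out.shape else float(out)


def assumed_cp(interim: InterimState, n: float, c: float, theta1: float) -> PowerEstimate:
    """Conditional power evaluated at the fixed planning alternative theta1."""
    v = conditional_power(interim.m, n, interim.z_m, c, theta1)
    return PowerEstimate("ACP", float(v), interim, n, c)


def observed_cp(interim: InterimState, n: float, c: float) -> PowerEstimate:
    """Conditional power with the interim estimate plugged in for theta."""
    v = conditional_power(interim.m, n, interim.z_m, c, interim.theta_hat)
    return PowerEstimate("OCP", float(v), interim, n, c)


def predictive_power(prior: Prior, interim: InterimState, n: float, c: float) -> PowerEstimate:
    """Posterior-mean conditional power given ``Z_m = z_m`` and a positive effect."""
    post = posterior(prior, interim, condition_positive=True)
    nodes, w = theta_quadrature(post)
    cp = conditional_power(interim.m, n, interim.z_m, c, nodes)
    return PowerEstimate("PP", float(np.sum(w * cp)), interim, n, c)


def predictive_power_curve(prior: Prior, m: int, z_m, n, c) -> np.ndarray:
    """Vectorized PP over matched arrays of (z_m, n, c) at a fixed interim m.

    Uses fixed Gauss-Legendre nodes on the positive part of the prior
    support with zm-dependent posterior weights, avoiding a per-point
    posterior construction.  Point priors reduce to ACP at the mass point.
    """
    z = np.atleast_1d(np.asarray(z_m, dtype=float))
    n = np.broadcast_to(np.asarray(n, dtype=float), z.shape)
    c = np.broadcast_to(np.asarray(c, dtype=float), z.shape)
    if prior.is_point:
        if prior.mu <= 0:
            raise ValueError("point prior has no mass above 0")
        return np.asarray(conditional_power(m, n, z, c, prior.mu))
    lo, hi = max(prior.lower, 0.0), prior.upper
    if hi <= 0:
        raise ValueError("prior has no mass above 0")
    x, wl = np.polynomial.legendre.leggauss(64)
    half = 0.5 * (hi - lo)
    nodes = lo + half * (x + 1.0)
    loc, scale = posterior_params(prior, m, z)  # loc: (nz,)
    dens = np.exp(-0.5 * ((nodes[None, :] - loc[:, None]) / scale) ** 2)
    wz = wl[None, :] * dens
    wz /= wz.sum(axis=1, keepdims=True)
    cp = conditional_power(m, n[:, None], z[:, None], c[:, None], nodes[None, :])
    out = np.sum(wz * cp, axis=1)
    return out


def expected_power(prior: Prior, n: float, c: float) -> float:
    """EP(n, c) = Pr[Z_n > c | Theta > 0] under the prior."""
    cond = prior.conditioned_positive()
    nodes, w = theta_quadrature(cond)
    return float(np.sum(w * ndtr(math.sqrt(n) * nodes - c)))


def single_stage_sample_size(
    prior: Prior, alpha: float = 0.025, target_power: float = 0.8, n_max: int = 100_000
) -> SingleStageDesign:
    """Smallest n whose expected power reaches the target at level alpha.

    The critical value is the (1 - alpha) standard normal quantile; n is
    found by bisection on the (monotone in n) expected power.
    """
    if not 0 < alpha < 1 or not 0 < target_power < 1:
        raise ValueError("alpha and target_power must lie in (0, 1)")
    c = float(ndtri(1.0 - alpha))
    prior.conditioned_positive()  # raises if no positive mass
    lo, hi = 1, 2
    while expected_power(prior, hi, c) < target_power:
        hi *= 2
        if hi > n_max:
            raise ValueError("target power not attainable below n_max")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if expected_power(prior, mid, c) >= target_power:
            hi = mid
        else:
            lo = mid
    return SingleStageDesign(n=hi, c=c)


# ---------------------------------------------------------------------------
# estimator risk (sampling study of the three CP estimators)


@dataclass
class EstimatorRisk:
    """Pointwise bias / MAE / MSE of a CP estimator across true effects."""

    estimator: str
    theta_grid: np.ndarray
    bias: np.ndarray
    mae: np.ndarray
    mse: np.ndarray

    def averaged_mse(self, prior: Prior) -> float:
        """MSE averaged over the grid with prior(. | Theta > 0) weights."""
        cond = prior.conditioned_positive()
        w = cond.pdf(self.theta_grid)
        w = w / w.sum()
        return float(np.sum(w * self.mse))


def estimator_risk(
    prior: Prior | None,
    estimator: str,
    theta_grid,
    m: int,
    n: float,
    c: float,
    theta1: float | None = None,
    gh_nodes: int = 50,
) -> EstimatorRisk:
    """Frequentist risk of a conditional-power estimator.

    For each true effect theta on the grid, the interim statistic is
    integrated out over its unconditional sampling law
    ``Z_m ~ N(sqrt(m) theta, 1)`` (Gauss-Hermite), and the estimator's
    error against the true CP(Z_m, c, theta) is summarized as bias, mean
    absolute error and mean squared error.
    """
    estimator = estimator.upper()
    theta_grid = np.asarray(theta_grid, dtype=float)
    xh, wh = np.polynomial.hermite_e.hermegauss(gh_nodes)
    wh = wh / wh.sum()
    bias = np.empty_like(theta_grid)
    mae = np.empty_like(theta_grid)
    mse = np.empty_like(theta_grid)
    for i, th in enumerate(theta_grid):
        zm = math.sqrt(m) * th + xh
        truth = conditional_power(m, n, zm, c, th)
        if estimator == "ACP":
            if theta1 is None:
                raise ValueError("ACP risk needs theta1")
            est = conditional_power(m, n, zm, c, theta1)
        elif estimator == "OCP":
            est = conditional_power(m, n, zm, c, zm / math.sqrt(m))
        elif estimator == "PP":
            if prior is None:
                raise ValueError("PP risk needs a prior")
            est = predictive_power_curve(prior, m, zm, n, c)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        err = est - truth
        bias[i] = np.sum(wh * err)
        mae[i] = np.sum(wh * np.abs(err))
        mse[i] = np.sum(wh * err**2)
    return EstimatorRisk(estimator, theta_grid, bias, mae, mse)
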
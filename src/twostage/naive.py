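"""Naive conditional-power-threshold sample-size recalculation.

Given an interim look at a single-stage design, the rule picks the smallest
new total sample size ``n'`` (with critical value ``c'``) such that the
predictive power reaches a threshold, subject to the conditional error
principle: the conditional type I error rate of the new design must not
exceed that of the original one, which guarantees overall type I control.
Pinning the conditional-error constraint to equality determines ``c'`` as a
function of ``n'``, after which predictive power is monotone in ``n'`` and
a one-dimensional root-find suffices.  Applying the rule mandatorily at
every interim outcome induces a two-stage design whose implicit futility
boundary sits where even the sample-size cap cannot rescue the power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri

from .designs import TwoStageDesign
from .monitoring import SingleStageDesign, conditional_power, predictive_power_curve
from .priors import InterimState, Prior

__all__ = ["conditional_error", "pinned_critical_value", "recalc_naive",
           "induce_design", "RecalcOutcome"]


def conditional_error(m, n, z_m, c):
    """Conditional type I error rate: CP evaluated at theta = 0."""
    return conditional_power(m, n, z_m, c, 0.0)


def pinned_critical_value(m, n_new, z_m, ce_target):
    """Critical value making the conditional error of (n_new, c') equal ce_target.

    Inverting the theta = 0 conditional law gives
    ``c' = sqrt(m/n') z_m + sqrt(1 - m/n') Phi^{-1}(1 - ce_target)``.
    """
    tau = np.asarray(m, dtype=float) / np.asarray(n_new, dtype=float)
    return np.sqrt(tau) * z_m + np.sqrt(1.0 - tau) * ndtri(1.0 - np.asarray(ce_target))


@dataclass(frozen=True)
class RecalcOutcome:
    action: str  # "continue" | "futility"
    n_new: float | None
    c_new: float | None
    conditional_error: float
    pp: float | None


def _resolve_beta(beta_tilde, z_m: float) -> float:
    b = beta_tilde(z_m) if callable(beta_tilde) else float(beta_tilde)
    if not 0.0 < b < 1.0:
        raise ValueError("beta_tilde must lie in (0, 1)")
    return b


def recalc_naive(
    original: SingleStageDesign,
    interim: InterimState,
    prior: Prior,
    beta_tilde: float | Callable[[float], float] = 0.2,
    nmin: float = None,
    nmax: float = None,
) -> RecalcOutcome:
    """Smallest n' in [nmin, nmax] with predictive power >= 1 - beta_tilde.

    The conditional-error constraint is treated as binding, pinning c'(n');
    infeasibility at the cap means early stopping for futility.  ``nmin``
    must exceed the interim size: stopping at ``n' = m`` would make the
    conditional error of the new design degenerate.
    """
    m, z_m = interim.m, interim.z_m
    if nmin is None or nmax is None:
        raise ValueError("nmin and nmax are required")
    if nmin <= m:
        raise ValueError("nmin must exceed the interim sample size m")
    if nmax < nmin:
        raise ValueError("nmax must be >= nmin")
    target = 1.0 - _resolve_beta(beta_tilde, z_m)
    ce = float(conditional_error(m, original.n, z_m, original.c))

    def pp_at(n_new: float) -> float:
        c_new = pinned_critical_value(m, n_new, z_m, ce)
        return float(predictive_power_curve(prior, m, z_m, n_new, c_new)[0])

    if pp_at(nmax) < target:
        return RecalcOutcome("futility", None, None, ce, pp_at(nmax))
    if pp_at(nmin) >= target:
        n_new = float(nmin)
    else:
        n_new = brentq(lambda n: pp_at(n) - target, nmin, nmax, xtol=1e-8)
    c_new = float(pinned_critical_value(m, n_new, z_m, ce))
    return RecalcOutcome("continue", n_new, c_new, ce, pp_at(n_new))


def futility_boundary(
    original: SingleStageDesign,
    m: int,
    prior: Prior,
    beta_tilde=0.2,
    nmin: float = None,
    nmax: float = None,
    bracket: tuple[float, float] = (-10.0, 10.0),
) -> float:
    """Interim z-value below which even n' = nmax misses the power target.

    Feasibility of the recalculation is monotone in z_m, so the boundary is
    located by root-finding on the cap's predictive-power deficit.
    """
    def deficit(z: float) -> float:
        st = InterimState(m, z)
        target = 1.0 - _resolve_beta(beta_tilde, z)
        ce = float(conditional_error(m, original.n, z, original.c))
        c_new = pinned_critical_value(m, nmax, z, ce)
        return float(predictive_power_curve(prior, m, z, nmax, c_new)[0]) - target

    lo, hi = bracket
    if deficit(lo) > 0:
        return -np.inf
    return float(brentq(deficit, lo, hi, xtol=1e-10))


def induce_design(
    original: SingleStageDesign,
    m: int,
    prior: Prior,
    beta_tilde=0.2,
    nmin: float = None,
    nmax: float = None,
    n_grid: int = 400,
    z_hi: float = 8.0,
) -> TwoStageDesign:
    """Two-stage design induced by mandatory recalculation at every z_m.

    Solves the naive rule pointwise on a z-grid spanning the continuation
    region (from the implicit futility boundary upward; the rule never
    stops early for efficacy) and packs the resulting n(z), c(z) curves
    into a linearly interpolated design.
    """
    zf = futility_boundary(original, m, prior, beta_tilde, nmin, nmax)
    eps = 1e-9
    z = np.linspace(zf + eps, z_hi, n_grid)
    n_vals = np.empty(n_grid)
    c_vals = np.empty(n_grid)
    for i, zi in enumerate(z):
        out = recalc_naive(original, InterimState(m, zi), prior, beta_tilde, nmin, nmax)
        if out.action == "futility":  # only possible by rounding at the boundary
            n_vals[i], c_vals[i] = nmax, pinned_critical_value(
                m, nmax, zi, out.conditional_error
            )
        else:
            n_vals[i], c_vals[i] = out.n_new, out.c_new
    return TwoStageDesign(
        m=m,
        z_futility=zf,
        z_efficacy=np.inf,
        pivots=tuple(z),
        n2=tuple(n_vals - m),
        c2=tuple(c_vals),
        interpolation="linear",
    )


def preference_cutoff(single_n: float, expected_n: float, sd_n: float) -> float:
    """Weight eta at which E[n] + eta SD[n] ties with the fixed design."""
    return (single_n - expected_n) / sd_n
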
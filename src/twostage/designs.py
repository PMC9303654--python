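"""Two-stage design container and operating-characteristic evaluation.

A two-stage design observes ``m`` outcomes, computes ``z_m``, and either
stops early (accept below the futility boundary, reject above the efficacy
boundary) or continues to a total of ``n(z_m)`` observations and rejects if
the final z-statistic exceeds ``c(z_m)``.  The stage-two size and critical
value functions are stored on interpolation pivots inside the continuation
region; group-sequential designs are the special case of constant pivots.

Operating characteristics (expected and maximal sample size, sample-size
standard deviation, expected power, maximal type I error rate) are obtained
by quadrature over the interim statistic and, for power, the prior.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline, interp1d
from scipy.special import ndtr

from .monitoring import SingleStageDesign, conditional_power
from .priors import Prior, theta_quadrature

__all__ = ["TwoStageDesign", "OperatingCharacteristics", "evaluate_oc", "decide",
           "from_single_stage"]

#: integration truncation for an unbounded continuation region
_Z_HI = 12.0


@dataclass(frozen=True)
class TwoStageDesign:
    """Interim boundaries plus pivot-based stage-two functions.

    ``pivots`` are z-values strictly inside ``(z_futility, z_efficacy)``;
    ``n2`` holds the stage-two sample sizes (>= 0) and ``c2`` the final
    critical values at the pivots.  ``z_efficacy = inf`` encodes a design
    without early rejection (continuation extends to the right, with the
    stage-two functions extrapolated as constants beyond the last pivot).
    Sample sizes are kept continuous; rounding happens at decision time.
    """

    m: float
    z_futility: float
    z_efficacy: float
    pivots: tuple
    n2: tuple
    c2: tuple
    interpolation: str = "cubic_spline"

    def __post_init__(self) -> None:
        if not self.z_futility < self.z_efficacy:
            raise ValueError("z_futility must be below z_efficacy")
        p = np.asarray(self.pivots, dtype=float)
        if p.ndim != 1 or len(p) != len(self.n2) or len(p) != len(self.c2):
            raise ValueError("pivots, n2, c2 must have equal length")
        if np.any(np.diff(p) <= 0):
            raise ValueError("pivots must be strictly increasing")
        if p[0] <= self.z_futility or p[-1] >= self.z_efficacy:
            raise ValueError("pivots must lie strictly inside the continuation region")
        if np.any(np.asarray(self.n2) < 0):
            raise ValueError("stage-two sample sizes must be nonnegative")
        if self.interpolation not in ("cubic_spline", "linear"):
            raise ValueError("interpolation must be cubic_spline or linear")

    # -- interpolants ------------------------------------------------------

    def _interp(self, values):
        x = np.asarray(self.pivots, dtype=float)
        y = np.asarray(values, dtype=float)
        if len(x) == 1:
            return lambda z: np.full_like(np.asarray(z, dtype=float), y[0])
        if self.interpolation == "cubic_spline":
            f = CubicSpline(x, y, extrapolate=False)
        else:
            f = interp1d(x, y, bounds_error=False)
        lo, hi = y[0], y[-1]

        def g(z):
            z = np.asarray(z, dtype=float)
            out = f(z)
            out = np.where(z <= x[0], lo, out)
            out = np.where(z >= x[-1], hi, out)
            return out

        return g

    def n2_of(self, z):
        """Stage-two sample size on the continuation region (0 outside)."""
        z = np.asarray(z, dtype=float)
        inside = (z > self.z_futility) & (z < self.z_efficacy)
        # spline undershoot between pivots is clipped: sizes are nonnegative
        return np.where(inside, np.maximum(self._interp(self.n2)(z), 0.0), 0.0)

    def n_of(self, z):
        """Total sample size function n(z) = m + n2(z)."""
        return self.m + self.n2_of(z)

    def c_of(self, z):
        """Final critical value on the continuation region (nan outside)."""
        z = np.asarray(z, dtype=float)
        inside = (z > self.z_futility) & (z < self.z_efficacy)
        return np.where(inside, self._interp(self.c2)(z), np.nan)

    @property
    def has_efficacy_stop(self) -> bool:
        return np.isfinite(self.z_efficacy)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "z_futility": self.z_futility,
            "z_efficacy": self.z_efficacy,
            "pivots": list(self.pivots),
            "n2": list(self.n2),
            "c2": list(self.c2),
            "interpolation": self.interpolation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoStageDesign":
        d = dict(d)
        for k in ("pivots", "n2", "c2"):
            d[k] = tuple(d[k])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "TwoStageDesign":
        return cls.from_dict(json.loads(s))


def from_single_stage(design: SingleStageDesign, m: float) -> TwoStageDesign:
    """Embed a fixed design: no early stopping, constant n and c."""
    return TwoStageDesign(
        m=m,
        z_futility=-np.inf,
        z_efficacy=np.inf,
        pivots=(0.0,),
        n2=(design.n - m,),
        c2=(design.c,),
        interpolation="linear",
    )


def decide(design: TwoStageDesign, z_m: float):
    """Interim decision: 'accept', 'reject', or ('continue', n_total, c).

    Continuation sample sizes are rounded up to whole participants.
    """
    if z_m <= design.z_futility:
        return "accept"
    if z_m >= design.z_efficacy:
        return "reject"
    n = math.ceil(float(design.n_of(z_m)) - 1e-9)
    return ("continue", n, float(design.c_of(z_m)))


@dataclass(frozen=True)
class OperatingCharacteristics:
    expected_n: float
    sd_n: float
    max_n: float
    expected_power: float
    max_type1: float
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_n < -1e-9:
            raise ValueError("sd_n must be nonnegative")

    @property
    def criterion(self) -> float:
        """Weighted score E[n] + eta * SD[n]."""
        return self.expected_n + self.eta * self.sd_n

    def to_dict(self) -> dict:
        return {
            "expected_n": self.expected_n,
            "sd_n": self.sd_n,
            "max_n": self.max_n,
            "expected_power": self.expected_power,
            "max_type1": self.max_type1,
            "eta": self.eta,
            "criterion": self.criterion,
        }


def _cont_quadrature(design: TwoStageDesign, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    lo = design.z_futility if np.isfinite(design.z_futility) else -_Z_HI
    hi = design.z_efficacy if np.isfinite(design.z_efficacy) else _Z_HI
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    half = 0.5 * (hi - lo)
    return lo + half * (x + 1.0), w * half


def evaluate_oc(
    design: TwoStageDesign,
    prior: Prior,
    eta: float = 0.0,
    n_nodes: int = 600,
    theta_nodes: int = 64,
) -> OperatingCharacteristics:
    """Unconditional operating characteristics of a two-stage design.

    Sample-size moments integrate ``n(Z_m)`` against the full prior
    predictive of ``Z_m`` (no conditioning on a positive effect); expected
    power conditions the prior on ``Theta > 0``.  The maximal type I error
    rate integrates the conditional rejection probability at ``theta = 0``
    over the continuation region plus the full mass beyond the efficacy
    boundary (binding boundaries: futility mass never rejects).
    """
    z, wz = _cont_quadrature(design, n_nodes)
    m = design.m
    # n -> m collapses the stage-two law; approximate by a hair above m
    n_z = np.maximum(np.asarray(design.n_of(z), dtype=float), m + 1e-6)
    c_z = np.asarray(design.c_of(z), dtype=float)
    zf, ze = design.z_futility, design.z_efficacy

    def stop_masses(theta):
        mu = math.sqrt(m) * theta
        p_fut = ndtr(zf - mu) if np.isfinite(zf) else 0.0
        p_eff = ndtr(mu - ze) if np.isfinite(ze) else 0.0
        return p_fut, p_eff

    # sample-size moments under the full prior predictive of Z_m
    th, wth = theta_quadrature(prior, theta_nodes)
    e_n = e_n2 = 0.0
    for t, wt in zip(th, wth):
        mu = math.sqrt(m) * t
        dens = np.exp(-0.5 * (z - mu) ** 2) / math.sqrt(2 * math.pi)
        p_fut, p_eff = stop_masses(t)
        e_n += wt * ((p_fut + p_eff) * m + np.sum(wz * dens * n_z))
        e_n2 += wt * ((p_fut + p_eff) * m**2 + np.sum(wz * dens * n_z**2))
    sd_n = math.sqrt(max(e_n2 - e_n**2, 0.0))

    # maximal type I error rate (theta = 0)
    dens0 = np.exp(-0.5 * z**2) / math.sqrt(2 * math.pi)
    cp0 = conditional_power(m, n_z, z, c_z, 0.0)
    _, p_eff0 = stop_masses(0.0)
    max_t1 = float(p_eff0 + np.sum(wz * dens0 * cp0))

    # expected power under the positively-conditioned prior
    cond = prior.conditioned_positive()
    thp, wthp = theta_quadrature(cond, theta_nodes)
    ep = 0.0
    for t, wt in zip(thp, wthp):
        mu = math.sqrt(m) * t
        dens = np.exp(-0.5 * (z - mu) ** 2) / math.sqrt(2 * math.pi)
        cp = conditional_power(m, n_z, z, c_z, t)
        _, p_eff = stop_masses(t)
        ep += wt * (p_eff + np.sum(wz * dens * cp))

    zg = np.linspace(z[0], z[-1], 4001)
    max_n = float(max(np.max(design.n_of(zg)), m))
    return OperatingCharacteristics(
        expected_n=float(e_n),
        sd_n=float(sd_n),
        max_n=max_n,
        expected_power=float(ep),
        max_type1=max_t1,
        eta=eta,
    )


def simulate_oc(
    design: TwoStageDesign,
    prior: Prior,
    n_rep: int = 10**6,
    rng: np.random.Generator | None = None,
    theta: float | None = None,
) -> dict:
    """Monte-Carlo oracle for the operating characteristics.

    Draws theta from the prior (or fixes it), simulates the interim
    statistic and the stage-two increment on the sufficient-statistic
    scale, and applies the design.  Returns empirical moments with
    standard errors for 3-sigma agreement checks against quadrature.
    """
    rng = np.random.default_rng() if rng is None else rng
    th = np.full(n_rep, theta) if theta is not None else prior.rvs(n_rep, rng)
    m = design.m
    zm = math.sqrt(m) * th + rng.standard_normal(n_rep)
    n_tot = np.asarray(design.n_of(zm), dtype=float)
    c = np.asarray(design.c_of(zm), dtype=float)
    cont = (zm > design.z_futility) & (zm < design.z_efficacy)
    reject = zm >= design.z_efficacy
    if np.any(cont):
        n2 = n_tot[cont] - m
        s2 = n2 * th[cont] + np.sqrt(n2) * rng.standard_normal(cont.sum())
        zn = (math.sqrt(m) * zm[cont] + s2) / np.sqrt(n_tot[cont])
        rej_cont = np.zeros(n_rep, dtype=bool)
        rej_cont[np.flatnonzero(cont)] = zn > c[cont]
        reject = reject | rej_cont
    pos = th > 0
    out = {
        "expected_n": float(n_tot.mean()),
        "se_expected_n": float(n_tot.std(ddof=1) / math.sqrt(n_rep)),
        "sd_n": float(n_tot.std(ddof=1)),
        "reject_rate": float(reject.mean()),
        "se_reject_rate": float(reject.std(ddof=1) / math.sqrt(n_rep)),
    }
    if theta is None and pos.any():
        r = reject[pos]
        out["expected_power"] = float(r.mean())
        out["se_expected_power"] = float(r.std(ddof=1) / math.sqrt(pos.sum()))
    return out
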
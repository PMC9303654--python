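"""Effect-size priors and the normal laws built on them.

The package works on the standardized single-observation scale: outcomes
``X_i`` are iid with mean ``theta`` and unit variance, so the z-statistic
after ``k`` observations satisfies ``Z_k ~ N(sqrt(k) * theta, 1)``.

Planning uncertainty about ``theta`` is expressed through a prior, either a
point mass (the classical fixed alternative) or a truncated normal — the
maximum-entropy choice on a compact interval given mean and spread, and
conjugate under the normal likelihood so posteriors stay in the family.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats
from scipy.special import ndtr

__all__ = [
    "Prior",
    "InterimState",
    "point_prior",
    "truncated_normal_prior",
    "prior_density",
    "posterior",
    "predictive_density_zm",
    "theta_quadrature",
]

#: nodes for Gauss-Legendre quadrature on the (bounded) prior support
GL_NODES = 64


class NoPositiveMassError(ValueError):
    """Raised when conditioning on a positive effect leaves zero prior mass."""


@dataclass(frozen=True)
class Prior:
    """Point or truncated-normal prior for the standardized effect size.

    For ``kind == "truncated_normal"``, ``mu`` and ``sigma`` are the
    location and scale of the underlying (untruncated) normal and
    ``lower < upper`` are the truncation bounds.  For ``kind == "point"``
    all mass sits at ``mu`` and the remaining fields are ignored.
    """

    kind: str
    mu: float
    sigma: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "truncated_normal"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "truncated_normal":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("truncated_normal prior needs sigma > 0")
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ValueError("truncated_normal prior needs lower < upper")

    # -- basic functionals -------------------------------------------------

    @property
    def is_point(self) -> bool:
        return self.kind == "point"

    def _dist(self) -> stats.rv_continuous:
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sigma)

    def pdf(self, theta):
        if self.is_point:
            raise ValueError("point priors have no density")
        return self._dist().pdf(theta)

    def mean(self) -> float:
        return self.mu if self.is_point else float(self._dist().mean())

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.is_point:
            return np.full(size, self.mu)
        return self._dist().rvs(size=size, random_state=rng)

    def mass_above(self, x: float) -> float:
        """Prior probability of ``theta > x``."""
        if self.is_point:
            return 1.0 if self.mu > x else 0.0
        return float(self._dist().sf(x))

    def conditioned_positive(self) -> "Prior":
        """The prior conditioned on a positive effect (support truncated at 0)."""
        if self.is_point:
            if self.mu <= 0:
                raise NoPositiveMassError("point prior has no mass above 0")
            return self
        if self.upper <= 0:
            raise NoPositiveMassError("prior has no mass above 0")
        return Prior(
            "truncated_normal",
            mu=self.mu,
            sigma=self.sigma,
            lower=max(self.lower, 0.0),
            upper=self.upper,
        )

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        if self.is_point:
            return {"kind": "point", "mu": self.mu}
        return {
            "kind": "truncated_normal",
            "mu": self.mu,
            "sigma": self.sigma,
            "lower": self.lower,
            "upper": self.upper,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Prior":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Prior":
        return cls.from_dict(json.loads(s))


def point_prior(theta1: float) -> Prior:
    return Prior("point", mu=theta1)


def truncated_normal_prior(mu: float, sigma: float, lower: float, upper: float) -> Prior:
    return Prior("truncated_normal", mu=mu, sigma=sigma, lower=lower, upper=upper)


def default_planning_prior() -> Prior:
    """Truncated normal N(0.4, 0.2^2) on [-0.5, 1].

    A moderately informative planning prior for a standardized effect:
    most mass on small-to-moderate positive effects, a little on harm.
    Used as default throughout the examples.
    """
    return truncated_normal_prior(0.4, 0.2, -0.5, 1.0)


@dataclass(frozen=True)
class InterimState:
    """Interim look after ``m`` observations with z-statistic ``z_m``."""

    m: int
    z_m: float

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("interim sample size m must be >= 1")

    @property
    def theta_hat(self) -> float:
        """Maximum-likelihood interim effect estimate z_m / sqrt(m)."""
        return self.z_m / math.sqrt(self.m)


# ---------------------------------------------------------------------------
# densities and updates


def prior_density(prior: Prior, theta) -> np.ndarray | float:
    """Normalized prior density; zero outside the truncation bounds."""
    return prior.pdf(theta)


def posterior(prior: Prior, interim: InterimState, condition_positive: bool = False) -> Prior:
    """Posterior of theta given ``Z_m = z_m`` (conjugate normal update).

    With a truncated-normal prior and the likelihood
    ``z_m ~ N(sqrt(m) * theta, 1)`` the posterior is again truncated normal
    on the same support with precision ``1/sigma^2 + m`` and location
    ``(mu/sigma^2 + sqrt(m) z_m) / (1/sigma^2 + m)``.  If
    ``condition_positive``, the support is additionally truncated at 0 and
    renormalized.  Point priors are invariant under updating.
    """
    if prior.is_point:
        p = prior
        return p.conditioned_positive() if condition_positive else p
    prec = 1.0 / prior.sigma**2 + interim.m
    loc = (prior.mu / prior.sigma**2 + math.sqrt(interim.m) * interim.z_m) / prec
    post = Prior(
        "truncated_normal",
        mu=float(loc),
        sigma=float(1.0 / math.sqrt(prec)),
        lower=prior.lower,
        upper=prior.upper,
    )
    return post.conditioned_positive() if condition_positive else post


def posterior_params(prior: Prior, m, z_m) -> tuple[np.ndarray, float]:
    """Vectorized conjugate-update location and scale (truncated-normal prior)."""
    prec = 1.0 / prior.sigma**2 + m
    loc = (prior.mu / prior.sigma**2 + np.sqrt(m) * np.asarray(z_m)) / prec
    return loc, 1.0 / math.sqrt(prec)


def predictive_density_zm(
    prior: Prior, m: int, z_m, condition_positive: bool = False
) -> np.ndarray | float:
    """Marginal (prior-predictive) density of ``Z_m`` under the prior.

    For a truncated-normal prior the marginal has the closed form
    ``N(z; sqrt(m) mu, 1 + m sigma^2)`` times the ratio of posterior to
    prior truncation mass; for a point prior it is the shifted standard
    normal density.
    """
    z = np.asarray(z_m, dtype=float)
    if condition_positive:
        prior = prior.conditioned_positive()
    if prior.is_point:
        out = stats.norm.pdf(z - math.sqrt(m) * prior.mu)
        return float(out) if np.isscalar(z_m) else out
    sd_marg = math.sqrt(1.0 + m * prior.sigma**2)
    base = stats.norm.pdf(z, loc=math.sqrt(m) * prior.mu, scale=sd_marg)
    loc, scale = posterior_params(prior, m, z)
    num = ndtr((prior.upper - loc) / scale) - ndtr((prior.lower - loc) / scale)
    den = ndtr((prior.upper - prior.mu) / prior.sigma) - ndtr(
        (prior.lower - prior.mu) / prior.sigma
    )
    out = base * num / den
    return float(out) if np.isscalar(z_m) else out


def theta_quadrature(prior: Prior, n_nodes: int = GL_NODES) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights integrating ``h(theta)`` against the prior.

    Gauss-Legendre on the truncated support, weighted by the prior density,
    so that ``sum(w * h(nodes)) ~= E[h(Theta)]``.  Point priors give a
    single unit-weight node.  Weights are renormalized to sum to one, which
    removes the (tiny) residual quadrature error in the normalizer.
    """
    if prior.is_point:
        return np.array([prior.mu]), np.array([1.0])
    # restrict to the effective support so tight distributions stay resolved
    span = 9.0 * prior.sigma
    lo = max(prior.lower, prior.mu - span)
    hi = min(prior.upper, prior.mu + span)
    if hi <= lo:  # all mass piled against one truncation bound
        lo, hi = ((prior.lower, min(prior.upper, prior.lower + 2 * span))
                  if prior.mu < prior.lower
                  else (max(prior.lower, prior.upper - 2 * span), prior.upper))
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    half = 0.5 * (hi - lo)
    nodes = lo + half * (x + 1.0)
    weights = w * half * prior.pdf(nodes)
    weights = weights / weights.sum()
    return nodes, weights
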
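"""Uncertainty distributions for model parameters.

Probabilistic sensitivity analysis needs a distribution for every uncertain
input.  Probabilities and utilities bounded on [0, 1] get Beta distributions,
fitted either directly from binomial counts or by the method of moments from a
point estimate and a standard error; standard errors quoted only as a range
(L, U) are recovered as (U - L) / (2 * 1.96).  Utility *decrements* (strictly
positive losses) get log-normal distributions fitted by moments.  Parameters
with no reported uncertainty stay fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistributionSpec",
    "se_from_range",
    "beta_from_moments",
    "beta_from_counts",
    "lognormal_for_decrement",
    "fixed",
    "beta_spec_from_range",
]


class InfeasibleMomentsError(ValueError):
    """Raised when (mean, sd) cannot be matched by a Beta distribution."""


@dataclass(frozen=True)
class DistributionSpec:
    """Description of one parameter's uncertainty.

    kind
        One of ``beta_counts``, ``beta_moments``, ``lognormal_decrement``,
        ``dirichlet``, ``uniform`` or ``fixed``.
    params
        Kind-specific parameters: ``(alpha, beta)`` for the Beta kinds,
        ``(mu, sigma)`` on the log scale for the log-normal, a tuple of
        concentrations for the Dirichlet, ``(low, high)`` for the uniform,
        and ``(value,)`` for a fixed parameter.
    point
        Base-case value used in deterministic analyses.
    source
        Provenance note (which table/assumption the value comes from).
    """

    kind: str
    params: tuple
    point: float | tuple
    source: str = ""
    degenerate: bool = field(default=False, compare=False)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the spec. ``size=None`` gives a scalar draw."""
        if self.kind == "fixed":
            val = self.params[0]
            if size is None:
                return val
            return np.broadcast_to(np.asarray(val, dtype=float), (size,)).copy()
        if self.kind == "beta_counts" or self.kind == "beta_moments":
            a, b = self.params
            if self.degenerate or b == 0:
                # no observed failures: point mass at 1 in the limit
                return np.ones(size) if size is not None else 1.0
            return rng.beta(a, b, size=size)
        if self.kind == "lognormal_decrement":
            mu, sigma = self.params
            if sigma == 0.0:
                return np.full(size, math.exp(mu)) if size is not None else math.exp(mu)
            return rng.lognormal(mu, sigma, size=size)
        if self.kind == "dirichlet":
            conc = np.asarray(self.params, dtype=float)
            if size is None:
                return rng.dirichlet(conc)
            return rng.dirichlet(conc, size=size)
        if self.kind == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, size=size)
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    @property
    def mean(self) -> float:
        if self.kind == "fixed":
            return float(self.params[0])
        if self.kind in ("beta_counts", "beta_moments"):
            a, b = self.params
            return 1.0 if (self.degenerate or b == 0) else a / (a + b)
        if self.kind == "lognormal_decrement":
            mu, sigma = self.params
            return math.exp(mu + sigma**2 / 2.0)
        if self.kind == "uniform":
            lo, hi = self.params
            return 0.5 * (lo + hi)
        raise ValueError(f"no scalar mean for kind {self.kind!r}")


def se_from_range(lower: float, upper: float) -> float:
    """Standard error recovered from a (lower, upper) 95% range.

    SE = (U - L) / (2 * 1.96).
    """
    if upper < lower:
        raise ValueError(f"upper ({upper}) < lower ({lower})")
    return (upper - lower) / (2.0 * 1.96)


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta parameters for a given mean and sd.

    Solves mean = a/(a+b) and var = ab / ((a+b)^2 (a+b+1)):
    a = mean * (mean(1-mean)/sd^2 - 1), b = a (1-mean)/mean.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie strictly in (0,1), got {mean}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"sd^2 = {var:.6g} >= mean(1-mean) = {mean * (1 - mean):.6g}"
        )
    if var == 0.0:
        raise InfeasibleMomentsError("zero variance: use a fixed spec instead")
    nu = mean * (1.0 - mean) / var - 1.0
    alpha = mean * nu
    beta = (1.0 - mean) * nu
    return alpha, beta


def beta_from_counts(successes: float, failures: float) -> tuple[float, float]:
    """Beta(successes, failures) — mean matches the observed proportion.

    No +1 pseudo-counts are added, so Beta(k, n-k) has mean exactly k/n.
    ``failures == 0`` is a degenerate point mass at 1 (flagged by the caller).
    """
    if successes < 0 or failures < 0:
        raise ValueError("counts must be non-negative")
    if successes + failures == 0:
        raise ValueError("successes + failures must be positive")
    return float(successes), float(failures)


def lognormal_for_decrement(mean_decrement: float, sd: float,
                            source: str = "") -> DistributionSpec:
    """Log-normal spec for a positive utility decrement, fitted by moments.

    mu = ln(mean) - sigma^2/2,  sigma^2 = ln(1 + sd^2/mean^2), so the draws
    have natural-scale mean ``mean_decrement`` and sd ``sd``.
    """
    if mean_decrement <= 0:
        raise ValueError("mean_decrement must be positive (magnitude of loss)")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    sigma2 = math.log1p((sd / mean_decrement) ** 2)
    mu = math.log(mean_decrement) - sigma2 / 2.0
    return DistributionSpec(
        kind="lognormal_decrement",
        params=(mu, math.sqrt(sigma2)),
        point=mean_decrement,
        source=source,
    )


def fixed(value, source: str = "") -> DistributionSpec:
    return DistributionSpec(kind="fixed", params=(value,), point=value, source=source)


def beta_spec_from_range(point: float, lower: float, upper: float,
                         source: str = "") -> DistributionSpec:
    """Beta spec with mean = point and SE from the (lower, upper) range."""
    a, b = beta_from_moments(point, se_from_range(lower, upper))
    return DistributionSpec(kind="beta_moments", params=(a, b), point=point,
                            source=source)
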
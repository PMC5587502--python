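"""Circular spawning-time distributions on the unit interval.

Spawning time ``s`` is the fraction of the year at which an individual was
spawned.  The population distribution is a von Mises wrapped onto [0, 1):
the angle ``theta = 2 pi s`` is von Mises with location ``2 pi mu`` and
concentration ``tau``, so the unit-interval density carries the 2 pi
Jacobian and reads

    p(s) = exp(tau * cos(2 pi (s - mu))) / I0(tau),      s in [0, 1),

which integrates to one and reduces to the uniform density 1 at tau = 0.
``tau`` is the concentration: a species with a short spawning season (cod,
tau = 5.473) has a more peaked density than one with a long season
(herring, tau = 0.404).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.special import i0e

__all__ = ["SpawningDist", "density", "sample", "cdf", "truncated_log_density"]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SpawningDist:
    """Von Mises spawning-time distribution on [0, 1).

    Attributes
    ----------
    mu : float
        Location (peak spawning time), fraction of year in [0, 1).
    tau : float
        Concentration, >= 0; tau = 0 is uniform.
    """

    mu: float
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu < 1.0:
            raise ValueError(f"mu must lie in [0, 1), got {self.mu}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")


def density(dist: SpawningDist, s):
    """Spawning-time density at s in [0, 1)."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s >= 1)):
        raise ValueError("spawning time must lie in [0, 1)")
    # exp(tau cos(.)) / I0(tau), computed with the scaled Bessel function
    # so large concentrations do not overflow
    out = np.exp(dist.tau * (np.cos(_TWO_PI * (s - dist.mu)) - 1.0)) / i0e(dist.tau)
    return out if out.ndim else float(out)


def log_density(dist: SpawningDist, s):
    """Log of :func:`density`; vectorized, no domain check beyond [0,1)."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s >= 1)):
        raise ValueError("spawning time must lie in [0, 1)")
    out = dist.tau * (np.cos(_TWO_PI * (s - dist.mu)) - 1.0) - np.log(i0e(dist.tau))
    return out if out.ndim else float(out)


def sample(dist: SpawningDist, n: int, seed=None) -> np.ndarray:
    """Draw n spawning times in [0, 1).

    ``seed`` may be an int, a Generator, or None.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if dist.tau == 0.0:
        return rng.uniform(0.0, 1.0, size=n)
    theta = stats.vonmises.rvs(kappa=dist.tau, loc=_TWO_PI * dist.mu, size=n, random_state=rng)
    return np.mod(theta / _TWO_PI, 1.0)


def cdf(dist: SpawningDist, upper: float) -> float:
    """Probability mass of [0, upper), 0 < upper <= 1, by adaptive quadrature."""
    if not 0.0 < upper <= 1.0:
        raise ValueError("upper must lie in (0, 1]")
    if upper == 1.0 or dist.tau == 0.0:
        return float(upper)
    val, _ = integrate.quad(lambda x: density(dist, x), 0.0, upper, limit=200)
    return float(val)


def truncated_log_density(dist: SpawningDist, s, upper_bound: float = 1.0):
    """Log density of s given s < upper_bound (renormalized truncation).

    With upper_bound = 1 this is the plain log density.  Truncation keeps
    the latent-spawning likelihood valid where the effective age must
    exceed t0.
    """
    if not 0.0 < upper_bound <= 1.0:
        raise ValueError("upper_bound must lie in (0, 1]")
    s = np.asarray(s, dtype=float)
    if np.any(s >= upper_bound):
        raise ValueError("s must be strictly below upper_bound")
    out = log_density(dist, s) - np.log(cdf(dist, upper_bound))
    return out if out.ndim else float(out)
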
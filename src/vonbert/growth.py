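"""Deterministic growth mathematics.

The von Bertalanffy growth function (VBGF)

    l(a) = l_inf * (1 - exp(-k * (a - t0)))

describes expected length at continuous age ``a``.  Survey ages are binned
(integer winters survived), so the continuous age entering the VBGF is an
*effective age* built from the winters count ``t``, the survey fraction of
the year ``q`` and the (possibly latent) spawning time ``s``:

    a = t - s + q.

Within-year growth need not be uniform.  A seasonal curve ``f`` maps the
fraction of the year to the cumulative fraction of that year's von
Bertalanffy growth already completed (f(0)=0, f(1)=1, non-decreasing); ages
are then mapped to *theoretical* ages ``floor(a) + f(frac(a))`` before
entering the growth curve, which leaves the interpretation of ``k`` and
``l_inf`` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GrowthParams",
    "SeasonalCurve",
    "SomersParams",
    "vbgf_length",
    "seasonal_fraction",
    "somers_fraction",
    "theoretical_age",
    "effective_age",
    "band_expected_length",
]


@dataclass(frozen=True)
class GrowthParams:
    """VBGF parameters with multiplicative lognormal length error.

    Attributes
    ----------
    k : float
        Growth coefficient (per year), rate of approach to ``l_inf``. > 0.
    l_inf : float
        Asymptotic length (mm). > 0.
    t0 : float
        Theoretical age (years) at which expected length is zero. <= 0.
    sigma2 : float
        Variance of the log multiplicative error, ``log eps ~ N(0, sigma2)``. > 0.
    """

    k: float
    l_inf: float
    t0: float
    sigma2: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if not self.l_inf > 0:
            raise ValueError(f"l_inf must be > 0, got {self.l_inf}")
        if self.t0 > 0:
            raise ValueError(f"t0 must be <= 0, got {self.t0}")
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))


class SeasonalCurve:
    """Piecewise-linear cumulative annual-growth-fraction function f(x).

    Defined by ordered knots (x_j, c_j) with first knot (0, 0), last knot
    (1, 1), strictly increasing x_j and non-decreasing c_j (so f' >= 0: an
    individual never shrinks within the year).  Evaluation outside [0, 1]
    is a domain error, not extrapolation.
    """

    def __init__(self, knots: Sequence[tuple[float, float]]):
        knots = [(float(x), float(c)) for x, c in knots]
        if len(knots) < 2:
            raise ValueError("need at least two knots")
        xs = np.array([x for x, _ in knots])
        cs = np.array([c for _, c in knots])
        if xs[0] != 0.0 or cs[0] != 0.0:
            raise ValueError("first knot must be (0, 0)")
        if xs[-1] != 1.0 or cs[-1] != 1.0:
            raise ValueError("last knot must be (1, 1)")
        if np.any(np.diff(xs) <= 0):
            raise ValueError("knot x-coordinates must be strictly increasing")
        if np.any(np.diff(cs) < 0):
            raise ValueError("knot growth fractions must be non-decreasing")
        self.xs = xs
        self.cs = cs

    @classmethod
    def identity(cls) -> "SeasonalCurve":
        """f(x) = x: growth uniform through the year (non-seasonal VBGF)."""
        return cls([(0.0, 0.0), (1.0, 1.0)])

    @classmethod
    def single_knot(cls, x: float, c: float) -> "SeasonalCurve":
        """Three-point interpolator (0,0), (x, c), (1,1).

        The survey-quarter parameterization: with x = 0.75 the free value
        c = f(0.75) is the fraction of annual growth completed by the start
        of the fourth quarter.
        """
        return cls([(0.0, 0.0), (float(x), float(c)), (1.0, 1.0)])

    def __call__(self, x):
        return seasonal_fraction(self, x)

    @property
    def knots(self) -> list[tuple[float, float]]:
        return list(zip(self.xs.tolist(), self.cs.tolist()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"SeasonalCurve({self.knots})"


@dataclass(frozen=True)
class SomersParams:
    """Somers seasonal-oscillation parameters.

    ``c`` is the seasonal amplitude (|c| <= 1 keeps f non-decreasing) and
    ``ts`` the phase offset as a fraction of the year.
    """

    c: float
    ts: float

    def __post_init__(self) -> None:
        if abs(self.c) > 1:
            raise ValueError(f"|c| must be <= 1 for non-decreasing growth, got {self.c}")


def vbgf_length(params: GrowthParams, age):
    """Expected length (mm) at continuous age (years) under the VBGF.

    Strictly increasing in age, bounded above by ``l_inf``; exactly zero at
    ``age == t0``.  Ages below ``t0`` are a domain error (negative growth
    bracket).
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < params.t0):
        raise ValueError(f"age must not be below t0={params.t0}")
    out = params.l_inf * (1.0 - np.exp(-params.k * (age - params.t0)))
    return out if out.ndim else float(out)


def seasonal_fraction(curve: SeasonalCurve, x):
    """Cumulative growth fraction f(x) for fraction-of-year x in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("fraction of year must lie in [0, 1]")
    out = np.interp(x, curve.xs, curve.cs)
    return out if out.ndim else float(out)


def somers_fraction(p: SomersParams, x):
    """Somers sinusoidal growth fraction f(x) = x + (c/2pi) sin(2pi(x - ts)).

    Note f(0) = -(c/2pi) sin(2pi ts) which is zero only when sin(2pi ts)=0;
    the form is kept as conventionally written, so the endpoint identities
    f(0)=0, f(1)=1 hold exactly only for ts in {0, 1/2}.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("fraction of year must lie in [0, 1]")
    out = x + p.c / (2.0 * np.pi) * np.sin(2.0 * np.pi * (x - p.ts))
    return out if out.ndim else float(out)


def theoretical_age(age, curve: SeasonalCurve):
    """Map a continuous age to the theoretical VBGF age floor(a) + f(frac(a)).

    The floor is toward -inf, so the map applies equally to negative ages
    (t0 = -0.713 decomposes as -1 + 0.287).  With the identity curve this
    is the identity map.
    """
    age = np.asarray(age, dtype=float)
    fl = np.floor(age)
    out = fl + seasonal_fraction(curve, age - fl)
    return out if out.ndim else float(out)


def effective_age(winters, survey_frac, spawn_time, curve: SeasonalCurve | None = None):
    """Continuous age entering the VBGF for a binned survey observation.

    Without a seasonal curve: ``t - s + q``.  With one: ``t - f(s) + f(q)``
    (the theoretical-age form).  Setting ``spawn_time=0`` recovers the
    winters-plus-quarter ageing ``t + q``; setting both ``spawn_time`` and
    ``survey_frac`` to zero recovers winters-as-age ``t``.
    """
    winters = np.asarray(winters, dtype=float)
    survey_frac = np.asarray(survey_frac, dtype=float)
    spawn_time = np.asarray(spawn_time, dtype=float)
    if curve is None:
        out = winters - spawn_time + survey_frac
    else:
        out = winters - seasonal_fraction(curve, spawn_time) + seasonal_fraction(curve, survey_frac)
    return out if out.ndim else float(out)


def band_expected_length(params: GrowthParams, a) -> float:
    """Expected length (mm) averaged over the age band [a, a+1].

    Integrates the lognormal-mean length E[l | age] = l_inf e^{sigma2/2}
    (1 - e^{-k(age - t0)}) exactly over the band:

        l_a = l_inf e^{sigma2/2} [1 - (1/k) e^{k t0} (e^{-k a} - e^{-k(a+1)})].

    Used as the length-at-age input of the yield-per-recruit projection.
    """
    a_arr = np.asarray(a)
    if np.any(a_arr < 0) or np.any(a_arr != np.floor(a_arr)):
        raise ValueError("band age must be a non-negative integer")
    a_arr = a_arr.astype(float)
    k, t0 = params.k, params.t0
    if np.any(a_arr <= t0):
        raise ValueError("band age must exceed t0")
    out = params.l_inf * np.exp(params.sigma2 / 2.0) * (
        1.0 - (1.0 / k) * np.exp(k * t0) * (np.exp(-k * a_arr) - np.exp(-k * (a_arr + 1.0)))
    )
    return out if out.ndim else float(out)
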
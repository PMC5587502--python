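"""Yield-per-recruit under the modified Thompson-Bell algorithm.

A cohort of one recruit at age 0 is projected through yearly age classes
under total mortality Z_a = M_a + F * sel_a.  Catch in numbers follows the
Baranov catch equation

    C_a = (F sel_a / Z_a) * N_a * (1 - exp(-Z_a)),

and yield converts numbers to weight with w = alpha * l_a^beta evaluated
at the band-expected length l_a (the exact mean of the lognormal-mean VBGF
over [a, a+1]).  Scanning a grid of fishing mortalities F gives the yield
curve, its maximizer F_max, and — fed with posterior draws of the growth
parameters — the induced distribution of management quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthParams, band_expected_length

__all__ = ["YPRInputs", "YPRResult", "ypr_curve", "f_max", "relative_ypr"]


@dataclass(frozen=True)
class YPRInputs:
    """Fixed (non-growth) inputs of the yield-per-recruit projection.

    ``alpha``/``beta`` convert length (mm) to weight, w = alpha * l^beta.
    ``mortality_at_age`` is natural mortality per year for ages 0..last;
    older ages reuse the last (plus-group) value up to ``max_age``.
    ``selectivity_at_age`` is the per-age fraction of F (default fully
    selected); ``f_grid`` the fishing mortalities scanned.
    """

    alpha: float
    beta: float
    mortality_at_age: tuple
    selectivity_at_age: tuple | None = None
    f_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.0, 3.0 + 1e-9, 0.01), 10))
    max_age: int = 20

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be > 0")
        if any(m <= 0 for m in self.mortality_at_age):
            raise ValueError("natural mortality must be > 0")
        f = np.asarray(self.f_grid, dtype=float)
        if np.any(f < 0) or np.any(np.diff(f) <= 0):
            raise ValueError("f_grid must be non-negative and increasing")
        if self.selectivity_at_age is not None:
            sel = np.asarray(self.selectivity_at_age, dtype=float)
            if np.any((sel < 0) | (sel > 1)):
                raise ValueError("selectivity must lie in [0, 1]")

    def m_vector(self) -> np.ndarray:
        M = np.asarray(self.mortality_at_age, dtype=float)
        return np.array([M[min(a, len(M) - 1)] for a in range(self.max_age + 1)])

    def sel_vector(self) -> np.ndarray:
        if self.selectivity_at_age is None:
            return np.ones(self.max_age + 1)
        sel = np.asarray(self.selectivity_at_age, dtype=float)
        return np.array([sel[min(a, len(sel) - 1)] for a in range(self.max_age + 1)])


@dataclass(frozen=True)
class YPRResult:
    """Yield curve over the F grid with its maximizer."""

    f_grid: np.ndarray
    yield_per_recruit: np.ndarray
    f_max: float
    yield_at_f_max: float
    boundary_warning: bool = False


def _yield_at(growth_weights: np.ndarray, M: np.ndarray, sel: np.ndarray, F: float) -> float:
    """Single-F Thompson-Bell projection; growth_weights = alpha * l_a^beta."""
    Z = M + F * sel
    n_ages = len(M)
    N = np.empty(n_ages)
    N[0] = 1.0
    N[1:] = np.exp(-np.cumsum(Z[:-1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(Z > 0, F * sel / np.where(Z > 0, Z, 1.0), 0.0)
    C = frac * N * (1.0 - np.exp(-Z))
    return float(np.sum(C * growth_weights))


def ypr_curve(growth: GrowthParams, inputs: YPRInputs) -> YPRResult:
    """Yield-per-recruit curve over ``inputs.f_grid`` for one parameter set."""
    M = inputs.m_vector()
    sel = inputs.sel_vector()
    ages = np.arange(inputs.max_age + 1)
    lengths = band_expected_length(growth, ages)
    weights = inputs.alpha * np.asarray(lengths) ** inputs.beta
    f = np.asarray(inputs.f_grid, dtype=float)
    y = np.array([_yield_at(weights, M, sel, float(F)) for F in f])
    fm, ym, boundary = _locate_max(f, y)
    return YPRResult(f_grid=f, yield_per_recruit=y, f_max=fm, yield_at_f_max=ym,
                     boundary_warning=boundary)


def _locate_max(f: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Grid argmax refined by local quadratic interpolation.

    Ties break toward lower F (first maximal grid point).  A maximum on
    the final grid point triggers a boundary warning (grid too short).
    """
    i = int(np.argmax(y))
    boundary = i == len(f) - 1
    if boundary:
        warnings.warn("yield maximum at the end of the F grid; extend f_grid", UserWarning)
    if 0 < i < len(f) - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            fm = f[i] + delta * (f[i + 1] - f[i])
            ym = y1 - 0.25 * (y0 - y2) * delta
            return float(fm), float(ym), boundary
    return float(f[i]), float(y[i]), boundary


def f_max(result: YPRResult) -> float:
    """Fishing mortality maximizing yield-per-recruit."""
    return result.f_max


def ypr_draws(param_draws: pd.DataFrame, inputs: YPRInputs) -> pd.DataFrame:
    """Per-posterior-draw F_max and maximum yield.

    ``param_draws`` needs columns k, l_inf, t0, sigma2.  Returns one row
    per draw with f_max and yield_at_f_max.
    """
    if len(param_draws) == 0:
        raise ValueError("no posterior draws supplied")
    out = np.empty((len(param_draws), 2))
    for i, row in enumerate(param_draws[["k", "l_inf", "t0", "sigma2"]].itertuples(index=False)):
        g = GrowthParams(k=row.k, l_inf=row.l_inf, t0=min(row.t0, 0.0), sigma2=row.sigma2)
        res = ypr_curve(g, inputs)
        out[i] = (res.f_max, res.yield_at_f_max)
    return pd.DataFrame(out, columns=["f_max", "yield_at_f_max"])


def relative_ypr(model_draws: dict, inputs: YPRInputs, reference: str = "II") -> pd.DataFrame:
    """Percentage change in maximum yield per variant relative to a reference.

    ``model_draws`` maps variant label -> posterior parameter draws (a
    DataFrame with k, l_inf, t0, sigma2 columns, or a PosteriorDraws).
    For each draw of each variant the yield at that draw's F_max is
    computed; the per-variant percentage change is reported against the
    reference variant's posterior-mean maximum yield (the reference row is
    identically 0 with sd 0).  Draw-wise values are returned alongside the
    summary so multimodality stays visible.
    """
    if reference not in model_draws:
        raise ValueError(f"reference variant {reference!r} not among fitted models "
                         f"{sorted(model_draws)}")

    def _frame(v):
        return v.draws if hasattr(v, "draws") else v

    per_variant = {name: ypr_draws(_frame(d), inputs) for name, d in model_draws.items()}
    ref_yield = float(per_variant[reference]["yield_at_f_max"].mean())
    rows = []
    for name, yd in per_variant.items():
        pct = 100.0 * (yd["yield_at_f_max"] - ref_yield) / ref_yield
        if name == reference:
            rows.append({"model": name, "pct_change_mean": 0.0, "pct_change_sd": 0.0,
                         "f_max_mean": yd["f_max"].mean(), "draws": pct.to_numpy()})
        else:
            rows.append({"model": name, "pct_change_mean": float(pct.mean()),
                         "pct_change_sd": float(pct.std(ddof=1)) if len(pct) > 1 else 0.0,
                         "f_max_mean": yd["f_max"].mean(), "draws": pct.to_numpy()})
    return pd.DataFrame(rows)
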
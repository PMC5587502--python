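"""Bayesian fitting of the binned-age VBGF model variants.

Five variants differ only in the continuous age entering the growth curve:

    I    a  = t                   winters as age
    II   a  = t + q               winters plus survey fraction
    III  a' = t + f(q)            as II with seasonal growth (free knot c2)
    IV   a  = t - s + q           latent spawning time s per fish
    V    a' = t - f(s) + f(q)     latent spawning with seasonal growth

Observed log-length is Normal(log E[l | age], sigma2); the reported
likelihood is a density over log-length.  Priors follow the weakly
informative scheme: k uniform on [0, 3], wide proper uniforms standing in
for the improper priors on l_inf and t0, sigma2 ~ inv-gamma(0.001, 0.001),
c2 uniform on [0, 1].

Sampling strategy
-----------------
For variants IV and V the per-fish spawning times are marginalized by
fixed-grid (midpoint) quadrature against the truncated von Mises density,
leaving a 4-5 dimensional marginal posterior.  That posterior is sampled
by an adaptive random-walk Metropolis chain whose proposal is seeded from
a Laplace approximation at the MAP (found by numerical optimization) and
re-estimated midway through burn-in.  Per-fish latent spawning times are
then recovered exactly by conditional draws given each retained parameter
draw (a collapsed-Gibbs scheme), which also yields the conditional
per-observation log-likelihood matrix used for WAIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit, logsumexp

from . import spawning as spawning_mod
from .growth import GrowthParams
from .spawning import SpawningDist

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "PosteriorDraws",
    "log_likelihood",
    "log_posterior",
    "fit",
    "summarize",
    "posterior_ages",
    "posterior_predictive_residuals",
]

VARIANTS = ("I", "II", "III", "IV", "V")
_LATENT_VARIANTS = ("IV", "V")
_SEASONAL_VARIANTS = ("III", "V")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Which age construction (variant) to fit, and its fixed inputs.

    ``spawn`` is the fixed spawning-time distribution, required when
    fitting variants IV/V.  ``spawn=None`` with explicitly supplied
    spawning times treats them as known constants (no latent prior term),
    which realizes the degenerate-spawning reductions IV->II and V->III.
    ``seasonal_knot_x`` is the x-position of the free seasonal knot
    (default 0.75, the start of the fourth quarter).
    """

    variant: str
    spawn: SpawningDist | None = None
    seasonal_knot_x: float = 0.75

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not 0.0 < self.seasonal_knot_x < 1.0:
            raise ValueError("seasonal_knot_x must lie in (0, 1)")

    @property
    def has_latents(self) -> bool:
        return self.variant in _LATENT_VARIANTS

    @property
    def has_seasonal(self) -> bool:
        return self.variant in _SEASONAL_VARIANTS

    @property
    def param_names(self) -> list[str]:
        names = ["k", "l_inf", "t0", "sigma2"]
        if self.has_seasonal:
            names.append("c2")
        return names


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    The improper priors on l_inf ([0, inf)) and t0 ((-inf, 0]) are
    realized as wide proper uniforms; the bounds sit far outside any
    posterior mass at survey scales.
    """

    k_bounds: tuple[float, float] = (0.0, 3.0)
    l_inf_upper: float = 10_000.0
    t0_lower: float = -20.0
    sigma2_shape: float = 0.001
    sigma2_scale: float = 0.001
    c2_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not (self.k_bounds[0] < self.k_bounds[1] and self.l_inf_upper > 0 and self.t0_lower < 0):
            raise ValueError("prior bounds must be finite and ordered")

    def log_prior(self, theta: dict) -> float:
        lp = 0.0
        if not self.k_bounds[0] <= theta["k"] <= self.k_bounds[1]:
            return -np.inf
        lp -= np.log(self.k_bounds[1] - self.k_bounds[0])
        if not 0.0 < theta["l_inf"] <= self.l_inf_upper:
            return -np.inf
        lp -= np.log(self.l_inf_upper)
        if not self.t0_lower <= theta["t0"] <= 0.0:
            return -np.inf
        lp -= np.log(-self.t0_lower)
        if theta["sigma2"] <= 0:
            return -np.inf
        lp += stats.invgamma.logpdf(theta["sigma2"], a=self.sigma2_shape, scale=self.sigma2_scale)
        if "c2" in theta:
            if not self.c2_bounds[0] <= theta["c2"] <= self.c2_bounds[1]:
                return -np.inf
        return float(lp)


@dataclass
class PosteriorDraws:
    """MCMC output: parameter draws plus per-observation log-likelihoods.

    ``draws`` has one row per retained draw with columns chain, draw and
    the model parameters.  ``loglik`` is (total draws x observations); for
    latent variants it is conditional on the per-draw latent spawning
    times stored in ``latent_spawn``.
    """

    draws: pd.DataFrame
    loglik: np.ndarray
    spec: ModelSpec
    priors: PriorSpec
    data: pd.DataFrame
    latent_spawn: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names

    @property
    def n_chains(self) -> int:
        return int(self.draws["chain"].nunique())

    def param_matrix(self) -> np.ndarray:
        return self.draws[self.param_names].to_numpy()

    def chain_array(self, name: str) -> np.ndarray:
        """Draws of one parameter shaped (chains, draws-per-chain)."""
        g = self.draws.groupby("chain")[name]
        return np.stack([v.to_numpy() for _, v in g])


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (winters, survey_frac, length) arrays from a dataset."""
    if isinstance(dataset, pd.DataFrame):
        t = dataset["winters"].to_numpy(dtype=float)
        q = dataset["survey_frac"].to_numpy(dtype=float)
        length = dataset["length_mm"].to_numpy(dtype=float)
    else:
        recs = list(dataset)
        t = np.array([r.winters for r in recs], dtype=float)
        q = np.array([r.survey_frac for r in recs], dtype=float)
        length = np.array([r.length for r in recs], dtype=float)
    if len(t) == 0:
        raise ValueError("dataset is empty")
    if np.any(t < 0) or np.any((q < 0) | (q >= 1)) or np.any(length <= 0):
        raise ValueError("dataset violates record invariants")
    if np.any((t == 0) & (q == 0)):
        raise ValueError("impossible record: winters=0 surveyed in quarter 1 (q=0)")
    return t, q, length


def _seasonal_f(x, c2: float, knot_x: float):
    """Piecewise-linear f through (0,0), (knot_x, c2), (1,1)."""
    return np.interp(x, [0.0, knot_x, 1.0], [0.0, float(c2), 1.0])


def _theoretical_t0(t0: float, c2: float, knot_x: float) -> float:
    fl = np.floor(t0)
    return float(fl + _seasonal_f(t0 - fl, c2, knot_x))


def _bracket(theta: dict, variant: str, knot_x: float, t, q, s=None):
    """Growth bracket (effective or theoretical age minus t0/t0')."""
    t0 = theta["t0"]
    if variant == "I":
        return t - t0
    if variant == "II":
        return t + q - t0
    if variant == "IV":
        if s is None:
            raise ValueError("variant IV needs spawning times")
        return t - s + q - t0
    c2 = theta["c2"]
    t0p = _theoretical_t0(t0, c2, knot_x)
    if variant == "III":
        return t + _seasonal_f(q, c2, knot_x) - t0p
    if s is None:
        raise ValueError("variant V needs spawning times")
    return t - _seasonal_f(s, c2, knot_x) + _seasonal_f(q, c2, knot_x) - t0p


def _loglik_from_bracket(theta: dict, bracket, log_length):
    """Normal log density of log-length given the growth bracket.

    Non-positive brackets (effective age at or below t0) give -inf.
    """
    bracket = np.asarray(bracket, dtype=float)
    ok = bracket > 0
    safe = np.where(ok, bracket, 1.0)
    mu = np.log(theta["l_inf"]) + np.log1p(-np.exp(-theta["k"] * safe))
    s2 = theta["sigma2"]
    ll = -0.5 * (_LOG_2PI + np.log(s2)) - (log_length - mu) ** 2 / (2.0 * s2)
    return np.where(ok, ll, -np.inf)


def _theta_dict(params, c2=None) -> dict:
    if isinstance(params, GrowthParams):
        theta = {"k": params.k, "l_inf": params.l_inf, "t0": params.t0, "sigma2": params.sigma2}
    else:
        theta = dict(params)
    if c2 is not None:
        theta["c2"] = float(c2)
    return theta


def log_likelihood(params, spec: ModelSpec, record, spawn_time: float | None = None, c2: float | None = None) -> float:
    """Log density (over log-length) of one observation under a variant.

    ``spawn_time`` conditions variants IV/V on a known spawning time; an
    effective age at or below t0 returns -inf (zero likelihood), never an
    exception.
    """
    theta = _theta_dict(params, c2)
    if spec.has_seasonal and "c2" not in theta:
        raise ValueError(f"variant {spec.variant} requires c2")
    t = np.asarray(float(record.winters) if hasattr(record, "winters") else float(record["winters"]))
    q = np.asarray(float(record.survey_frac) if hasattr(record, "survey_frac") else float(record["survey_frac"]))
    length = float(record.length) if hasattr(record, "length") else float(record["length_mm"])
    s = None
    if spec.has_latents:
        if spawn_time is None:
            raise ValueError(f"variant {spec.variant} needs a spawn_time to condition on")
        s = np.asarray(float(spawn_time))
    br = _bracket(theta, spec.variant, spec.seasonal_knot_x, t, q, s)
    return float(_loglik_from_bracket(theta, br, np.log(length)))


def log_posterior(params, spec: ModelSpec, dataset, priors: PriorSpec | None = None,
                  spawn_times=None, c2: float | None = None) -> float:
    """Joint log posterior (conditional on any supplied latents).

    Sum of per-record log-likelihoods, parameter log priors and — for
    variants IV/V with a spawning distribution in ``spec`` — the truncated
    spawning-time log density of each latent (upper bound
    min(1, t + q - t0), the likelihood-support constraint).
    """
    priors = priors or PriorSpec()
    theta = _theta_dict(params, c2)
    lp = priors.log_prior(theta)
    if not np.isfinite(lp):
        return -np.inf
    t, q, length = _as_arrays(dataset)
    s = None
    if spec.has_latents:
        if spawn_times is None:
            raise ValueError(f"variant {spec.variant} needs spawn_times")
        s = np.asarray(spawn_times, dtype=float)
        if s.shape != t.shape:
            raise ValueError("spawn_times must match the dataset length")
    br = _bracket(theta, spec.variant, spec.seasonal_knot_x, t, q, s)
    ll = _loglik_from_bracket(theta, br, np.log(length))
    total = lp + float(np.sum(ll))
    if not np.isfinite(total):
        return -np.inf
    if spec.has_latents and spec.spawn is not None:
        upper = np.minimum(1.0, t + q - theta["t0"])
        if np.any(s >= upper):
            return -np.inf
        for si, ui in zip(s, upper):
            total += spawning_mod.truncated_log_density(spec.spawn, si, ui)
    return float(total)


# ---------------------------------------------------------------------------
# parameter transform (unconstrained sampling space)
# ---------------------------------------------------------------------------

class _Transform:
    """Map between constrained parameters and unconstrained z-space.

    Bounded parameters use a scaled logit, sigma2 a log transform; the
    log-Jacobian makes the z-space density match the theta-space posterior.
    """

    def __init__(self, spec: ModelSpec, priors: PriorSpec):
        self.names = spec.param_names
        self.bounds = {
            "k": priors.k_bounds,
            "l_inf": (0.0, priors.l_inf_upper),
            "t0": (priors.t0_lower, 0.0),
            "c2": priors.c2_bounds,
        }

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_theta(self, z: np.ndarray) -> dict:
        theta = {}
        for name, zi in zip(self.names, z):
            if name == "sigma2":
                theta[name] = float(np.exp(zi))
            else:
                lo, hi = self.bounds[name]
                theta[name] = float(lo + (hi - lo) * expit(zi))
        return theta

    def to_z(self, theta: dict) -> np.ndarray:
        z = []
        for name in self.names:
            v = theta[name]
            if name == "sigma2":
                z.append(np.log(v))
            else:
                lo, hi = self.bounds[name]
                p = np.clip((v - lo) / (hi - lo), 1e-12, 1 - 1e-12)
                z.append(logit(p))
        return np.array(z, dtype=float)

    def log_jac(self, z: np.ndarray) -> float:
        lj = 0.0
        for name, zi in zip(self.names, z):
            if name == "sigma2":
                lj += zi
            else:
                lo, hi = self.bounds[name]
                # log sigmoid(z) + log sigmoid(-z), stable near the bounds
                lj += np.log(hi - lo) - np.logaddexp(0.0, -zi) - np.logaddexp(0.0, zi)
        return float(lj)


# ---------------------------------------------------------------------------
# marginal likelihood machinery for the latent variants
# ---------------------------------------------------------------------------

class _LikelihoodEngine:
    """Vectorized data log-likelihood as a function of theta.

    Latent variants integrate the spawning time out on a fixed midpoint
    grid against the (truncation-renormalized) von Mises density.
    """

    def __init__(self, spec: ModelSpec, t, q, length, grid_size: int = 128):
        self.spec = spec
        self.t, self.q = t, q
        self.log_length = np.log(length)
        if spec.has_latents:
            if spec.spawn is None:
                raise ValueError(f"fitting variant {spec.variant} requires spec.spawn")
            self.grid = (np.arange(grid_size) + 0.5) / grid_size
            self.log_w = spawning_mod.log_density(spec.spawn, self.grid) - np.log(grid_size)
            # the bracket matrix bracket[i, g] = t_i + (f(q_i)) - t0' - (f(s_g))
            # has one distinct row per (t, q) combination: do the expensive
            # transcendental work on unique rows and gather
            pairs = np.stack([t, q], axis=1)
            uniq, self._inv = np.unique(pairs, axis=0, return_inverse=True)
            self._u_t, self._u_q = uniq[:, 0], uniq[:, 1]

    def _grid_parts(self, theta: dict):
        """Per-unique-row mean log-lengths, support mask and latent-mass
        normalizers on the quadrature grid."""
        spec = self.spec
        t0 = theta["t0"]
        if spec.variant == "IV":
            offset_u = self._u_t + self._u_q - t0
            gs = self.grid
        else:
            c2 = theta["c2"]
            kx = spec.seasonal_knot_x
            offset_u = self._u_t + _seasonal_f(self._u_q, c2, kx) - _theoretical_t0(t0, c2, kx)
            gs = _seasonal_f(self.grid, c2, kx)
        br_u = offset_u[:, None] - gs[None, :]
        ok_u = br_u > 0
        safe = np.where(ok_u, br_u, 1.0)
        mu_u = np.log(theta["l_inf"]) + np.log1p(-np.exp(-theta["k"] * safe))
        den_u = logsumexp(np.where(ok_u, self.log_w[None, :], -np.inf), axis=1)
        return mu_u, ok_u, den_u

    def _exponent(self, theta: dict, mu_u, ok_u):
        """(n, G) matrix lw_g + loglik(l_i | s_g) without the sigma constant."""
        s2 = theta["sigma2"]
        mu = mu_u[self._inv]
        A = self.log_w[None, :] - (self.log_length[:, None] - mu) ** 2 / (2.0 * s2)
        return np.where(ok_u[self._inv], A, -np.inf)

    def loglik_vector(self, theta: dict) -> np.ndarray:
        spec = self.spec
        if not spec.has_latents:
            br = _bracket(theta, spec.variant, spec.seasonal_knot_x, self.t, self.q)
            return _loglik_from_bracket(theta, br, self.log_length)
        mu_u, ok_u, den_u = self._grid_parts(theta)
        A = self._exponent(theta, mu_u, ok_u)
        num = logsumexp(A, axis=1) - 0.5 * (_LOG_2PI + np.log(theta["sigma2"]))
        den = den_u[self._inv]
        # a fish with no feasible spawning time has zero likelihood
        return np.where(np.isfinite(den), num - den, -np.inf)

    def total(self, theta: dict) -> float:
        v = self.loglik_vector(theta)
        tot = float(np.sum(v))
        return tot if np.isfinite(tot) else -np.inf

    def conditional_latents(self, theta: dict, rng: np.random.Generator):
        """Draw s_i | theta, l_i on the grid (jittered within cells).

        Returns (s draws (n,), conditional loglik vector at those draws).
        """
        mu_u, ok_u, _ = self._grid_parts(theta)
        A = self._exponent(theta, mu_u, ok_u)
        A = A - A.max(axis=1, keepdims=True)
        p = np.exp(A)
        cdf = np.cumsum(p, axis=1)
        u = rng.uniform(size=(len(self.t), 1)) * cdf[:, -1:]
        idx = np.minimum((cdf < u).sum(axis=1), len(self.grid) - 1)
        h = 1.0 / len(self.grid)
        s = self.grid[idx] + (rng.uniform(size=len(self.t)) - 0.5) * h
        s = np.clip(s, 0.0, np.nextafter(1.0, 0.0))
        spec = self.spec
        br = _bracket(theta, spec.variant, spec.seasonal_knot_x, self.t, self.q, s)
        # keep draws inside the support (cell jitter can cross the boundary)
        bad = br <= 0
        if bad.any():
            s[bad] = self.grid[idx[bad]]
            br = _bracket(theta, spec.variant, spec.seasonal_knot_x, self.t, self.q, s)
        return s, _loglik_from_bracket(theta, br, self.log_length)


# ---------------------------------------------------------------------------
# adaptive random-walk Metropolis
# ---------------------------------------------------------------------------

def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            continue
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, max(w.max(), 1e-8) * 1e-8, None)
    return np.linalg.cholesky((v * w) @ v.T)


def _run_chain(logpost, z0, cov, burn_in, n_draws, rng, target_accept=0.3):
    """Adaptive RWM: scale adaptation throughout burn-in, covariance
    re-estimated from the second half of burn-in, then frozen sampling."""
    d = len(z0)
    base = 2.38 / np.sqrt(d)
    L = _safe_cholesky(cov)
    log_scale = 0.0
    z = z0.copy()
    lp = logpost(z)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite log posterior at chain start")
    burn_store = np.empty((burn_in, d))
    half = burn_in // 2
    n_acc = 0
    adapt_t = 0
    for i in range(burn_in):
        step = base * np.exp(log_scale) * (L @ rng.standard_normal(d))
        z_new = z + step
        lp_new = logpost(z_new)
        alpha = min(1.0, np.exp(min(0.0, lp_new - lp))) if np.isfinite(lp_new) else 0.0
        if rng.uniform() < alpha:
            z, lp = z_new, lp_new
        adapt_t += 1
        log_scale += (alpha - target_accept) / adapt_t**0.6
        burn_store[i] = z
        # mid-burn-in: switch to the empirical covariance of the chain so far
        if i == half and half >= max(20, 4 * d):
            emp = np.atleast_2d(np.cov(burn_store[half // 2:half].T))
            if np.all(np.isfinite(emp)) and np.linalg.matrix_rank(emp) == d:
                L = _safe_cholesky(emp)
                log_scale, adapt_t = 0.0, 0
    out = np.empty((n_draws, d))
    for i in range(n_draws):
        step = base * np.exp(log_scale) * (L @ rng.standard_normal(d))
        z_new = z + step
        lp_new = logpost(z_new)
        alpha = min(1.0, np.exp(min(0.0, lp_new - lp))) if np.isfinite(lp_new) else 0.0
        if rng.uniform() < alpha:
            z, lp = z_new, lp_new
            n_acc += 1
        out[i] = z
    return out, n_acc / max(n_draws, 1)


def _initial_theta(spec: ModelSpec, priors: PriorSpec, t, q, length) -> dict:
    """Deterministic, data-informed starting point."""
    theta = {
        "k": 0.5 * (priors.k_bounds[0] + priors.k_bounds[1]),
        "l_inf": min(float(length.max()) * 1.1, priors.l_inf_upper * 0.99),
        "t0": -0.5,
    }
    # crude log-linear fit of log-length on log(1 + nominal age) for a
    # starting residual variance
    a = t + q + 1.0
    X = np.column_stack([np.ones_like(a), np.log(a)])
    beta, *_ = np.linalg.lstsq(X, np.log(length), rcond=None)
    resid = np.log(length) - X @ beta
    theta["sigma2"] = float(max(np.var(resid), 1e-4))
    if spec.has_seasonal:
        theta["c2"] = 0.5
    return theta


def _find_map(neg_logpost, z_starts: list[np.ndarray]) -> np.ndarray:
    """Multistart MAP search.

    The marginal posterior can carry local modes along the (k, t0) ridge,
    so a deterministic grid of starting points is explored with
    Nelder-Mead and only the best candidate is polished.
    """
    best_z, best_f = None, np.inf
    for z0 in z_starts:
        if not np.isfinite(neg_logpost(z0)):
            continue
        res = optimize.minimize(neg_logpost, z0, method="Nelder-Mead",
                                options={"maxiter": 1500, "xatol": 1e-6, "fatol": 1e-6})
        if res.fun < best_f:
            best_z, best_f = res.x, res.fun
    if best_z is None:
        raise RuntimeError("no finite starting point for the MAP search")
    res = optimize.minimize(neg_logpost, best_z, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
    if res.fun < best_f:
        best_z, best_f = res.x, res.fun
    res2 = optimize.minimize(neg_logpost, best_z, method="BFGS",
                             options={"maxiter": 500, "gtol": 1e-6})
    return res2.x if res2.fun <= best_f else best_z


def _numerical_hessian(f, z: np.ndarray, h: float = 1e-3) -> np.ndarray:
    d = len(z)
    H = np.empty((d, d))
    f0 = f(z)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            if i == j:
                H[i, i] = (f(z + ei) - 2 * f0 + f(z - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(z + ei + ej) - f(z + ei - ej) - f(z - ei + ej) + f(z - ei - ej)
                ) / (4 * h**2)
    return H


def _laplace_cov(neg_logpost, z_map: np.ndarray) -> np.ndarray:
    H = _numerical_hessian(neg_logpost, z_map)
    # boundary-hugging modes can leave non-finite finite-difference entries;
    # fall back to a conservative diagonal there
    if not np.all(np.isfinite(H)):
        diag = np.diag(H).copy()
        finite_diag = diag[np.isfinite(diag) & (diag > 0)]
        fill = float(finite_diag.max()) if len(finite_diag) else 1.0
        diag[~(np.isfinite(diag) & (diag > 0))] = fill
        H = np.where(np.isfinite(H), H, 0.0)
        np.fill_diagonal(H, diag)
    w, v = np.linalg.eigh(0.5 * (H + H.T))
    w = np.clip(w, max(w.max(), 1e-6) * 1e-8, None)
    return (v / w) @ v.T


def fit(dataset, spec: ModelSpec, priors: PriorSpec | None = None, *,
        chains: int = 4, burn_in: int = 1000, draws: int = 1000, seed: int = 0,
        grid_size: int = 128, max_init_attempts: int = 20,
        loglik_mode: str = "conditional") -> PosteriorDraws:
    """Fit one model variant by adaptive-Metropolis MCMC.

    Parameters mirror the analysis protocol defaults: 4 chains, 1,000
    burn-in iterations and 1,000 retained draws per chain.  For latent
    variants ``grid_size`` controls the spawning-time quadrature grid and
    ``loglik_mode`` whether the stored per-observation log-likelihood
    matrix conditions on the drawn latents ("conditional", default) or
    marginalizes them ("marginal").

    Returns a :class:`PosteriorDraws` whose metadata records seeds,
    acceptance rates and split R-hat per parameter (flagged above 1.05).
    """
    priors = priors or PriorSpec()
    if loglik_mode not in ("conditional", "marginal"):
        raise ValueError("loglik_mode must be 'conditional' or 'marginal'")
    t, q, length = _as_arrays(dataset)
    engine = _LikelihoodEngine(spec, t, q, length, grid_size=grid_size)
    tr = _Transform(spec, priors)

    def logpost_z(z):
        theta = tr.to_theta(z)
        lp = priors.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        return engine.total(theta) + lp + tr.log_jac(z)

    neg = lambda z: -logpost_z(z)

    theta0 = _initial_theta(spec, priors, t, q, length)
    z0 = tr.to_z(theta0)
    if not np.isfinite(logpost_z(z0)):
        raise RuntimeError("non-finite posterior at the deterministic start")
    # deterministic multistart grid across the (k, t0) ridge
    z_starts = [z0]
    k_hi = priors.k_bounds[1]
    for k0 in (0.1, 0.25, 0.5, 1.0, 2.0):
        for t00 in (-0.1, -0.75, -2.0):
            th = dict(theta0, k=min(k0, 0.97 * k_hi), t0=max(t00, 0.97 * priors.t0_lower))
            z_starts.append(tr.to_z(th))
    z_map = _find_map(neg, z_starts)
    cov = _laplace_cov(neg, z_map)
    L = _safe_cholesky(cov)

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains + 1)
    latent_rng = np.random.default_rng(chain_seeds[-1])

    all_draws, accept_rates = [], []
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        z_start, lp_start = None, -np.inf
        for _ in range(max_init_attempts):
            cand = z_map + 0.5 * (L @ rng.standard_normal(tr.dim))
            if np.isfinite(logpost_z(cand)):
                z_start = cand
                break
        if z_start is None:
            raise RuntimeError(f"chain {c}: no finite starting point after {max_init_attempts} attempts")
        zs, acc = _run_chain(logpost_z, z_start, cov, burn_in, draws, rng)
        all_draws.append(zs)
        accept_rates.append(acc)

    rows = []
    for c, zs in enumerate(all_draws):
        for i, z in enumerate(zs):
            theta = tr.to_theta(z)
            rows.append({"chain": c, "draw": i, **theta})
    df = pd.DataFrame(rows)

    total = chains * draws
    n_obs = len(t)
    thetas = [tr.to_theta(z) for zs in all_draws for z in zs]
    loglik = np.empty((total, n_obs))
    latent = None
    if spec.has_latents:
        latent = np.empty((total, n_obs), dtype=np.float32)
        for m, theta in enumerate(thetas):
            if loglik_mode == "marginal":
                loglik[m] = engine.loglik_vector(theta)
                s, _ = engine.conditional_latents(theta, latent_rng)
            else:
                s, ll = engine.conditional_latents(theta, latent_rng)
                loglik[m] = ll
            latent[m] = s
    else:
        for m, theta in enumerate(thetas):
            loglik[m] = engine.loglik_vector(theta)

    pdraws = PosteriorDraws(
        draws=df, loglik=loglik, spec=spec, priors=priors,
        data=pd.DataFrame({"winters": t.astype(int), "survey_frac": q, "length_mm": length}),
        latent_spawn=latent,
        meta={
            "chains": chains, "burn_in": burn_in, "draws_per_chain": draws,
            "seed": seed, "grid_size": grid_size if spec.has_latents else None,
            "accept_rates": accept_rates, "loglik_mode": loglik_mode,
            "map_estimate": tr.to_theta(z_map),
        },
    )
    pdraws.meta["rhat"] = {p: _split_rhat(pdraws.chain_array(p)) for p in spec.param_names}
    pdraws.meta["converged"] = all(r <= 1.05 for r in pdraws.meta["rhat"].values() if np.isfinite(r))
    return pdraws


def loglik_matrix(param_draws: pd.DataFrame, spec: ModelSpec, dataset, *,
                  grid_size: int = 128, seed: int = 0, mode: str = "conditional") -> np.ndarray:
    """Per-observation log-likelihood matrix rebuilt from stored draws.

    Deterministic for variants I-III; latent variants re-draw the
    conditional spawning times from ``seed`` ("conditional" mode) or
    marginalize them on the quadrature grid ("marginal").
    """
    t, q, length = _as_arrays(dataset)
    engine = _LikelihoodEngine(spec, t, q, length, grid_size=grid_size)
    rng = np.random.default_rng(seed)
    names = spec.param_names
    out = np.empty((len(param_draws), len(t)))
    for m, row in enumerate(param_draws[names].itertuples(index=False)):
        theta = dict(zip(names, row))
        if spec.has_latents and mode == "conditional":
            _, out[m] = engine.conditional_latents(theta, rng)
        else:
            out[m] = engine.loglik_vector(theta)
    return out


def _split_rhat(chains_draws: np.ndarray) -> float:
    """Split R-hat from an array shaped (chains, draws-per-chain)."""
    import arviz as az

    c, n = chains_draws.shape
    if c < 2 or n < 4:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(chains_draws))


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, sd, central quantiles and split R-hat per parameter.

    R-hat above 1.05 is flagged in the ``converged`` column; with fewer
    than two chains R-hat is omitted with a warning.
    """
    rows = {}
    single_chain = draws.n_chains < 2
    if single_chain:
        warnings.warn("R-hat requires at least two chains; omitting", UserWarning)
    for p in draws.param_names:
        x = draws.draws[p].to_numpy()
        rhat = float("nan") if single_chain else _split_rhat(draws.chain_array(p))
        rows[p] = {
            "mean": x.mean(), "sd": x.std(ddof=1),
            "q2.5": np.quantile(x, 0.025), "q50": np.quantile(x, 0.5),
            "q97.5": np.quantile(x, 0.975),
            "rhat": rhat, "converged": bool(rhat <= 1.05) if np.isfinite(rhat) else None,
        }
    return pd.DataFrame(rows).T


def posterior_ages(draws: PosteriorDraws, dataset=None, interval: float = 0.90) -> pd.DataFrame:
    """Per-fish posterior summary of the effective age at survey.

    Only defined for the latent variants (IV/V).  Returns mean, central
    credible interval bounds and interval width per record.
    """
    if not draws.spec.has_latents or draws.latent_spawn is None:
        raise ValueError("posterior ages require a latent-spawning variant (IV or V)")
    data = draws.data if dataset is None else dataset
    t, q, _ = _as_arrays(data)
    s = draws.latent_spawn.astype(float)
    if draws.spec.variant == "IV":
        ages = t[None, :] - s + q[None, :]
    else:
        kx = draws.spec.seasonal_knot_x
        c2 = draws.draws["c2"].to_numpy()
        ages = np.empty_like(s)
        for m in range(s.shape[0]):
            ages[m] = t - _seasonal_f(s[m], c2[m], kx) + _seasonal_f(q, c2[m], kx)
    lo, hi = (1 - interval) / 2, 1 - (1 - interval) / 2
    return pd.DataFrame({
        "mean_age": ages.mean(axis=0),
        "lower": np.quantile(ages, lo, axis=0),
        "upper": np.quantile(ages, hi, axis=0),
        "width": np.quantile(ages, hi, axis=0) - np.quantile(ages, lo, axis=0),
    })


def posterior_predictive_residuals(draws: PosteriorDraws, dataset=None, n_rep: int = 200, seed: int = 0):
    """Standardized log-length residuals and posterior-predictive replicates.

    Residuals are log l - log(fitted mean length) at the posterior-mean
    parameters (latent variants use each fish's posterior-mean effective
    age).  ``n_rep`` replicated datasets are drawn, one per thinned
    posterior draw, for predictive checking.  Returns (residuals,
    replicated log-length matrix (n_rep, n_obs)).
    """
    data = draws.data if dataset is None else dataset
    t, q, length = _as_arrays(data)
    theta_mean = {p: float(draws.draws[p].mean()) for p in draws.param_names}
    spec = draws.spec
    if spec.has_latents:
        mean_age = posterior_ages(draws, data)["mean_age"].to_numpy()
        br = mean_age - theta_mean["t0"]
        if spec.variant == "V":
            # mean_age is already on the theoretical-age scale
            br = mean_age - _theoretical_t0(theta_mean["t0"], theta_mean["c2"], spec.seasonal_knot_x)
    else:
        br = _bracket(theta_mean, spec.variant, spec.seasonal_knot_x, t, q)
    mu = np.log(theta_mean["l_inf"]) + np.log1p(-np.exp(-theta_mean["k"] * np.maximum(br, 1e-12)))
    residuals = np.log(length) - mu

    rng = np.random.default_rng(seed)
    total = len(draws.draws)
    idx = np.linspace(0, total - 1, min(n_rep, total)).astype(int)
    reps = np.empty((len(idx), len(t)))
    for r, m in enumerate(idx):
        theta = {p: float(draws.draws[p].iloc[m]) for p in draws.param_names}
        if spec.has_latents:
            s = draws.latent_spawn[m].astype(float)
            brm = _bracket(theta, spec.variant, spec.seasonal_knot_x, t, q, s)
        else:
            brm = _bracket(theta, spec.variant, spec.seasonal_knot_x, t, q)
        mum = np.log(theta["l_inf"]) + np.log1p(-np.exp(-theta["k"] * np.maximum(brm, 1e-12)))
        reps[r] = mum + rng.normal(0.0, np.sqrt(theta["sigma2"]), size=len(t))
    return residuals, reps
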
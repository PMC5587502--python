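# Methods

## The model

Survey age-length records report, for each fish *i*, the number of winters
survived `t_i` (an otolith-ring count), the fraction of the year at which
the survey ran `q_i` (quarter 1 → 0, quarter 4 → 0.75), and a length
`l_i` in mm. Growth follows the von Bertalanffy growth function (VBGF)
with multiplicative lognormal error:

    l_i = l_inf * (1 - exp(-k * (a_i - t0))) * eps_i,    log eps_i ~ N(0, sigma2)

The true continuous age `a_i` is not observed: a fish with `t` winters
caught at fraction `q` is anywhere in `[t - 1 + q, t + q]` depending on
when within the spawning season it was spawned. Writing `s_i` for the
spawning time (fraction of the year), the effective age is

    a_i = t_i - s_i + q_i.

The population distribution of spawning times is a von Mises on the unit
circle, `s ~ vonMises(mu, tau)` mapped to [0, 1): density
`exp(tau * cos(2 pi (s - mu))) / I0(tau)`. `tau` is read as the
*concentration*: the short-season species (cod, tau = 5.473) has the
peaked density, the long-season one (herring, tau = 0.404) the diffuse
one. At tau = 0 the density is uniform. The hyperparameters (mu, tau) are
fixed inputs from published spawning studies, never estimated.

Within-year growth need not be uniform. A seasonal curve `f(x)` gives the
cumulative fraction of a year's VBGF growth completed by fraction `x` of
the year, with `f(0) = 0`, `f(1) = 1` and `f' >= 0` (no shrinkage). Ages
map to theoretical ages `floor(a) + f(a - floor(a))` (floor toward minus
infinity, so t0 = -0.713 decomposes as -1 + 0.287) before entering the
growth curve; because `f(1) = 1` the interpretation of `k` and `l_inf` is
unchanged. The default seasonal form is the piecewise-linear interpolator
through (0,0), (0.75, c2), (1,1), with `c2 = f(0.75)` a free parameter;
the Somers sinusoid `f(x) = x + (c/2pi) sin(2 pi (x - t_s))` is provided
for reference (note it satisfies the endpoint identities only when
`sin(2 pi t_s) = 0`; it is implemented exactly as conventionally written).

Five variants differ in the age fed to the curve:

| variant | age | free parameters |
|---|---|---|
| I   | `t`                    | k, l_inf, t0, sigma2 |
| II  | `t + q`                | k, l_inf, t0, sigma2 |
| III | `t + f(q)`             | + c2 |
| IV  | `t - s + q`            | + latent s_i per fish |
| V   | `t - f(s) + f(q)`      | + c2 and latent s_i |

Priors: `k ~ U[0, 3]`; improper flat priors on `l_inf` in [0, inf) and
`t0` in (-inf, 0] are realized as wide proper uniforms (`l_inf <= 10,000`
mm, `t0 >= -20` y — far outside any posterior mass at survey scales, and
recorded in the run manifest); `sigma2 ~ inv-gamma(0.001, 0.001)` (shape,
scale); `c2 ~ U[0, 1]`.

**Support constraint.** The likelihood requires the effective age to
exceed t0. Latent spawning times are therefore truncated to
`s < min(1, t + q - t0)` with the density renormalized, *both* when
simulating data and in the likelihood, keeping the generative and fitted
models identical. Parameter/latent combinations that violate the
constraint have zero likelihood (`-inf` log density), never raise.
Whether the constraint should instead be `a > 0` is debatable for
zero-winter fish; `a > t0` is the weaker, likelihood-motivated choice and
is applied uniformly.

The observation density is defined over **log-length**. The choice is
fixed because WAIC values are only comparable within one convention;
model *ordering* is unaffected (the change-of-variables term
`-sum_i log l_i` is identical across variants on a fixed dataset), but
under this convention survey-scale fits produce the familiar large
negative WAIC values.

## Sampling strategy

No probabilistic-programming backend is required: the sampler is a
self-contained adaptive random-walk Metropolis on transformed parameters
(scaled logit for bounded parameters, log for sigma2, with the matching
Jacobians).

For variants IV and V the per-fish latents are *marginalized by
quadrature*: the spawning time enters the likelihood through a fixed
midpoint grid of G = 128 points on [0, 1), against the
truncation-renormalized von Mises weights. This reduces the sampling
problem to 4-5 dimensions regardless of the number of fish. Because the
bracket matrix `t_i + f(q_i) - t0' - f(s_g)` has one distinct row per
(t, q) combination, the expensive transcendental work is done on unique
rows only, making a likelihood evaluation O(n G) cheap arithmetic.

The chain is initialized from a deterministic, data-informed start
(`k` at the prior midpoint, `l_inf` at 1.1 x the maximum observed length,
`t0 = -0.5`, `sigma2` from the residual variance of a crude log-linear
fit, `c2 = 0.5`), driven to the MAP by Nelder-Mead + BFGS, and the
proposal covariance seeded from the Laplace approximation (numerical
Hessian at the MAP, eigenvalue-clipped; boundary-hugging modes — e.g. t0
piling against 0 under a misspecified variant — fall back to a diagonal).
During burn-in the proposal scale follows a Robbins-Monro recursion
toward 0.3 acceptance and the covariance is re-estimated from the chain
midway; after burn-in the proposal is frozen. Defaults: 4 chains, 1,000
burn-in iterations, 1,000 retained draws per chain. Split R-hat is
reported per parameter and flagged above 1.05.

Per-fish latent spawning times are recovered *exactly* by conditional
draws: for each retained parameter draw, `s_i | theta, l_i` is sampled
from its grid-cell posterior (jittered uniformly within the cell). This
collapsed-Gibbs construction targets the same joint posterior as sampling
parameters and latents together, up to grid resolution, and avoids a
random-walk over thousands of latent coordinates that could not mix in
any reasonable budget. A direct conditional route (explicit spawn-time
arguments to `log_likelihood` / `log_posterior`) is kept alongside the
marginal one; the variant-nesting identities (IV→II, V→III at s ≡ 0;
III→II, V→IV at the identity seasonal curve) and a brute-force quadrature
oracle tie the two routes together in the test suite.

**Grid resolution.** G = 128 gives marginal log-likelihood errors of
order 1e-4 (checked against adaptive quadrature), far below posterior
standard deviations at the sample sizes used. The grid size is
configurable; conditional latent draws inherit the same resolution.

## WAIC

WAIC is computed on the deviance scale from the (draws x observations)
log-likelihood matrix:

    waic = -2 * (lppd - p_waic),          p_waic = 2 * sum_i (log E[p_i] - E[log p_i])

with expectations over posterior draws and `log E[p]` evaluated by
log-sum-exp. For latent variants the matrix is **conditional on the
drawn latents** by default — that is what the sampler naturally produces
— with the quadrature-marginalized matrix available as an option; the
two conventions are not mixed within one comparison, and models are only
ranked when computed on the identical dataset.

## Yield per recruit

The modified Thompson-Bell projection: one recruit enters at age 0,
survives age class `a` with total mortality `Z_a = M_a + F * sel_a`, and
is caught according to the Baranov equation
`C_a = (F sel_a / Z_a) N_a (1 - exp(-Z_a))`. Yield converts numbers to
weight with `w = alpha * l_a^beta`, where `l_a` is the band-expected
length — the exact integral of the lognormal-mean VBGF over [a, a+1]:

    l_a = l_inf e^{sigma2/2} [1 - (1/k) e^{k t0} (e^{-k a} - e^{-k (a+1)})].

Note the sign of the t0 exponent: with the convention t0 <= 0 the direct
integral requires `exp(+k t0)`; the form with `exp(-k t0)` sometimes seen
in write-ups disagrees with the integral oracle and is not used here.

Natural mortality beyond the last tabulated age reuses the plus-group
value; the projection runs to `max_age = 20` by default, beyond which the
surviving fraction is below `exp(-6)` for the bundled mortality
schedules, so truncation is immaterial at the reported precision.
Selectivity defaults to 1 at all ages (only the growth inputs vary across
model variants); a per-age vector is accepted. `F_max` is the grid argmax
(default grid 0 to 3 by 0.01) refined by local quadratic interpolation,
with ties broken toward lower F and a warning when the maximum sits on
the grid boundary.

Posterior uncertainty propagates by evaluating the curve at each
posterior draw. The per-variant "% change in maximum yield" is reported
against the *reference variant's posterior-mean maximum yield* (so the
reference row is identically 0 ± 0); because the draw-wise yield
distribution can be multimodal, the raw draw-wise percentages are
returned alongside the mean/sd summary.

## Synthetic surveys

The generator emulates bottom-trawl survey records: winters drawn from
the discrete distribution proportional to cumulative survival
`exp(-sum_j M_j)` under the species' natural mortality schedule with a
plus-group cap (10 winters for herring, 15 for cod) — a surrogate for the
unpublished empirical survey age histogram, built only from the tabulated
mortalities; survey fraction drawn from the recorded quarter mix (herring
18,933 : 3,857 for quarters 1 : 4; cod 1,910 : 905); spawning time from
the truncated von Mises; length lognormal around the VBGF at the
effective age. The impossible cell (t = 0, q = 0 — a first-quarter survey
cannot catch a fish with no winters) and spawning times violating the
support constraint are rejected and redrawn, with the rejection count
recorded.

What the generator does *not* emulate: gear selectivity in sampling,
spatial or year structure, cohort-correlated growth, ageing error in the
otolith counts themselves, or non-lognormal length error. Passing
recovery tests therefore demonstrate correctness of the inference
machinery under the stated generative model, not robustness to those
real-data features.

Generative truths used throughout testing: herring k = 0.60,
l_inf = 293.3 mm, t0 = -0.713 y, sigma = 0.057, mu = 0.868, tau = 0.404;
cod k = 0.24, l_inf = 1143 mm, t0 = -0.179 y, sigma = 0.139, mu = 0.312,
tau = 5.473. (The species table also records a herring spawning location
of 0.858 / 0.405 from the survey-input listing; the simulation
configuration above is the one used for recovery checks.)

## Problem sizes

Recovery runs simulate n = 2,000 fish per species and use the default
sampler protocol (4 x 1,000 draws after 1,000 burn-in) — enough for
posterior standard deviations a factor ~3 wider than survey scale while
keeping a full two-species recovery under ten minutes on one core. The
large-sample inconsistency demonstration uses n = 10,000; the
credible-interval coverage sweep uses 20 replicates of n = 300 with a
reduced protocol (2 x 400 after 400, G = 48).

## Known limitations

- The Metropolis sampler yields effective sample sizes well below the
  nominal 4,000 draws; posterior means and sds are accurate at the
  tolerances tested, but tail quantiles are noisier than a gradient-based
  sampler would give.
- Marginalization resolution is bounded by the spawning grid; extremely
  concentrated spawning distributions (tau >> 100) concentrate posterior
  mass within single grid cells and would need a larger G.
- The YPR projection treats length-weight constants, mortality and
  selectivity as known; only growth-parameter uncertainty is propagated.
- `winters` plus-group caps and the survival-derived age surrogate make
  the simulated age histogram smoother than real survey histograms;
  recovery targets are insensitive to this, year-class strength effects
  are out of scope.
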
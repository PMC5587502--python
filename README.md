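# vonbert

Bayesian von Bertalanffy growth curves for binned survey ages, with
latent spawning times, seasonal growth, WAIC model comparison and
yield-per-recruit propagation.

## The problem

Fish survey databases record the age of a fish as the number of winters
it has survived (`t`, counted from otolith rings) together with the
survey quarter (`q`, as a fraction of the year) and its length. The true
continuous age is anywhere in `[t - 1 + q, t + q]`: two fish in the same
age bin can differ by almost a year depending on when in the spawning
season each was spawned. Fitting the von Bertalanffy growth function
(VBGF)

    l = l_inf * (1 - exp(-k (a - t0))) * eps,    log eps ~ N(0, sigma2)

while pretending the binned age is the true age is *statistically
inconsistent*: with more data the posterior concentrates on the wrong
growth coefficient. `vonbert` instead treats each fish's spawning time
`s` as a latent variable with a fixed von Mises population distribution
on the year circle, so the age entering the growth curve is
`a = t - s + q` (optionally with a seasonal within-year growth curve
`f`, giving `a' = t - f(s) + f(q)`). Five nested model variants — ages
`t`, `t + q`, `t + f(q)`, `t - s + q`, `t - f(s) + f(q)` — can be
fitted, compared by WAIC, and propagated into a Thompson–Bell
yield-per-recruit analysis for management reference points.

The package is aimed at fisheries/growth modellers working with
survey-style age-length keys (bundled presets cover Atlantic herring and
Atlantic cod), but the machinery applies to any taxon whose ages are
binned into yearly groups.

See `docs/methods.md` for the model, priors, sampler and design choices.

## Worked example

Simulate a herring-like survey of 2,000 fish under known growth
parameters (k = 0.60, l_inf = 293.3 mm, t0 = -0.713 y, sigma = 0.057)
and recover them with the latent-spawning model (variant IV):

```python
import vonbert as vb

cfg = vb.herring_config(n=2000, seed=42)      # winters, quarters, spawning, noise
data = vb.simulate_dataset(cfg)                # DataFrame: winters, survey_frac, length_mm
draws = vb.fit(data, vb.ModelSpec("IV", spawn=cfg.spawn),
               chains=4, burn_in=1000, draws=1000, seed=7)
print(vb.summarize(draws))
```

which prints (about 100 s on one core):

```
              mean        sd        q2.5         q50       q97.5      rhat converged
k          0.60565  0.008339    0.589864    0.605283    0.623311  1.017415      True
l_inf   292.794884  0.897158  291.091935  292.748175  294.632638  1.013657      True
t0       -0.713876  0.011941   -0.734371   -0.714793   -0.689428  1.011504      True
sigma2     0.00325  0.000153    0.002972    0.003242    0.003586  1.017123      True
```

Each generative value sits well inside its 95% credible interval
(sigma2 truth: 0.057² = 0.003249), and split R-hat near 1 indicates the
four chains mixed. From here, `vb.posterior_ages(draws)` gives each
fish's inferred age at survey, `vb.waic(draws.loglik)` the model's WAIC,
and `vb.ypr_curve` / `vb.relative_ypr` the yield-per-recruit
consequences of the fitted growth parameters.

The same pipeline is scriptable from a shell:

```sh
vonbert simulate --species herring --n 2000 --seed 42 --out herring.csv
vonbert fit --species herring --data herring.csv --variant IV --seed 7 --out runIV
vonbert fit --species herring --data herring.csv --variant II --seed 8 --out runII
vonbert compare --run runIV --run runII --data herring.csv --out waic.csv
vonbert ypr --draws IV runIV --draws II runII --species herring --reference II --out ypr.csv
```

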
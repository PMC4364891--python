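# hbdsm — hierarchical Bayesian distance sampling from ocean dynamic topography

`hbdsm` infers cetacean population density from line-transect survey data and
satellite altimetry, for ecologists who want spatially explicit density
surfaces with full uncertainty propagation rather than stratified abundance
point estimates. It targets species whose large-scale distribution tracks the
physical structure of the water column — the motivating cases are a
blue-whale-like species (small Poisson-distributed groups) and a
common-dolphin-like species (large log-normal groups) in an eastern-Pacific
setting, where low absolute dynamic topography (ADT, the satellite-measured
height of the sea surface above the geoid, in cm) marks pycnocline shoaling
and productive habitat.

## The model

Survey effort and sightings are gridded into 1/3° cells matching the weekly
ADT raster. The joint hierarchical model couples an observational process
with an ecological one:

**Detection.** Perpendicular distances are half-normal,
`x_j ~ HalfNormal(σ_j)` with `σ_j = w_j·√(2/π)`, where the effective strip
half-width is log-linear in Beaufort sea state `b` and group size `s`
(`ln s` for the dolphin form), with a per-sighting normal residual:

    w_j = exp(α₀ + α₁·b_j + α₂·c(s_j) + ε₀ⱼ)

The same coefficients give each cell's strip width from its effort-weighted
Beaufort `B_i` and the predicted mean group size (per-cell residual ε₁).

**Group size.** `s_j ~ Poisson(λ_s)` (whale form, zero-truncation optional
and on by default since observed groups have `s ≥ 1`) or
`s_j ~ logNormal(μ_s, σ_s²)` (dolphin form), fitted from the sightings alone;
the arithmetic mean group size is `S̃ = exp(μ_s + σ_s²/2)`.

**Counts and density.** Group counts per cell are Poisson,
`n_i ~ Poisson(λ_i)` with

    λ_i = 2·w_i·L_i·d_i·ĝ(0) / S̃

(`L_i` effort in km, `d_i` density in individuals·km⁻², `ĝ(0)` trackline
detection probability with an informative Beta prior built from a published
mean and CV). Density responds log-polynomially to rescaled ADT
`z = (ADT − mean)/100`:

    d_i(2nd) = exp(ω₀ + ω₁·z + ω₂·z² + ε₂),

plus a 3rd-order variant (θ) and their mixture (weight ϑ), compared by DIC.
With `ω₂ < 0` the optimum habitat sits at `z* = −ω₁/(2ω₂)`.

Inference is by MCMC (adaptive Metropolis-within-Gibbs, written in this
package; 3 chains, 10 000 iterations, 2 000 burn-in, thinning 10 by default)
with Gelman–Rubin R̂, batch-means MC errors, DIC and a posterior predictive
Bayesian p-value (Freeman–Tukey discrepancy on the count likelihood). A
`synthetic_data`-style generator (`hbdsm.simulate`) produces complete
surveys — smooth weekly ADT fields, zig-zag transects, covariate-dependent
detections and sparse Poisson counts — with the latent truth attached, so
the entire pipeline is testable without proprietary data.

## Worked example

```python
from hbdsm import whale_like_config, simulate_survey, CetaceanDensityModel, optimum_adt

survey = simulate_survey(whale_like_config(seed=1))   # 516 surveyed cells, 122 sightings

model = CetaceanDensityModel(
    species_form="whale_like", habitat_form="poly2",
    g0_mean=0.921, g0_cv=0.023,
    n_iterations=3000, n_burnin=1000, thin=5, n_chains=3, seed=42,
).fit(survey.cells, survey.sightings)

print(model.summary_.round(4))
```

```
               mean       sd     q2.5   median    q97.5  mc_error    rhat
alpha0       1.3318   0.2192   0.9231   1.3305   1.7668    0.0125  0.9994
alpha1      -0.0647   0.0595  -0.1744  -0.0629   0.0524    0.0034  1.0164
alpha2      -0.0167   0.0537  -0.1177  -0.0202   0.0871    0.0030  1.0031
g0           0.9218   0.0214   0.8746   0.9245   0.9562    0.0007  1.0035
sigma_eps0   0.1665   0.1131   0.0092   0.1487   0.4171    0.0107  0.9997
sigma_eps1   0.2803   0.1825   0.0181   0.2580   0.6841    0.0170  1.0021
lambda_s     1.9340   0.1475   1.6501   1.9287   2.2406    0.0072  1.0007
omega0      -6.6503   0.1974  -7.0561  -6.6476  -6.2669    0.0107  1.0055
omega1     -15.6592   2.7483 -21.6587 -15.4427 -10.9537    0.0890  1.0006
omega2     -35.7466  24.1742 -86.3035 -34.8985   9.2620    0.8779  0.9991
sigma_eps2   0.2709   0.1696   0.0422   0.2412   0.6487    0.0151  1.0065
```

Every row is a model parameter with posterior mean, SD, the 95% credible
interval bounds and median, its Monte Carlo standard error and convergence
diagnostic. Here the generating values (α₀ = 1.111, λ_s = 1.8, ω = (−6.6,
−16.2, −46.9), …) all fall inside their credible intervals; `g0` reproduces
its Beta(≈148.4, ≈12.7) prior (mean 0.921), which is expected — a
single-platform survey cannot separate trackline detectability from the
density intercept, so the posterior is prior-driven.

```python
print(f"DIC {model.dic_:.1f} (pD {model.pd_:.1f}), "
      f"Bayesian p-value {model.bayesian_pvalue_:.3f}")
om = model.summary_.loc[["omega0", "omega1", "omega2"], "median"]
z, cm, dmax = optimum_adt(tuple(om), model.adt_reference_mean_)
print(f"optimum habitat at {cm:.1f} cm ADT, max density {dmax:.2e} ind/km^2")

surface = model.predict(survey.field.isel(week=0))    # q025/median/q975 maps
```

```
DIC 1291.2 (pD 35.6), Bayesian p-value 0.688
optimum habitat at 44.4 cm ADT, max density 7.16e-03 ind/km^2
```

A p-value near 0.5 indicates the Poisson count assumption is adequate;
`predict` returns an `xarray.Dataset` of per-cell density quantiles with
cells outside the fitted ADT range flagged as extrapolations.
`hbdsm.enso_yearly_surfaces` stratifies yearly surfaces by the July–December
mean of a monthly ENSO index (El Niño ≥ +0.5, La Niña ≤ −0.5).

The same pipeline is scriptable from the shell:

```bash
hbdsm simulate --form whale_like --seed 1 --out sim/
hbdsm fit --cells sim/cells.csv --sightings sim/sightings.csv --form poly2 --out fit/
hbdsm predict --posterior fit/ --adt sim/adt.nc --out surface.nc
```

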
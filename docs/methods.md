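# Methods

## Model structure and assumptions

The package fits a joint hierarchical model for line-transect surveys in
which the quantity of ecological interest — population density as a function
of absolute dynamic topography (ADT) — is linked to the raw observations
through an explicit observational process. All sub-models share parameters
and are fitted jointly, so detection uncertainty propagates into the habitat
response.

Assumptions, in the order they act:

1. **Half-normal detection.** The probability of detecting a group decays as
   `exp(-x²/2σ²)` in perpendicular distance `x`. The scale relates to the
   effective strip half-width (ESW) by `σ = w·√(2/π)`, the unique relation
   for which `∫₀^∞ g(x) dx = w`. Distances are untruncated by default; a
   right-truncation option exists for robustness studies. No alternative
   detection keys (hazard-rate, uniform) are provided.
2. **Log-linear ESW.** `ln w` is linear in Beaufort sea state and a
   group-size covariate (raw size for the whale form, `ln s` for the dolphin
   form), with i.i.d. normal residuals: one per sighting (ε₀) and one per
   cell (ε₁). At cell level the group-size covariate is the predicted mean on
   the same scale — the Poisson mean `λ_s`, or the log-scale mean
   `μ_s + σ_s²/2 = ln S̃` — so the shared slope α₂ multiplies commensurate
   quantities at both levels.
3. **Group sizes carry no spatial signal.** They are fitted from the
   sightings alone (Poisson or log-normal); the per-cell mean group size is a
   single parameter, not a spatial field.
4. **Sparse Poisson counts.** Group counts per surveyed cell-year are
   Poisson with mean `λ_i = 2 w_i L_i d_i ĝ(0) / S̃`. Division by the mean
   group size converts individual density (ind·km⁻²) to group density; any
   other arrangement is dimensionally inconsistent. Gridding effort into
   cells of the raster's resolution keeps per-cell expected counts well below
   one, which is what makes the Poisson assumption (and its posterior
   predictive check, below) well behaved.
5. **g(0) is imported knowledge.** A single trackline detection probability
   per species, shared across cells, with a Beta prior moment-matched to a
   published mean and CV (0.921/0.023 whale-like; 0.970/0.017 dolphin-like).
   The count likelihood only sees the product `e^{ω₀}·ĝ(0)`, so the
   posterior of `ĝ(0)` necessarily tracks its prior; the prior's job is to
   propagate that external uncertainty into the density scale.
6. **Unimodal habitat response.** `ln d` is quadratic (or cubic, or a
   ϑ-mixture of both) in rescaled ADT `z = (ADT − m)/100`, with a per-cell
   residual ε₂. The centering constant `m` is the effort-weighted mean ADT of
   the cells entering the likelihood (stored with every fit and overridable),
   chosen because those are the data the likelihood actually sees. Rescaling
   only improves mixing; `shift_reference` re-expresses coefficients under a
   different centering exactly.

## Priors

Non-informative except for g(0): Normal(0, 100²) on all regression
coefficients and on μ_s; Uniform(0, 10) on the residual SDs σ_ε0, σ_ε1, σ_ε2
and on σ_s; Uniform(0, 100) on λ_s; Uniform(0, 1) on the mixing weight ϑ;
the Beta prior on g(0) as above. At the simulated data sizes the likelihood
dominates everything except g(0) (by design) and the split between σ_ε1 and
σ_ε2 (see identifiability, below).

The whale-form group-size likelihood is zero-truncated by default
(`zero_truncated_groupsize=True`): observed groups necessarily contain at
least one animal, and fitting the untruncated pmf to ≥1 data would bias
λ_s upward by `λ/(1−e^{−λ}) − λ` (≈ 0.36 at λ = 1.8), which is several
posterior SDs at realistic sample sizes. The untruncated pmf remains
available both as an option and as the `groupsize_loglik` default for
compatibility with the classical formulation.

## Sampler

No probabilistic-programming backend is used; the sampler
(`hbdsm._sampler`) is an adaptive Metropolis-within-Gibbs scheme:

* coefficient blocks (α; ω; θ) — multivariate normal random-walk proposals
  whose covariance is estimated from the chain history during burn-in
  (Haario-style), with a Robbins–Monro global scale targeting ≈28%
  acceptance;
* positive/bounded scalars (λ_s, σ's, ĝ(0), ϑ) — random-walk proposals on
  log/logit scales with Jacobian corrections, scales targeting ≈44%;
* random-effect vectors — element-wise parallel Metropolis updates (each
  element's likelihood contribution is local to one sighting or cell);
* two non-local moves that are essential in practice: a joint **scale move**
  `(σ, ε) → (cσ, cε)` for each residual family, which traverses the funnel
  between small-SD/small-effects and large-SD/large-effects states, and an
  exact **Gibbs rebalance** of the ε₁/ε₂ split given their sum (the
  likelihood constrains only ε₁+ε₂; the conditional split is normal and is
  sampled in closed form).

All adaptation is frozen at the end of burn-in, so retained draws come from
a fixed, valid kernel. Chains are seeded independently from one
`SeedSequence`; fits are bit-reproducible given (data, config, seed).
Default protocol: 10 000 iterations, 2 000 burn-in, thinning 10, 3 chains —
800 retained draws per chain (the per-chain reading of the protocol;
chains × draws are pooled for summaries).

**Identifiability notes.** (i) ĝ(0) and ω₀ are perfectly confounded; only
the Beta prior locates ĝ(0). (ii) ε₁ (detection residual) and ε₂ (habitat
residual) enter `ln λ_i` identically, so the counts identify only their sum;
the SD split is driven by the hierarchical priors, mixes only through the
rebalance move, and neither SD should be over-interpreted individually.
This mirrors the model's design rather than a defect of the sampler.

## Diagnostics

* **R̂** — classical Gelman–Rubin between/within-chain variance ratio; fits
  with any R̂ > 1.1 set `converged_ = False` and warn, never fail silently.
* **MC error** — batch-means standard error of the posterior mean
  (50 batches over pooled draws).
* **DIC** — `D̄ + pD` with `pD = D̄ − D(posterior means)`, the plug-in
  deviance evaluated at the posterior means of all stochastic quantities,
  random effects included, over the full joint likelihood (distances +
  group sizes + counts). Used to choose among the habitat forms; it carries
  the usual caveats for hierarchical models.
* **Bayesian p-value** — posterior predictive check of the count likelihood:
  per retained draw, the Freeman–Tukey discrepancy `Σ(√n_i − √λ_i)²` is
  computed for the observed counts and for replicate counts drawn from the
  same λ draws; p is the fraction of draws where the replicate discrepancy
  meets or exceeds the observed one (ties split). The raw form `Σ(n−λ)²` is
  available via `discrepancy="sums_of_squares"`. With per-cell random
  effects in the model this check is mildly conservative whenever cells are
  individually informative (λ_i approaching 1), because the effects adapt to
  the observed counts; in the sparse regime the generator produces by
  default (λ_i ≈ 0.1–0.4) the bias is small (p ≈ 0.5–0.65 on correctly
  specified data). Detecting overdispersion therefore requires fixing the
  cell residuals out of the model (`sigma_e1_fixed=0, sigma_e2_fixed=0`),
  in which case strongly overdispersed counts give p ≈ 0.

## Synthetic surveys

`hbdsm.simulate` generates everything downstream code consumes, plus the
latent truth (per-cell λ_i, true ESWs, residuals) for exact oracle tests.

What it emulates: a weekly ADT raster on a 1/3° grid — low-order spatial
harmonics with a weekly-varying component and an AR(1) week-level offset,
clipped to a realistic 30–110 cm range; zig-zag transects chopped into ~10 km
dated segments with categorical Beaufort states (integers 0–5); detections
generated exactly from the model above.

Default study conditions (fixed once, used by the tests and the acceptance
script): a 30 × 30-cell grid, 20 000 km of effort (≈22–30 km per surveyed
cell), detection coefficients, g(0), group-size parameters and habitat
slope/curvature of the magnitudes a blue-whale-like (α₀ = 1.111,
α₁ = −0.008, α₂ = 0.022, λ_s = 1.8, ω₁ = −16.2, ω₂ = −46.9) or
common-dolphin-like (α = (0.172, −0.155, 0.274), S̃ ≈ 259, ω₁ = −10.1,
ω₂ = −28.9) analysis would produce. The density intercepts (ω₀ = −6.6 and
−1.3) are the one deliberately non-realistic choice: real blue-whale
densities would yield ≪1 detection at this total effort, so the intercept is
raised until a survey produces ~120–180 detections while keeping per-cell
expected counts sparse (λ_i ≈ 0.1–0.4) — enough information to fit every
sub-model, in the count regime the gridding is designed to create. Residual
SDs (σ_ε0 = 0.2, σ_ε1 = 0.1, σ_ε2 = 0.3) are moderate overdispersion typical
of line-transect data. Whale-like group sizes are drawn ≥ 1 by rejection
(zero-truncated Poisson, matching the fitted likelihood); dolphin-like sizes
are kept continuous log-normal rather than rounded so the generative model
and the likelihood agree exactly.

What it does **not** emulate: real eastern-Pacific oceanography (no Costa
Rica Dome, Kelvin waves, or coastline), multi-year survey programmes with
changing designs, responsive animal movement, or observer heterogeneity
beyond Beaufort. Passing calibration tests on these surveys demonstrates
that the inference machinery is correct for data satisfying the model's
assumptions — not that the model is adequate for any particular real survey.

Transect placement is a plain sawtooth sweep of the extent; real designs
allocate zig-zags within strata, but placement details do not enter the
likelihood (cells condition on realised effort), so the simple design is
sufficient for testing.

## Numerical choices

* Cell indexing uses half-open intervals with a 1e-9-cell-width snap so
  decimal-exact boundary points land in the upper cell despite binary
  rounding; segment lengths are haversine, splitting is linear in lon/lat
  (error negligible at 1/3°).
* Expected counts are computed on the log scale; overflowing proposals give
  −∞ log-likelihood and are rejected. `λ = 0` with `n > 0` returns the
  representable floor rather than −∞, with a warning.
* Quantile surfaces exclude the cell residual ε₂ by default (the residuals
  belong to the fitted survey's cells, and the conversion from ADT to density
  uses the parameter posteriors); `include_residuals=True` gives
  observation-level bands.
* ENSO labels use ±0.5 thresholds on the July–December mean of the monthly
  index; years without index coverage are labelled "unknown", never dropped.
* NetCDF output is classic-format (scipy backend); booleans are stored as
  int8.

## Problem sizes used in the test suite

Replicated calibration checks (parameter recovery, DIC selection) use a
reduced survey — a 21 × 21-cell grid, 10 000 km of effort, ≈260 surveyed
cells and ~60 detections — fitted with 2 chains × 2 500 iterations
(burn-in 1 000, thinning 3), and 20 replicates; single-fit checks use the
full default survey with 3 chains × 3 000 iterations. These sizes give
per-parameter credible intervals wide enough that 95% coverage is meaningful
while each fit completes in a few seconds.

## Known limitations

* DIC discrimination between nested habitat forms is weak at the reduced
  problem size (the 3rd-order model costs ≈1 effective parameter); the
  selection test asserts only a majority preference, matching how close the
  two models are.
* The σ_ε1/σ_ε2 split and σ_ε0 are weakly identified (above); their R̂
  occasionally exceeds 1.1 at small sample sizes, which the fit reports
  honestly via `converged_`.
* The posterior predictive p-value's regime-dependence (above) means its
  interpretation requires knowing the per-cell information content; it is a
  check of the count likelihood, not of the detection or group-size models.
* Planar geometry inside the simulated extent; the gridding module handles
  geographic lengths, but no land masking or survey-stratum bookkeeping is
  attempted.
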
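# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices, and the limitations of `anthrotrend`.

## Z scores and growth references

A child's height or weight is expressed as a Z score relative to an LMS
reference: Z = ((x/M)^L − 1)/(L·S), with the L = 0 limit log(x/M)/S. The
implementation evaluates the transform as expm1(L·log(x/M))/(L·S), which is
exact in both branches and stable for L near zero; the inverse uses the
matching log1p form and rejects z outside the Box-Cox domain
(1 + L·S·z ≤ 0). Between tabulated ages, L, M and S are linearly
interpolated — standard practice, and smooth enough at monthly resolution.

The packaged tables (`data/who2006_synthetic_lms.csv`,
`data/nchs1977_synthetic_lms.csv`) are *synthetic*: six-monthly anchor
values assembled from public growth-chart medians and SD spans, not the
official releases. They reproduce the familiar unit equivalents of the WHO
2006 standards (one height-for-age Z ≈ 3.2 cm at 24 months, ≈ 4.7 cm at
60 months; one weight-for-age Z ≈ 1.45 kg and ≈ 2.55 kg) to within a
tenth of a unit. Any real LMS table with columns
`kind,metric,sex,age_months,L,M,S` is a drop-in replacement.

### NCHS → WHO conversion

Summary statistics reported against the NCHS 1977 reference are re-expressed
in WHO Z space by deterministic quantile mapping: the source population is
assumed normal in NCHS Z space, mapped through measurement space cell by
cell (each grid age in the requested range × both sexes, equal weights,
uniform age distribution), and its mapped mean, SD and below-−2 tail are
pooled across cells. Gauss–Hermite quadrature (61 nodes) evaluates the
within-cell moments. A `conversion_variance` accompanies every converted
summary: the squared discrepancy between the mapped mean under the normal
assumption and under a mildly left-skewed two-component mixture with the
same mean and SD. This measures the mapping's sensitivity to the
unobserved population shape and is added to the source's observation
variance. When source and target tables coincide, the conversion is the
identity with zero added variance. Converted prevalences are derived from
the mapped normal population (the threshold is mapped cell-wise), not from
the reported prevalence value itself.

## The hierarchical mixture model

### Mean structure

With years t̃ centred at 1998 and covariates x standardised to mean 0,
SD 1 over all country-years:

- rural mean: μ_r(c,t) = a_c + b_c·t̃ + u_{c,t} + x_{c,t}'γ
- urban mean: μ_u(c,t) = μ_r(c,t) + d_c + e_c·t̃
- combined-stratum mean: (1−p_{c,t})·μ_r + p_{c,t}·μ_u with p the
  country-year urban fraction from the metadata (a known input).

a_c, b_c, d_c and e_c decompose into global + region + country terms; each
region/country level has its own SD (nine variance components in total,
including the smoothness SD). u_c is a second-order random walk over the
27 analysis years with its level and linear trend constrained to zero so it
is identified separately from the intercept and slope (implemented as a
quadratic penalty with weight 10⁶ on the level/trend projections, which
makes the prior proper). The urban offset carries an intercept and a linear
slope only; whether it should also carry its own smooth nonlinear component
is genuinely open, and the simpler form was chosen for identifiability at
small data scale.

### Population mixtures

Each country-year-stratum Z distribution is a K = 5 normal mixture with
fixed weights (0.1, 0.2, 0.4, 0.2, 0.1), a fixed mean-zero offset pattern
scaled by a stratum-level skewness parameter λ ≥ 0, and fixed component SD
ratios scaled by a stratum-level s₀ > 0. The mixture mean equals the
stratum mean parameter exactly by construction (the pattern is re-centred
under the weights at specification time). The default pattern produces the
mild left skew typical of child anthropometry. λ and s₀ are estimated
globally per stratum — two free shape parameters per stratum keeps the
shape identifiable from tail-prevalence observations at desk scale;
estimating free weights/offsets for five components would not be. λ is
constrained nonnegative so the direction of skew is pinned to the pattern.

### Observation model

Each source contributes a Gaussian term for its observed mean with variance

    se² + τ²_national (+ τ²_subnational) (+ τ²_partial_age) (+ conversion_variance)

and, when present, a probit-scale term for its observed prevalence below
−2 with delta-method sampling variance p̂(1−p̂)/(n·φ(Φ⁻¹(p̂))²) plus the
same τ terms. The τ parameters are fixed constants of the model
specification (defaults 0.03, 0.06, 0.04 Z), not estimated: with a few
dozen sources they are weakly identified, and treating them as known
non-sampling-error allowances matches how such terms are normally
calibrated externally. Combined-stratum sources tie both stratum means
together through the urban-fraction weighting; prevalence terms for
combined sources use the 2K-component pooled mixture.

### Priors

Fixed effects (global intercepts/slopes, urban offset globals, covariate
coefficients): normal(0, 10²). Hierarchy SDs: half-normal with scale 0.5
(intercept-like) or 0.05 (slope-like and RW2 smoothness — slopes are
per-year quantities an order of magnitude smaller). λ: half-normal(1);
s₀: half-normal(2). All stated explicitly so that deviations are declared,
not buried; they are weakly informative at the scale of child Z scores.

### Sampler

The posterior is explored by a blocked MCMC, exploiting that every mean
parameter enters the Gaussian observation terms linearly:

1. **Linear effects (joint).** Given variance components and mixture shape,
   all intercepts, slopes, offsets, covariate coefficients and RW2 values
   (~270 dimensions at the default desk scale) are drawn jointly. Without
   prevalence observations this is the exact Gaussian full conditional
   (sparse precision, dense Cholesky). With prevalence observations the
   probit terms are linearised and the resulting Gaussian is used as a
   Metropolis–Hastings proposal with exact acceptance correction;
   iterations alternate between linearising at the current state (exact
   there, so local moves always have somewhere to go) and iterating the
   linearisation toward the conditional mode (efficient global refreshes).
   Chains are initialised from a draw of the mode approximation.
2. **Variance components.** Slice sampling of each SD on the log scale,
   followed by joint multiplicative rescaling moves on (SD, effects) per
   block with the scale-group volume correction. The rescaling moves
   traverse the "funnel" that otherwise traps centred Gibbs samplers at
   SD ≈ 0 — without them chains can freeze with the smooth-trend variance
   collapsed.
3. **Mixture shape.** Slice sampling of λ and s₀ per stratum (these touch
   only the prevalence terms).

Acceptance rates for the joint update are typically above 0.95 at the
default scale. Convergence is monitored by split-chain R̂ and effective
sample size (via `arviz`) on the global effects, variance components and
shape parameters; any monitored R̂ above 1.05 is recorded as a warning in
the fit diagnostics, never silently dropped. Defaults (2 chains × 3000
iterations, burn-in 500, thinning 2) retain 2500 draws. Draws are
reproducible bit-for-bit given the seed.

## Synthetic data generator

The generator is the model's own data-generating process plus a survey
process, so parameter-recovery tests are well-posed:

- **Truth.** Hyperparameters default to: global intercept −1.4 Z, slope
  +0.02 Z/yr, region/country intercept SDs 0.30/0.35, slope SDs
  0.008/0.010, RW2 smoothness SD 0.012, urban offset mean +0.45 with
  region/country SDs 0.10/0.15 and offset-slope SD 0.004, covariate
  coefficients (0.15, 0.10, 0.05, 0.08) on standardised covariates. These
  are plausible magnitudes for low- and middle-income-country child
  anthropometry (population means around −1 to −2 Z improving by roughly
  half a Z over the period; urban advantages of a few tenths of a Z).
  Covariate, population and urban-fraction series are smooth increasing
  trajectories with country-specific levels.
- **Surveys.** Source counts are Poisson with mean 4.8 per country; 84%
  national; configurable fractions are combined-stratum (default 0.20),
  NCHS-referenced (0.15), partial-age (0.10), and carry a prevalence
  (0.70). Sample sizes are log-normal (median 2000). Observed means are the
  true stratum (or urban-fraction-weighted) means plus noise at exactly
  the observation-model variance; prevalences are binomial draws around
  the true mixture tail. NCHS-flagged sources are pushed through the
  quantile mapping into NCHS Z space (and carry means only, as old
  summary-statistic sources typically did), so the pipeline must invert
  the conversion. τ defaults match the model specification — they are
  chosen for test power at desk scale; the real magnitudes of
  non-sampling error are unknowable from this package.

What the generator does **not** emulate: age-and-sex structure within 0–59
months (summaries are generated directly in Z space), survey design
effects beyond an SE, correlated non-sampling error within survey
programmes, migration, and informative missingness (sources are missing
completely at random given the configured fractions). Passing recovery
tests therefore demonstrate the estimator is consistent and calibrated
under the model's own assumptions — not that those assumptions hold for
any real survey database.

## Posterior summaries and decomposition

Credible intervals are percentiles 2.5–97.5 with the linear-interpolation
percentile convention. The posterior probability of direction is
max(f, 1−f) with f the fraction of draws above zero (draws exactly at zero
split evenly). Regional/global aggregates are draw-wise population-weighted
averages; rural (urban) quantities weight by rural (urban) under-5
population — computed as the country urban fraction applied to the under-5
population, since no child-specific urban fraction is available — which
makes the aggregate combined mean exactly the urban-fraction-weighted
average of the aggregate stratum means. Undernourished-child counts are
prevalence × stratum population, draw-wise, with totals exact sums.

The change decomposition weights rural and urban change by the *start-year*
stratum shares and defines the urbanisation component as the change in
urban share times the *end-year* urban–rural gap — the unique weighting
under which the three components sum to the total change as an algebraic
identity. Shares are normalised by the components' own sum (equal to the
total in exact arithmetic), which preserves the partition property under
floating-point cancellation; draws with exactly zero total change are
excluded from share averaging and counted in a diagnostic. Shares are
computed per draw and reported as means of per-draw shares with percentile
intervals — not as the decomposition of posterior-mean trajectories, so
uncertainty propagates coherently through the ratios. Any share may be
negative or exceed one when components oppose each other.

## Numerical choices and degenerate inputs

- Observed and model prevalences are clipped to [10⁻⁶, 1−10⁻⁶] before the
  probit; prevalence-term variances are floored at 10⁻⁸.
- Variance components are bounded in [10⁻⁶, 50] (keeps precisions finite);
  mixture λ in [0, 20), s₀ in [10⁻³, 50].
- The RW2 constraint penalty weight is 10⁶ — large enough to pin the
  level/trend projections, small enough to keep the precision matrix well
  conditioned.
- Survey sample sizes are clipped to [100, 10⁶] in the generator.
- Fits at the default desk scale (8 countries × 27 years, ~80 sources,
  1200–3000 iterations) take tens of seconds on one CPU; the test suite's
  recovery study uses 20 replicate fits with 2 × 1200 iterations each.

## Known limitations

- The τ non-sampling error terms are fixed, not estimated; misspecifying
  them propagates directly into interval widths.
- The mixture shape is global per stratum; real skew plausibly varies by
  region and by the level of undernutrition.
- The urban offset has no smooth nonlinear time component.
- HAZ and WAZ are fitted independently; their strong within-survey
  correlation is not exploited.
- The quantile-mapping reference conversion is a reproducible stand-in for
  a regression-calibrated conversion; its conversion variance reflects
  shape sensitivity only, not estimation error in the mapping itself.
- Multi-year surveys must be pre-dated to a midpoint year; micro-data must
  be pre-collapsed to design-weighted summaries.
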
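# anthrotrend

Estimation of rural and urban trends in children's height-for-age (HAZ) and
weight-for-age (WAZ) Z scores across countries and years, from sparse and
heterogeneous survey *summary statistics*, with a Bayesian hierarchical
normal-mixture model.

## Who this is for

Population-health analysts who need country-year estimates of child growth
status stratified by place of residence when the evidence base is a few
survey summaries per country — some national, some subnational, some
reporting rural and urban children separately, some combined, and some
expressed against the older NCHS 1977 reference instead of the WHO 2006
growth standards.

## The model

For country *c*, year *t* and stratum *s* ∈ {rural, urban}, the population
distribution of Z scores is a five-component normal mixture with a globally
shared shape (left-skew pattern λ, component SD scale s₀, one pair per
stratum) anchored at the stratum mean

```
mu_rural(c,t) = a_c + b_c·t̃ + u_{c,t} + x_{c,t}'γ
mu_urban(c,t) = mu_rural(c,t) + d_c + e_c·t̃
```

where t̃ is the year centred at 1998, u_c is a smooth second-order
random-walk deviation, x are standardised covariates (maternal education,
log per-person GDP, urban proportion, health-care access), and the
intercepts a_c, slopes b_c and urban offsets (d_c, e_c) have nested
global → region → country Gaussian hierarchies. Survey means are observed
with variance se² + τ²(national) [+ τ²(subnational)] [+ τ²(partial ages)]
[+ NCHS-conversion variance]; prevalences below Z = −2 (stunting for HAZ,
underweight for WAZ) enter on the probit scale with delta-method variance.
Posterior draws (default 2500 after burn-in and thinning) come from a
blocked MCMC; credible intervals are percentiles 2.5–97.5 of the draws.

Downstream, the package computes prevalence and undernourished-child counts
by stratum, population-weighted regional and global aggregates, posterior
probabilities of direction for changes in the urban–rural differential, and
the exact additive decomposition of a change in population mean Z into
rural-change, urban-change and urbanisation components

```
Δ = p₀·(zu₁−zu₀) + (1−p₀)·(zr₁−zr₀) + (p₁−p₀)·(zu₁−zr₁)
```

whose normalised shares sum to one.

Because individual-country survey databases are not redistributable, the
package ships a first-class synthetic-data generator
(`anthrotrend.synthetic_data`) reproducing the statistical structure the
model assumes — on average 4.8 sources per country, 84% nationally
representative, mixed stratum reporting and mixed reference populations —
so the full pipeline is testable end to end. The packaged LMS reference
tables are synthetic approximations of the WHO 2006 and NCHS 1977
references built from public growth-chart anchor values; real LMS tables
with the same CSV schema are drop-in replacements.

## Worked example

```
cat > pipeline.yaml <<'YAML'
seed: 7
metrics: [haz]
simulation: {n_regions: 2, countries_per_region: 4}
mcmc: {chains: 2, iterations: 1500, burnin: 400, thin: 2}
decomposition: {start: 1985, end: 2011}
YAML
anthrotrend --quiet run --config pipeline.yaml --out-dir out/
```

The run simulates eight countries in two regions, fits the model, and
writes `estimates_haz.csv`, `decomposition_haz.csv`, the saved fit,
diagnostics and a manifest. Selected global rows of the estimates file:

```
 year stratum  mean  mean_lo  mean_hi  prev
 1985   rural -1.80    -1.92    -1.68  0.42
 2011   rural -0.84    -0.97    -0.71  0.15
 1985   urban -1.43    -1.56    -1.30  0.30
 2011   urban -0.44    -0.55    -0.32  0.08
```

Rural children start about 0.4 Z below urban children and both improve by
roughly one Z score over 1985–2011; stunting prevalence falls from 42% to
15% in rural areas. The global decomposition of that mean-Z change:

```
   component  share_mean  share_lo  share_hi
       rural        0.61      0.58      0.64
       urban        0.33      0.31      0.35
urbanisation        0.06      0.05      0.08
```

i.e. about 61% of the improvement is attributable to rural children, 33%
to urban children and 6% to urbanisation, with 95% credible intervals from
the posterior draws.

Other subcommands: `anthrotrend simulate`, `zscore`, `fit`, `summarize`,
`decompose` (see `--help` for each). For instance

```
anthrotrend zscore --metric height --sex male --age 24 --value 87.1
# 0.0000  (87.1 cm is the reference median at 24 months)
```

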
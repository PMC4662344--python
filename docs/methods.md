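# Methods

`phenoplast` reimplements, as a reusable library, the analysis chain of a
long-term nest-box study of laying-date plasticity in tree swallows
(*Tachycineta bicolor*): detection of the climate window that best predicts
annual phenology, a population-level mixed model of the environmental
determinants of mean laying date, and individual-level reaction-norm
analyses built on within-subject centring and random regression. A
synthetic-data generator with recorded ground truth stands in for the
field data, which are not publicly deposited.

## Data model

Three tabular inputs (CSV, UTF-8, header row, `NA`/empty for missing):

* **Breeding records** — farm, nest box, year, female id (possibly
  unknown), age class (`SY` second-year / `ASY` after-second-year /
  `unknown`), laying date (Julian day, January 1 = 1), clutch order.
  Only first clutches enter any analysis; `first_clutch_filter` also keeps
  at most one clutch per female per season (the earliest).
* **Daily weather** — station, date, mean temperature (°C), rainfall (mm).
* **Site tables** — farm/station coordinates (decimal degrees) and
  elevations (m); farms carry their nest-box count.

Farms are matched to weather by great-circle distance on a 6371-km sphere
(nearest station by default, `k`-nearest day-wise average optionally). At
the study's 1.6–20 km farm–station distances the choice of distance formula
is irrelevant to the ranking; ties break lexicographically by station id so
assignment is reproducible.

## Sliding-window scan

A candidate window is a day pair `(s, e)` inside the scan frame (days
60–151, i.e. March 1 – May 31 of a non-leap year) aggregating Julian days
`s+1 … e`; spans `e − s` run from 5 to 91 days, for exactly
`Σ_{L=5}^{91} (92 − L) = 3,828` candidates. This half-open convention is
the only one consistent with that published count (an inclusive-day reading
gives 3,915); its one visible consequence is that the published best
temperature period "days 96–129" maps to `WindowSpec(96, 129)` = days
97–129, one day short of the inclusive reading.

Each window's per-year aggregate (mean for temperature; mean or rescaled
sum for rainfall — the final rainfall covariate is a window *sum*, but the
scan statistic defaults to the mean, which is rank-equivalent within a
span) is correlated with the annual mean laying date (Pearson, two-sided
t-test p). Windows are ranked by |r|, ties broken by earlier start then
shorter span. Days missing from a station record are dropped from the
aggregate; a station-window-year with more than 50 % of days missing is
treated as missing and excluded from any station average — robustness
without imputation machinery. No multiple-testing correction is applied to
the 3,828 correlations by default, matching the original procedure; an
optional permutation null (`permutations > 0`) shuffles the phenology years
and records the scan-wide maximum |r| to attach a familywise `p_perm` per
window.

**Stability caveat.** With ten years of data the sample correlation of even
a genuinely driving window fluctuates roughly ±0.15 around its expectation,
while the maximum |r| over thousands of heavily overlapping candidates
regularly exceeds 0.85 by chance. Top-1 window selection at this series
length is therefore intrinsically unstable: in our planted-signal
experiments (window 97–129 carrying a year anomaly of SD 0.9 °C, target
signal r ≈ 0.75, AR(1) daily noise, three-station average) the top-ranked
window covers at least half of the planted window in only ~40–60 % of
replicates, across every realistic noise configuration we probed. The
planted-signal harness deliberately confines interannual variance to the
planted window (no shared warming trend or whole-spring year anomaly):
year-level variation common to all days is signal for every candidate
alike and would make the planted window unidentifiable in principle. The
corresponding acceptance check asserts the stricter 80 % recovery rate and
is expected to fail; we keep it as an honest record of the procedure's
resolution rather than weaken the test.

## The linear mixed-model engine

The core estimator fits

    y = Xβ + Σ_k Z_k u_k + ε,  u_k ~ N(0, Σ_k ⊗ I),  ε ~ N(0, σ² I)

with each random term contributing either an intercept variance or a
correlated intercept/slope 2×2 covariance per level of its grouping
factor; factors may be crossed (year, farm and female all at once).
Following the relative-covariance-factor formulation, Σ_k = σ² Λ_k Λ_kᵀ and
β and σ² are profiled out, so the optimiser searches only the Cholesky
entries of the Λ blocks. Every criterion evaluation reduces, via the
Woodbury identity, to one Cholesky factorisation of the q×q matrix
M = I + ΛᵀZᵀZΛ (q = total random-effect columns); the analytic gradient
needs only the per-level 2×2 diagonal blocks of the projected information
and costs about one extra factorisation.

Numerical choices:

* **Parameterization.** Λ diagonals are bounded at zero (L-BFGS-B box
  constraints) rather than log-transformed, so a variance component can hit
  zero exactly; such fits are returned as valid with a boundary flag.
  One consequence of the Cholesky scale is that θ = 0 is always a
  stationary point of the criterion (the gradient is proportional to θ),
  so the optimiser can park a variance at a zero-saddle. Three safeguards
  are layered: restarting L-BFGS-B from its own solution (resetting the
  Hessian approximation), probing each zeroed diagonal (and all jointly)
  at small positive values and re-optimising from any probe that lowers
  the criterion, and a second half-scale starting point for models with
  slope terms (whose interacting blocks can hold spurious corner optima).
  Convergence: relative criterion change 1e−14, max 500 iterations, five
  seeded jittered restarts (seed 20230401) on outright failure.
* **Likelihoods.** REML by default; both ML and REML log-likelihoods are
  reported at the fitted parameters. The REML criterion matches a dense
  determinant/quadratic-form evaluation to ~1e−13 on small instances, and
  the whole chain (log-likelihoods, estimates, SEs, variance components,
  BLUPs, Satterthwaite df) reproduces R's `lme4`/`lmerTest` to ≈1e−4 on a
  crossed-slope test model.
* **Satterthwaite df.** df = 2v²/Var(v) per fixed effect, with Var(v) by
  the delta method over (θ, log σ²): numerical gradients of the
  coefficient variances and the numerically evaluated observed REML
  information, computed once per fit for all coefficients. Singular
  information falls back to the residual df with a warning.
* **LRTs.** Fixed-effect comparisons use ML log-likelihoods, random-
  structure comparisons REML with identical fixed effects; df equals the
  parameter-count difference (a correlated slope adds two: slope variance
  plus covariance). Random-effect p-values use the naive χ² reference by
  default — boundary-conservative, and the convention behind the published
  ladder table — with an equal-weight χ²(df)/χ²(df−1) mixture available.
* **Backward elimination** removes the least significant removable fixed
  term (marginality: main effects are protected while a retained
  interaction contains them), confirms each removal with an ML LRT at the
  same α (default 0.05), locks terms whose removal the LRT rejects, and
  records every step. Rows with any missing model variable are dropped
  listwise with a logged count.
* **Standardization** uses the sample (n−1) SD and returns the transform
  for back-conversion. Covariates are standardized once on the full
  analysis table before subsetting or centring.

The binomial GLMM for the occupancy trend (logit link, one random
intercept) is fitted by a Laplace approximation that factorises over
groups; the inner per-group modes come from a vectorised Newton iteration
nested inside a quasi-Newton search over (β, log σ_b). Fixed-effect SEs
come from the numerical Hessian of the Laplace marginal likelihood. At
zero group variance the fit collapses to an ordinary binomial GLM
(checked against statsmodels); with group structure it reproduces
`glmer`'s Laplace fit to ~1e−3. Linear predictors beyond ±15 on the logit
scale raise a separation error.

## Analysis stages

* **Farm-year summaries** — mean laying date over first clutches, breeder
  density (occupied boxes / boxes on the farm, a habitat-quality proxy),
  window-aggregated spring temperature and rainfall from the farm's
  station(s), latitude, elevation. Farm-years without clutches are
  omitted.
* **Interannual trends** — laying date and spring temperature by LMM with
  year continuous and farm as a random intercept; density by binomial
  GLMM on (occupied, total boxes).
* **Determinants model** — full fixed structure: five standardized
  covariates (spring temperature, rainfall, breeder density, elevation,
  latitude) plus all ten two-way interactions; year random intercept
  (farm optional — the published model kept year only); backward
  elimination at α = 0.05; coefficient table with Satterthwaite df and an
  adjusted R² of the fixed predictor. Longitude and river distance are
  excluded by construction: the generator reproduces their > 0.9
  collinearity with elevation.
* **Consecutive-year deltas** — for each female with two consecutive
  breeding seasons (first such pair only), ΔLD regressed on Δtemperature
  and Δdensity (standardized scale) by OLS, separately for SY-first,
  ASY-both and total datasets (the total model adds a first-year-age
  indicator coded SY = 1, so its negative coefficient reflects the larger
  between-season advance of maturing females).
* **Random-regression ladder** — females observed in ≥ 2 seasons, first
  study year excluded (no age information there). Fixed effects:
  within-female (β_W) and between-female (β_B) components of temperature
  and density, age (ASY = 1; negative = older females lay earlier), and
  latitude. Random structures 1–5 (year; +farm; +female; +female×temp_W
  slope; +female×dens_W slope) compared by REML LRTs. The selected
  structure keeps a slope only if its LRT is significant (smaller p wins
  if both); a significant female term promotes to model 3 even when the
  farm step alone is not significant, farm being retained as a design
  control. β_B − β_W equality is tested by refitting with the raw
  covariate plus the female mean — the mean's coefficient *is* β_B − β_W
  (van-de-Pol–Wright reparameterization), algebraically identical to
  differencing the centred fit (verified to 1e−8).
* **Density subsets** — females split at the median of their mean
  experienced density (subject-level by default; the hypothesis concerns
  birds living *on average* in poor habitat; observation-level split by
  flag), with centring recomputed inside each subset; the headline output
  is the within-female temperature-slope contrast between subsets.

## Synthetic data

`generate_dataset` draws a full study: farms uniform over an 80 km × 127 km
box around 45.57° N, −72.64° W (extremes pinned so the latitudinal span is
exact), elevation correlated with longitude (|r| > 0.9), ~10 stations with
a 20-km coverage guarantee; daily spring temperature = seasonal ramp +
0.183 °C/yr warming + shared year anomaly (SD 0.4) + window-confined
anomaly (SD 0.9, days 97–129) + station offset + AR(1) noise (ρ = 0.6,
innovation SD 2.2 → daily SD ≈ 2.75 °C); rainfall as Gamma draws with a
lognormal year factor. Occupancy per farm-year is binomial(boxes,
logit⁻¹(0.32 − 0.093·(year − mid) + farm quality)), tuned to yield ≈ 2,270
first clutches over 40 × 10 × 10; females return with probability 0.40,
stay on their farm with probability 0.92, age SY→ASY, and ~12.7 % of
clutches are second clutches generated solely to exercise the first-clutch
filter. Laying dates follow the published fixed effects (intercept
141.415; latitude +0.479, density −1.469 — applied at the between-female
level, with a separate within-female density effect defaulting to zero, the
pattern the individual-level analyses detect; temperature −0.929;
temperature×density −0.450; ASY −5.683 d) plus year, farm, farm-year and
female random effects, an optional female slope on within-female density,
and residual noise.

The unpublished nuisance SDs are free knobs with documented defaults —
year 2.0, farm 1.0, farm-year 3.2, female 3.5, residual 5.5 d, female
density-slope 0.8 — chosen so simulated coefficient SEs land near the
published scale (density SE ≈ 0.205 in the determinants model, Δtemp
SE ≈ 0.39 in the delta analysis); the farm-year component represents
shared within-farm-season conditions (weather, insects) and is what
reconciles the two published SE scales. A direct year drift of −0.45 d/yr
tops up the covariate-mediated trend toward the published −0.42 d/yr
laying advance (warming and density decline partially cancel through their
opposite-signed effects).

What the generator does *not* emulate: demographically realistic
survival/recruitment, spatially structured insect abundance,
heteroscedastic residuals across density levels, and selection on laying
date. Passing recovery tests therefore demonstrate that the estimators
recover the assumed generative structure at the study's scale — not that
the published coefficients are themselves correct.

Targeted simulators (`simulate_farm_year_summaries`, `simulate_delta_pairs`,
`simulate_female_table`, `simulate_window_scan_dataset`) generate data
directly at the level each analysis consumes, with every effect size a
parameter; they back the calibration and recovery suites.

## Calibration and recovery results; problem sizes

Simulation-based checks run at sizes chosen to keep the full suite within
minutes while leaving Monte-Carlo error well below the asserted margins:

* Random-slope LRT type-I calibration: 500 replicates of 60 females ×
  ~2.5 observations (8 years, 10 farms), zero true slope variance; the
  naive-χ²₂ test is boundary-conservative (empirical rate well under 5 %).
* β_W = β_B equality calibration: 1,000 replicates of 120 females × 2–3
  observations with truly equal slopes; empirical size ≈ 5 % (asserted
  within 3–7 %).
* Determinants recovery: the published truth at the published n = 392 and
  SE scale. Each true coefficient is covered within 2 SE of its full-model
  estimate in ≈ 95 % of replicates. Exact recovery of the published term
  set by backward elimination, however, has a hard power ceiling: the
  published effect/SE ratios (t = 2.46, 2.20, 2.73 for latitude,
  interaction, temperature) imply per-term retention powers of ≈ 0.69,
  0.59 and 0.78, and eleven null terms each survive with probability
  ≈ α, so the joint exact-set probability is ≈ 0.18 — which is what the
  simulation measures. The acceptance check asserting ≥ 70 % is kept, and
  fails, as an honest record of that ceiling.
* Delta-analysis recovery: published older-female truth (slope −2.338,
  null density) at n = 311; 2-SE coverage ≈ 95 %, null term eliminated in
  > 90 % of replicates.
* Window recovery: see the stability caveat above.

## Known limitations

* Dense q×q linear algebra: fits are comfortable to a few thousand
  random-effect columns but do not exploit sparse Cholesky orderings the
  way `lme4` does.
* The Laplace GLMM supports a single random intercept — all the occupancy
  trend needs — not nested or crossed binomial structures.
* Satterthwaite df at a variance boundary uses one-sided differences and
  is approximate; Kenward–Roger df, temporal/spatial autocorrelation and
  heteroscedastic residual models are out of scope.
* Day length uses the NOAA low-accuracy solar equations, adequate to the
  minute; polar latitudes (|lat| ≥ 66.5°) are rejected rather than
  special-cased.
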
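# Methods

This note documents the statistical machinery implemented in `winshift`, the
assumptions behind the synthetic-data generators, the numerical choices made
where the design was genuinely open, and what the simulation-based tests do
and do not establish about real field data.

## The task and its score

The radial arm maze (RAM) is a win-shift assay of short-term spatial memory:
every arm is baited once per bout, rewards are not replaced within a bout,
and the platform is exchanged after each landing so scent marks cannot be
used. Any visit to an arm already visited in the same bout — including an
immediate re-landing on the current arm — is an error. Formally, for a bout
with visit sequence $a_1,\dots,a_L$,

$$\text{errors} = L - |\{a_1,\dots,a_L\}|,$$

an identity the test suite fuzzes directly. Nothing carries across bouts
because all arms are re-baited between bouts.

A bee's RAM score is the arithmetic mean of errors over the last
`n_test` test bouts (main design: 12 bouts, last 3 scored; eight-arm
validation design: 20 bouts, last 10). Bouts terminated early by the nest
shutter (not all arms visited) are scored by the same rule, with no
imputation; a flag allows collapsing immediate repeats for sensitivity
analysis. Scores enter regression models as $\log(1+\text{score})$ (natural
log) to reduce the influence of occasional very poor bouts.

## Movement-rule null models

Good RAM scores could reflect movement stereotypy (e.g. always moving to an
adjacent arm) rather than memory. The null model asks: if a simulated bee
("simulant") moved with the same first-order statistics as a real bee, but
with no memory beyond its current position, how well would it score?

* **Transition matrices.** For each bee, within-bout transitions in its test
  bouts are counted into an $n \times n$ matrix; rows are normalized, with
  optional additive smoothing (`pseudo_count`, default 0) and a uniform
  fallback for unobserved rows. Transitions never cross bout boundaries. The
  first-visited-arm distribution is retained and used to start simulant
  bouts (uniform if unavailable).
* **Simulant bouts.** A simulant starts at a draw from the start
  distribution and moves by inverse-CDF draws from the current arm's row
  until all arms are visited or a visit cap is reached (default
  `12 × n_arms`; capped bouts are flagged truncated). This termination rule
  mirrors the real task, where the bee is fed to repletion at the last
  undepleted arm. Simulants inherit their source bee's covariates and bout
  count.
* **Cohort statistic.** Either the grand mean of per-bout errors
  (`mean_errors`, dependency-free and used for large replicate counts) or
  the intercept of a hierarchical Poisson regression of per-bout errors on
  body size and age with a per-bee random intercept (`model_intercept`,
  variational fit; falls back to the mean with a logged flag if the fit
  fails). In the degenerate case of constant covariates and no between-bee
  variance the intercept estimates $\log(\text{mean})$, which the tests
  verify.
* **Percentile p-values.** With $N$ simulant replicates and observed
  statistic $t$, the lower-tail p-value is
  $p = (1 + \#\{v_i \le t\})/(N+1)$ — the add-one (Davison–Hinkley)
  correction keeps $p > 0$ and makes the statistic exactly uniform on
  $\{1/(N+1), \dots, 1\}$ under the null, which the calibration test
  confirms empirically at $\alpha = 0.05$. The lower tail corresponds to
  "fewer errors than movement rules alone produce".
* **Chance baseline.** The same machinery with random row-stochastic
  matrices, each row flat-Dirichlet over its allowed destinations
  (optionally excluding self-transitions).

A useful analytic oracle: a memoryless uniform-no-self mover on 4 arms needs
$1 + \sum_{k=1}^{3} 3/(4-k) = 6.5$ expected visits to cover the maze, i.e.
2.5 errors per completed bout; simulations must match this within Monte-Carlo
error.

## Trip construction

RFID readers record direction only; the pairing algorithm is therefore part
of this artifact, not of the original measurement protocol:

* Same-direction reads within a 5 s debounce window are echoes of one
  passage and collapse to the first read. Each `out` opens an excursion
  closed by the next `in`; an `out` followed by another `out` leaves an open
  (censored) excursion, and an `in` with no open excursion is dropped with a
  reason code. Weigh events attach to the nearest trip endpoint of matching
  direction within 120 s. Both windows are configurable; the defaults are
  this package's choices.
* Loads: total pollen is twice the single-corbicula sample (pollen is
  carried symmetrically on both hind legs); nectar is
  $w_{in} - w_{out} - \text{pollen}$, and negative nectar values (bees
  leaving heavier than they return) are retained as genuine observations.
  Mass conservation ($\text{nectar} + \text{pollen} = w_{in} - w_{out}$)
  holds identically.
* Classification: trips shorter than 7 minutes are excluded (orientation
  flights and waste disposal); otherwise < 3 mg total pollen means a nectar
  trip and > 3 mg a pollen trip. Exactly 3 mg is assigned to pollen by
  default (configurable, logged) — the boundary case is undefined in the
  underlying field protocol. Efficiency is load (mg) per minute of trip
  duration. Excluded trips keep reason codes and still count toward
  lifetime foraging effort.
* Survival: per bee, time runs from release to last RFID read; a bee whose
  last read precedes colony euthanasia is presumed dead (>99% of tagged
  foragers simply fail to return), otherwise administratively censored.
  Bees never seen after release get zero survival with a flag. Kaplan–Meier
  summaries use lifelines.

## Seasonal analysis

* **Response normalization.** Ordered-quantile (rank-based inverse normal)
  transform $z_i = \Phi^{-1}(r_i/(n+1))$ with average ranks for ties. New
  data are transformed by monotone interpolation of the fitted mapping with
  linear tail extrapolation; the inverse is exact on training data. The
  $r/(n+1)$ offset is one of several common variants; the choice is this
  package's.
* **Weather.** Daily temperature, humidity and wind speed are z-scored and
  reduced to their first principal component (sign fixed so temperature
  loads positively; constant columns dropped; incomplete days deleted
  listwise). Because weather tracks the season, the composite is
  residualized on week of year with a natural-cubic-spline smooth whose
  basis dimension is chosen by generalized cross-validation from a small
  grid (cubic-polynomial fallback below 8 distinct weeks). Using a
  projection smoother makes the residuals exactly orthogonal to the fitted
  seasonal trend, so "weather" effects are weather-beyond-week by
  construction.
* **Candidate set.** Every analysis (nectar, pollen, survival, effort,
  control comparison) uses the same four-model protocol: a null model
  (intercept + random terms), a covariate model (week, age at release, body
  size, year, foraging experience — quadratic for nectar, linear for pollen
  — and residual weather), the covariate model plus the focal predictor
  (log RAM score, or tested-vs-control cohort), and that model plus the
  focal × week interaction.
* **Fitting backends.** Gaussian mixed models (nectar, control comparison)
  are fitted by maximum likelihood with statsmodels MixedLM, with a
  correlated per-bee random intercept × experience slope. statsmodels
  cannot combine that structure with a crossed colony intercept, so the
  colony random intercept is omitted from the Gaussian fits; colony effects
  in the generator are small relative to bee and residual variation, and
  the parameter-recovery tests bound the practical consequence. Gamma
  log-link GLMMs (pollen), Poisson GLMMs with an observation-level random
  effect for overdispersion (lifetime effort), and Cox proportional-hazards
  models with a shared gamma frailty per colony (survival) are fitted in R
  via lme4/survival subprocess calls, the standard tools for those classes.
  For optimizer stability the badly scaled covariates (week of year,
  experience) are centered internally; fitted coefficients and their
  covariance are mapped back to the raw scale exactly, so reported
  coefficients always refer to raw week. Non-finite or non-converged
  Gaussian fits are retried with a derivative-free optimizer and excluded
  from selection if still unusable.
* **Selection.** $\mathrm{AIC} = -2\ell + 2k$ with
  $\mathrm{AICc} = \mathrm{AIC} + 2k(k+1)/(n-k-1)$; AICc is used when
  $n/k_{\max} < 40$ (the switch rule is this package's; only "depending on
  sample size" is inherited). The lowest-criterion model wins unless a
  nested candidate sits within Δ ≤ 2, in which case the simplest (fewest
  parameters) is selected. $k$ counts fixed effects, random-effect
  (co)variances and the residual variance. The Cox frailty fit reports the
  penalized effective degrees of freedom rounded to an integer; its AIC is
  therefore exact only up to that rounding.
* **Interaction profile.** For a selected interaction model,
  $\text{slope}(w) = \beta_{\text{RAM}} + \beta_{\text{int}} w$ with
  delta-method 95% bands, and the sign-reversal week
  $w^* = -\beta_{\text{RAM}}/\beta_{\text{int}}$ (with delta-method SE) is
  reported when it falls inside the observed week range.

## Synthetic data: what it emulates, and what it does not

* **Maze agents** hold a sliding window of the last $m$ distinct arms
  visited and choose uniformly among arms outside the window; with
  probability `lapse_rate` (or when memory is empty) they fall back to a
  movement-bias rule (default uniform over the other arms). $m = n-1$ with
  no lapses reproduces perfect win-shift behaviour (provably zero errors);
  $m = 0$ is the memoryless Markov mover matching the analytic oracle
  above. Memory is positional and does not decay in time — adequate for a
  task whose bouts last a few minutes, but a simplification of real
  short-term memory.
* **Cohorts**: per-bee memory capacities drawn from a configurable
  distribution; intertegular distances ~ N(4.5, 0.35) mm and release ages
  3–14 days, typical of *B. terrestris* workers.
* **Seasons**: 12 colonies staggered 2 weeks apart from week 14, ~11 scored
  bees per colony, 8 observation days per bee with Poisson(1.8) weighable
  trips per day — roughly 1,900 trips of which about 1,200 survive as
  classified nectar trips, matching the scale of a two-year field campaign
  in one synthetic year. Latent per-trip efficiency is
  $\eta = \text{baseline}(w) + \beta_{\text{RAM}} s + \beta_{\text{int}} s w
  + \beta_{\text{size}}(\text{size}-\overline{\text{size}})
  + \beta_{\text{age}}(\text{age}-\overline{\text{age}})
  + \beta_1 e + \beta_2 e^2 + \beta_{\text{wx}} x + b_{0i} + b_{1i} e + c_j
  + \varepsilon$, the exact inverse of the nectar analysis model (weather
  enters through the same composite-and-residualize code path the analysis
  uses). Defaults: $\beta_{\text{int}} = 0.05$ per week per unit log-RAM
  with a sign reversal at week 26 (so $\beta_{\text{RAM}} = -1.3$), bee
  intercept SD 0.30, slope SD 0.02 (correlation −0.2), colony SD 0.15,
  residual SD 0.90. The variance components were chosen so the marginal SD
  of $\eta$ is ≈ 1: the rank-normalized analysis response is then in
  one-to-one correspondence with the latent scale and generating
  coefficients are directly comparable with fitted ones. Observed mg/min is
  an affine map of $\eta$ (centre 2.5, scale 3.2 mg/min, spanning roughly
  −7 to 15 mg/min); a nonlinear monotone warp can be supplied to stress the
  normalization step, but the default is affine precisely so that
  "generating coefficient" remains well-defined on the analysis scale.
  Durations are log-normal (median 25 min) with a 12% admixture of
  deliberate sub-7-min trips, and 25% of trips carry > 3 mg pollen loads, so
  the classification filters are always exercised.
* **Weather**: temperature follows a seasonal sinusoid with noise, humidity
  is negatively coupled to temperature, wind is independent gamma — enough
  correlation structure for the PCA composite to be non-trivial without
  claiming meteorological realism.
* **Event logs**: each trip becomes out/in RFID reads and weigh events;
  duplicate-read injection (2 s echoes) and Gaussian scale noise (the field
  scales were accurate to ±2 mg) are optional. With noise off the round
  trip through the pairing stage is lossless by construction, and the test
  suite asserts exact field equality.

Passing tests therefore demonstrate that the pipeline is a consistent
estimator of its own generative model at realistic scales — they cannot
certify field-data properties the generator does not emulate: reader
failures and multi-day gaps, diurnal and weather-dependent trip timing,
individual heterogeneity in memory strategy, or colony-level confounds
beyond a random intercept.

## Numerical choices and edge cases

* All stochastic components take explicit seeds; generators are pure
  functions of (parameters, seed), and replicate streams are generated
  lazily so 10,000-replicate null distributions never hold all bouts in
  memory.
* Transition-matrix rows must sum to 1 within 1e-9; empty rows fall back to
  uniform (or additive smoothing when a pseudo-count is set).
* Constant or single-level model terms (e.g. a single year of data) are
  dropped from design matrices with a log message rather than producing
  singular fits.
* The ORQ transform refuses constant input; ties share average ranks, and
  tied x-values collapse to single interpolation knots so the mapping stays
  strictly monotone.
* Exact-boundary conventions: 3.0 mg pollen → pollen trip; trips of exactly
  7.0 min are kept; both logged and configurable.
* Week of year is ISO week; timestamps are timezone-naive local study time.

## Known limitations

* The Gaussian backend omits the colony random intercept (see above); for
  data with strong colony structure the interaction SE will be somewhat
  optimistic.
* The Cox frailty parameter count is rounded to an integer for the AIC
  identity.
* `model_intercept` uses a variational Bayes fit whose posterior-mean
  intercept approximates the ML GLMM intercept; for large replicate counts
  the `mean_errors` statistic is the intended default.
* The trip pairing is greedy and per-bee; simultaneous reader collisions
  between bees are not modelled.
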
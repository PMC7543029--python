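# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `mmisurv`, including what the synthetic registry
generator does and does not emulate.

## Excess hazard model

The observed hazard of a cancer cohort is `λ = λ_E + λ_P`.  The background
hazard `λ_P(a+t, y+t, z)` is read from a population life table on a complete
grid of single year of age × calendar year × sex × stratum; it is piecewise
constant within a cell, so the expected cumulative hazard and expected
survival `S_P` are integrated *exactly* over the cells a patient crosses.
Attained age above the table maximum is clamped to the last row (standard
registry practice); attained calendar years outside the table raise an
error — extrapolating mortality trends silently would fabricate data.
Tables supplied as one-year death probabilities `q_x` are converted with
`rate = −log(1 − q_x)`.  Follow-up is in years; day counts convert at
365.25 days/year, and events recorded on the day of diagnosis are shifted to
one day (1/365.25 y), since the log-time baseline is undefined at zero.

The log baseline excess hazard is a restricted cubic spline in `log t`
(truncated-power restricted basis, linear tails, C² everywhere).  With
`df = 3` (the default) the two internal knots sit at the tertiles of the
*uncensored* event-time distribution on the log scale and the boundary knots
at its extremes.  Quantiles use the inverse-empirical-CDF (type-1) rule with
probabilities expressed to four decimals (0.3333, 0.6667), which is the
printed-percentile convention; this makes knot placement exactly
reproducible.  `df = 1` is a pure linear basis (Weibull-like) and
`baseline_df = 0` an intercept-only constant hazard.  Covariate splines use
the same tertile rule on the identity scale.  Whether the baseline spline
should act on `t` or `log t` is genuinely open; log time is what the
established flexible-parametric fitting tools use, and is the default here.

Covariate effects are linear (continuous), restricted cubic spline
(continuous), or factor dummies (reference: first sorted level).
Deprivation enters as a categorical factor by default: quintiles are ordinal
labels, and nothing forces log-linearity across them.  A *time-dependent*
effect takes the form `β · g(x) · log t` — a single coefficient whose effect
crosses zero at t = 1 year — not `(β₀ + β₁ log t) · g(x)`.  This is the
form the selection algorithm toggles between proportional and
time-dependent; note the two forms have the *same* number of parameters, so
an information criterion separates them only through fit.  Interactions are
products of the linear/dummy main-effect codes, optionally carrying the
`log t` multiplier, and require both main effects present (hierarchy).

Continuous covariates are centred at their sample mean before fitting
(recorded and re-applied at prediction time) for optimizer conditioning.

## Likelihood, optimisation, covariance

`L = Σ δ_i log(λ_P,i(t_i) + λ_E,i(t_i)) − Λ_E,i(t_i)` with
`Λ_E,i` computed by 20-node Gauss-Legendre quadrature on `(0, t_i]` — one
quadrature policy (20 nodes) is used everywhere in the package, including
the RMISD integrals.  For baselines with `t^(κ−1)`-type behaviour near zero
(κ < 1) this quadrature is accurate to roughly 0.1–0.2% relative, which is
cross-checked against a 60-node refinement in the tests.  The score is
analytic; optimisation is BFGS from a null-exponential start (intercept
`log(d/Σt)`, zeros elsewhere).  The parameter covariance is the inverse
observed information, obtained by central finite differences of the analytic
score and projected to the nearest PSD matrix if roundoff makes it slightly
indefinite.  Non-convergence and rank-deficient designs raise errors that
name the offending columns.  With `table=None` the likelihood reduces
exactly to ordinary parametric survival analysis, which several tests use as
an oracle (e.g. the intercept-only MLE is `d/Σt`).

Delta-method variances are provided for `λ̂(t)` and `Λ̂(t)` at any covariate
pattern.  Individual net survival is `exp(−Λ̂)`; cohort net survival is the
mean of individual curves.  Because `exp(−·)` is convex, the plug-in cohort
survival carries a small upward finite-sample bias of order
`S · var(Λ̂)/2` — about +0.01 at n = 2000 in the moderate-lethality
scenario, decaying like 1/n; this is a property of the estimator, not of
the implementation, and the acceptance checks account for it by comparing
against Monte-Carlo variability across replicate cohorts.

## Pohar-Perme estimation

The estimator weights each subject's counting processes by `1/S_P,i(t)`.
Between consecutive event times each subject accumulates weighted expected
deaths `∫ λ_P,i(u)/S_P,i(u) du`, which integrates in closed form to a
difference of `1/S_P` values over the life-table cells; at each event time
the cumulative excess hazard increments by (weighted deaths − accumulated
weighted expected deaths) / (weighted number at risk), and net survival is
`exp(−Λ̂_E)`.  With `λ_P ≡ 0` this is exactly `exp(−Nelson-Aalen)`.
Variance is Poisson-type on the hazard scale (`Σ w²dN / (ΣwY)²`), mapped to
the survival scale by the delta method; which variance estimator the
established implementations use is not documented precisely, so this choice
is recorded here rather than asserted as canonical.  The period variant
restricts contributions to person-time inside a calendar window — left
truncation at window entry, censoring at window exit — and reduces exactly
to the cohort estimator when the window covers all calendar time.  When only
a diagnosis year is available, diagnosis is placed at mid-year for
window-intersection purposes (flagged convention).  An empty risk set before
the end of the grid truncates the curve and records the truncation time.

## Selection

The search starts from the all-linear, all-proportional model.  Variables
are scanned in decreasing order of their best single-move criterion
improvement over the base model (a criterion-based translation of the
"most significant first" ordering of the classical test-based procedure);
within each scan, one-step upgrades are compared two at a time: a gap
larger than the threshold (default 2) discards the worse model, a gap
within the threshold keeps *both*, and each survivor is expanded further.
Pairwise interactions are scanned after the main effects
(`adapted-stepwise`) or before them (`interaction-first`).  Fit failures
prune the branch with a logged warning, never silently.  Branches are
capped (default 16, pruning the worst criterion value, logged); converging
branches are deduplicated by a canonical spec string, which also breaks
ties deterministically.  The final set keeps every frontier model within
the threshold of the minimum criterion.  "Within two" is read as two
*units* of AIC/BIC, anchored by the evidence-ratio argument
(`exp(2/2) ≈ 2.7`) and by the AIC/LRT correspondence
(`P(χ²₁ > 2) = 0.157`).

A structural caveat found while validating on synthetic cohorts: under
administrative censoring at a calendar cut-off, a calendar-time covariate
(diagnosis year) becomes nearly collinear with `log t` inside the risk
sets — recent diagnoses only contribute short follow-up — so its
proportional and time-dependent forms fit almost identically and *no*
criterion can separate them.  The selection-consistency conditions in the
test-suite therefore use cohorts with complete five-year follow-up and
covariates (age, deprivation) whose forms are identified.

## Averaging and unconditional variance

Weights are `w_m = exp(−Δ_m/2)/Σ exp(−Δ_n/2)`; they are invariant to
shifting all criteria and sum to one to 1e−12.  Averaging is applied to the
predicted quantities — hazards and cumulative hazards per patient per time —
never to parameters, whose meaning differs across functional forms.
Individual averaged net survival is `exp(−Λ_MA)` (averaging on the
cumulative-hazard scale, *then* exponentiating), and cohort survival is the
mean of individual curves.  The unconditional variance

`var(λ̂_MA) = [Σ_m w_m √(var(λ̂_m) + (λ̂_m − λ̂_MA)²)]²`

assumes perfect correlation between the models' deviations, making it
conservative; it is never below `[Σ w_m √var_m]²`.  It is computed on the
hazard scale (the scale on which averaging is defined) and on the
cumulative-hazard scale; survival intervals are obtained by mapping normal
`Λ`-scale intervals through `exp(−·)` — a declared policy, since the
interval scale is not standardised in this literature.  The default
prediction grid is monthly.

## RMISD

`ISD_g = ∫₀ᴴ (Ŝ_g − S_g)² du` by 20-node Gauss-Legendre (exact to 1e−12 for
polynomial differences up to degree 39), `RMISD = sqrt(mean_g ISD_g)`.
Non-parametric reference curves are evaluated at the nodes by
right-continuous step interpolation (survival step functions are
right-continuous); model curves are evaluated directly.  The integral runs
over `(0, H]` with `S(0) = 1`; horizons of 1 and 5 years are the defaults.
Default grouping is age band × deprivation quintile with bands
15–44, 45–54, 55–64, 65–74, 75–99 (configurable; registry reports differ in
banding per cancer).  A reference curve that stops before the horizon is an
error naming its last supported time, and a predicted group with no
reference counterpart is an error — silent group dropping would bias the
mean.

## Synthetic registry generator

Each scenario draws age (truncated normal), deprivation quintile
(categorical), diagnosis year (uniform over the window) and a uniform
within-year diagnosis date; a cancer death time by exact inversion of the
closed-form cumulative excess hazard
`Λ_E(t) = λ₀ κ e^{ps(x)} t^{κ+s(x)}/(κ+s(x))` (Weibull-form baseline,
log-linear proportional predictor `ps`, time-dependent predictor `s`); an
other-cause death time by inversion of the patient's piecewise-linear
cumulative background hazard along their attained age/year path; and
administrative censoring at the calendar cut-off.  Observed status is death
from *either* cause before censoring — the observable-mortality convention
of the relative-survival setting.  All draws come from named substreams of
one seed, so adding a covariate does not perturb the other streams and a
fixed seed reproduces cohorts byte-for-byte.

The same life table drives simulation and estimation, so the
background-mortality assumption holds exactly by construction; a
multiplicative `misspecification` factor can break it deliberately.

Scenario presets encode three qualitative regimes, with effect sizes that
are package choices (documented, not registry estimates):

| preset | baseline (λ₀, κ) | 5-y net survival | age (per decade) | dep (per quintile) | year (per year) |
|---|---|---|---|---|---|
| `lung_like` | 0.65, 0.75 | ≈ 0.12 | 0.22 | 0.08 | −0.015 |
| `colon_like` | 0.25, 0.80 | ≈ 0.40 | 0.20 | 0.10 | −0.045 |
| `breast_like` | 0.04, 1.10 | ≈ 0.81 | 0.12 | 0.05 | −0.025 |

`selection_scenario` (age and deprivation effects only, complete five-year
follow-up, n = 3000 by default) defines the conditions for studying
selection behaviour, for the collinearity reason above;
`with_time_dependent_age` replaces the age effect by `0.12 · g(age) · log t`
(kept small enough that `κ + s(x) > 0` at every age, so the hazard stays
integrable at 0).  The synthetic life table is Gompertz
(`rate = a·e^{b·age}`, a = 1e−5, b = 0.095) with quintile multipliers
0.925–1.225 and a mild calendar decline of 0.5%/year.

What the generator deliberately does *not* emulate: registry data-quality
artifacts (duplicate records, date errors), missing stage and its
imputation, non-administrative loss to follow-up, and within-year seasonal
structure.  Passing tests therefore demonstrate correctness of the
estimators and of the selection/averaging machinery under a correctly
specified background-mortality model — not robustness to the data-quality
problems real registries add on top.

## Study harness

`run_study` reproduces the prediction/projection design: follow-up is
artificially censored at a calendar cut-off, models are selected on
diagnosis-year windows ending at the prediction year, predictions are made
for the prediction-year cohort (only its first year of follow-up informs
selection) and projections for the cohort diagnosed one year later, which
never enters any fit — a leakage guard raises if a record with follow-up
beyond the cut-off reaches fitting or selection, and the projection year
must lie outside every window.  Projection evaluates the fitted
year-of-diagnosis effect one year beyond the data (linear or spline-tail
extrapolation per the fitted form) — the structural advantage a parametric
model has over the period approach.  Comparison arms: model averaging, the
simple all-linear-PH model, and the period-approach estimator with the
prediction year as the default window.  A run manifest records the
configuration, per-stage timings, model counts and collected warnings.

## Problem sizes used in the checks

The statistical acceptance checks run on synthetic cohorts of n = 2000
(coverage and averaged-recovery, 20 replicates), n = 3000 (selection
consistency and time-dependent power, 50 replicates each; accuracy ordering
of arms, 25 replicates), and n = 5000 (estimator-consistency checks) —
sizes at which every property examined is comfortably identified while the
whole suite stays quick to run.  Monte-Carlo comparisons use 2 standard
errors of the replicate distribution.

## Known limitations

- No cure fraction, frailty, or alternative link functions; cause-of-death
  information is deliberately unused.
- The time-dependent form is exactly `β log t`; effects that change
  non-monotonically over follow-up are only approximated through the
  baseline spline.
- Age standardisation and hybrid cohort/period estimation are out of scope.
- The unconditional variance is conservative by construction; intervals
  built from it over-cover.
- Life tables are used as given: no graduation or smoothing, and no
  calendar extrapolation beyond the supplied years.
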
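# Methods

## Problem and data model

Fishery variable costs (fuel cost, fuel consumption, labour cost, other
variable costs) are observed once per vessel and year, while fishing
activity is observed per trip and métier. The package works with four flat
tables: trip-level activity records, annual per-vessel costs, official
aggregate costs by fleet segment × year, and transversal data (hours at
sea, fishing-days × kW, landings value) by fleet segment × métier × year.
Years are pooled throughout: a vessel monitored in two years contributes
two observations, which trades some independence for sample size. Currency
and consumption units are carried as labels and never converted.

Validation is total: every input row is either accepted or logged with a
reason. A trip row missing its landings value is kept — it still informs
the effort-based (fuel) analyses — but the vessel-year's revenue becomes
unknown and the observation drops out of the labour-side analyses only.

## Phase 1: observation building

**Prevalent métier.** For each vessel-year the prevalent métier is the
argmax of summed activity over trips; the activity metric is hours at sea
by default (fishing days or trip counts are available for gears where
hours are a poor effort measure). Exact ties go to the lexicographically
smaller métier code, logged. The activity share is the prevalent métier's
fraction of the vessel-year total.

**Proportional adjustment.** All four cost series *and* the transversal
totals (hours, days×kW, revenue) are multiplied by the activity share, so
the adjusted observation describes the prevalent métier's part of the
vessel's year on both sides of every regression. Applying the adjustment
to the regressors as well as the costs is required for internal
consistency (a 75%-share vessel with 1000 hours did not spend 1000 hours
in its prevalent métier); the choice is logged at run time.

**Coverage filter.** Within each segment, métiers are ranked by the number
of vessels whose prevalent métier they are, and the smallest prefix whose
cumulative count share reaches the threshold (default 0.80, per-segment
overrides allowed) is retained. The prefix rule is re-applied until the
retained set is stable; the iteration makes the filter idempotent — a
property the pipeline relies on — and on realistic fleet compositions it
changes nothing or removes a borderline métier that the per-métier
minimum-observation rule (below) would have excluded anyway. An
activity-weighted variant of the coverage measure was considered and
rejected: counts are what determine whether a métier's coefficients are
estimable.

## Phase 1: estimation

**Exploratory screen.** For every segment × métier with at least `min_n`
observations (default 30) and for the pooled segment (`ALL`), the package
reports the Pearson correlation and a regression through the origin for
each relationship in the catalogue: fuel cost ~ effort, fuel consumption ~
effort, labour cost ~ {revenue, revenue − variable costs, revenue − fuel
cost, effort}. The null intercept mirrors the disaggregation step (zero
activity must imply zero cost); the correlation is the ordinary centred
one. The through-origin slope is Σxy/Σx² with standard error
√(RSS/(n−1)/Σx²) and a t test on n−1 degrees of freedom; "total variable
costs" in the net-revenue regressor defaults to fuel + labour + other and
is configurable.

**GLM.** Candidate models are Gaussian identity-link GLMs with no global
intercept. The métier factor is cell-means coded so every métier gets its
own coefficient, directly usable in phase 2. The métier-slope model adds
slope deviations γ_m relative to the first métier (2·M columns for M
métiers). Fits use iteratively reweighted least squares (statsmodels);
p-values use the t distribution, as for a least-squares fit with estimated
error variance. Explained deviance is 100·(1 − residual/null deviance)
with the intercept-only model as the null reference. When a fit is
numerically exact (residual deviance at rounding-noise level), standard
errors vanish and t ratios degenerate; coefficients that are materially
nonzero on the response scale are then reported with p = 0 and the rest
with p = 1, and the AIC of a perfect fit is −∞ so it dominates any
imperfect alternative.

**Significance of the métier factor** uses the permissive any-level rule:
the factor matters if any métier coefficient has p < α (default 0.05,
strict inequality). A joint Wald F-test is available (`joint_metier_test`)
but off by default — the permissive rule is what lets a model with one
marginal métier level survive, which is the behaviour the method's
reference outputs exhibit.

**Decision flow.** Per segment, cost variable and candidate transversal:

1. *Gate*: if the pooled through-origin regression of the cost on the
   transversal is not significant, no disaggregation is attempted for that
   transversal ("none" is a valid outcome).
2. With ≥ 2 métiers, fit the métier-slope model; if the métier factor, the
   common slope and at least one slope deviation are all significant, keep
   it.
3. Else fit the métier-intercept model; if the métier factor and the slope
   are significant, keep it.
4. Else keep the proportional model if its slope is significant; else
   "none".

With a single métier the flow skips straight to the proportional model —
the métier effect is untestable. When several transversals qualify (the
usual case for labour costs), the qualifying fit with the lowest AIC wins.
The gate uses the pooled regression rather than the per-métier ones: the
flow asks whether *any* systematic cost–activity relationship exists
before asking whether the métier modulates it.

## Phase 2: disaggregation and reconciliation

The selected coefficients are applied to the transversal table:
`α_m + slope_m·X_m` per métier-year, or `α·X_m` for the proportional
model. Labour under the proportional model uses landings value as X; the
net-revenue regressors are carried by landings value at the aggregate
level, the closest observable quantity. Métiers present in the transversal
table but absent from the fitted model follow a fallback policy: `pooled`
(default) applies the segment's pooled through-origin slope; `skip` leaves
them unallocated, reproducing the coverage-loss part of the reconciliation
gap.

The consistency report gives, per (year, segment, cost), the signed
relative difference (Σ métier estimates − official)/official, and overall
the mean of absolute relative differences in percent. Rows with a zero
official value are flagged and excluded from the overall mean.

Two known scale caveats, surfaced rather than repaired:

- métier intercepts are estimated per vessel-year but added once per
  métier when disaggregating fleet totals, so intercept-bearing models
  under-allocate roughly by the vessel count; a
  `scale_intercepts_by_vessel_count` flag (off by default, requires a
  vessel-count table) multiplies them up for users who want scale
  consistency;
- the residual gap is reported, never reallocated to force the métier
  costs to sum to the official total.

## Synthetic fleets

The generator emulates a monitored Mediterranean fleet: by default four
segments (three trawler length classes and a hooks segment), ~515 vessels,
two pooled years, ~13 monitored trips per vessel-year, gamma-distributed
trip hours with lognormal vessel-level activity heterogeneity, métier
shares drawn from a Dirichlet concentrated (0.8) on the designed prevalent
métier, and trips assigned greedily to match those shares so the designed
prevalent métier is always recoverable. Fuel costs follow métier-specific
intercepts (10 000–18 000) plus a common 14-per-hour slope; labour is a
0.3 crew share of revenue; fuel consumption is fuel cost over a 0.8 price;
catch value varies trip to trip (cv 0.3) around 100 per hour.

The ground truth is written to be identifiable by the estimator: a
vessel-year's fuel cost is the prevalent métier's cost (α_m + β·h_prev)
scaled by the inverse activity share, so the proportional-adjustment step
recovers exactly α_m + β·h_prev before noise. Aggregate tables are exact
marginal sums of the micro-data.

Observation noise comes in two kinds. The default is mean-one
multiplicative lognormal (cv 0.1): bookkeeping noise that scales with the
cost, realistic but heteroscedastic. The `gaussian` kind is additive with
one standard deviation of cv × the series' mean cost — the iid error
structure the estimation GLM itself assumes. The canned structure
scenarios (`eq1`, `eq2`, `eq3`, `none`) use the gaussian kind so that
selection-correctness studies exercise the decision flow at its nominal
test sizes; the `none` scenario uses zero-mean noise costs (a diagnostic
construct — real costs are positive, but a positive activity-independent
cost is partially absorbed by a through-origin slope, so it is not a
no-relationship case).

What passing synthetic tests do *not* show about real fleets: the
generator has no fuel-price variation across years, no vessel random
effects or serial dependence between pooled years, no spatial structure,
and its métier mixing is stationary. Results on real data inherit none of
these simplifications' guarantees.

## Measured behaviour (recomputed by the test suite and acceptance script)

- On 200 replicates of the 200-vessel métier-intercept fleet with noise sd
  at 10% of the mean cost, the intercepts and slope fall within 3 standard
  errors of truth in 99.5–100% of replicates and the mean fitted crew
  share is 0.300. Under the multiplicative-lognormal variant the measured
  3-SE coverage drops to 95–99% and the crew share is unchanged.
- The decision flow identifies each canned structure in ≥ 90 of 100
  replicates (measured 93–100). Under lognormal noise the métier-intercept
  scenario is misclassified as métier-slopes in ~12% of replicates — the
  heteroscedasticity inflates the interaction test; this is a known
  limitation of the homoscedastic GLM on multiplicative-noise data.
- A noiseless proportional fleet reconciles end to end with an overall gap
  at machine precision (~1e-14 %).

## Numerical choices and degenerate inputs

Tolerances: exact-fit detection at residual deviance ≤ 1e-16·n·max|y|²;
material-coefficient threshold 1e-6 on the response scale; oracle
equivalence asserted at 1e-8. Ties: prevalence ties lexicographic; métier
ranking ties in the coverage filter lexicographic; transversal ties by
AIC, then catalogue order. Degenerate inputs: all-zero activity, all-zero
regressors, single-observation métiers in slope models, and rank-deficient
designs are rejected with the offending métier named; zero-variance
correlations are reported missing with a reason. Problem sizes in the test
suite (200 vessels × 200 replicates for recovery, 100 replicates per
selection scenario) keep the full run within a few minutes on one core
while leaving Monte-Carlo error well below the asserted margins.
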
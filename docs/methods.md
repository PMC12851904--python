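# Methods

This note documents the statistical machinery in `hzrd`: the estimators, the
synthetic data-generating process, the numerical choices, and what the test
suite does and does not establish about real data.

## The design

Eligibility for the live-attenuated herpes zoster vaccine in Wales was
assigned by date of birth: persons born on or before September 1, 1933 never
became eligible; persons born after became eligible in staggered yearly
catch-up waves starting September 1, 2013 (and on their 78th birthday from
April 2017). Dates of birth are observed only at week resolution, with weeks
starting on a Monday. The running variable is the signed number of weeks
between a person's birth week and the first eligible week.

**The straddling week.** September 2, 1933 was a Saturday, so the week of
Monday August 28 – Sunday September 3 contains days on both sides of the
cutoff. The default `majority` rule assigns that week to the side holding at
least four of its seven days — here the ineligible side, since only the
Saturday and Sunday fall on or after the cutoff — giving the week index −1
and making Monday September 4 the first eligible week (index 0). The rule is
configurable (`eligible`, `ineligible`, `drop`) because the classification
is a genuine judgment call at week-resolved data, and its sensitivity is
testable. Throughout the package, "eligible" means the week-level side of
the threshold, so eligibility is exactly the sign of the running variable.

## Sharp and fuzzy RD estimation

The sharp estimator fits, by weighted least squares within a bandwidth `h`
and with triangular kernel weights, an intercept, an eligibility jump, and
side-specific polynomial slopes of order `p` (default 1, order 2 available
as a robustness check; higher orders are deliberately not offered). Optional
covariates and fixed effects enter additively with coefficients common to
both sides. The polynomial basis is evaluated in `x/h` so the normal
equations stay well conditioned at wide bandwidths; the jump coefficient is
invariant to this scaling.

**Fixed-effect reference levels.** Rollout-cohort fixed effects partition
the data along the threshold, so they are structurally collinear with the
eligibility indicator. The encoder therefore uses the kernel-weight-dominant
level on each side of the threshold as the reference: the constant absorbs
the just-ineligible cohort, the jump coefficient the just-eligible one, and
all other cohorts receive dummies. Residually dependent dummy columns are
pruned by a rank test; an explicit covariate that turns out collinear is an
error naming it, because that always indicates a user mistake rather than
design structure.

The fuzzy estimator instruments receipt with eligibility in a
just-identified weighted 2SLS sharing the sharp fit's bandwidth and weights
(the bandwidth is selected on the outcome, matching the practice of one
bandwidth per cohort-outcome pair). Without covariates the point estimate
equals the outcome jump divided by the uptake jump exactly. A first-stage
jump smaller than 0.01 raises a weak-instrument error rather than returning
a silently unstable ratio.

## Bandwidth selection

The MSE-optimal bandwidth uses a plug-in of the Imbens–Kalyanaraman type
with exact triangular boundary-kernel constants (the kernel moment matrices
are polynomial integrals computed in closed form):

1. pilot window `h₁ = 1.84·sd(x)·n^(−1/5)`; density `f̂(0)` from the count
   within `h₁`, side variances from the outcome variance within `h₁`;
2. third derivatives from global cubic side fits give side-specific pilot
   windows `h₂± = 3.56·(σ̂²±/(f̂·m̂₃±²))^(1/7)·n±^(−1/7)`;
3. curvatures `m̂₂±` from unweighted quadratics within `h₂±`, with the
   regularization `r± = 2160·σ̂²±/(n₂±·h₂±⁴)` guarding against near-zero
   curvature differences;
4. `h = [V·(σ̂²₋+σ̂²₊)/f̂ ÷ (2(p+1)·(B·Δm̂₂/(p+1)!)²)]^(1/(2p+3)) · n^(−1/(2p+3))`,
   where `B` and `V` are the boundary bias and variance constants.

The bias bandwidth `b` is selected analogously for the order-(p+1) curvature
estimand (rate `n^(−1/7)`, pilot third-derivative differences from global
quartic side fits, regularization with the exponent matched to the
derivative order), floored at `h`. Degenerate variance or curvature falls
back to a rule of thumb with a warning. The selector is exactly
scale-equivariant — rescaling the running variable by `c` rescales both
bandwidths by `c` — and all pilot fits run on rescaled abscissae for
numerical stability.

## Robust bias-corrected inference

Both the jump estimate and its leading-bias estimate are linear functionals
of the outcomes: the order-(p+1) fit at bandwidth `b` estimates the `x^(p+1)`
curvature coefficients on each side, and the finite-sample bias factor of
the order-p jump functional multiplies them. Subtracting gives the
bias-corrected estimate; because the combined weights are explicit, the
"robust" variance — which accounts for the bias-estimation step — is the
sandwich variance of the combined linear functional, with residuals taken
from the higher-order fit. Confidence intervals are centered on the
bias-corrected estimate; the reported point estimate is the conventional
one, so the interval need not contain it.

The running variable is discrete (weeks), so the default variance estimator
clusters on week-of-birth mass points; plain HC0/HC1/HC3 and a mass-point
variance (within-week sample variances of the outcome) are available. For
the fuzzy design the numerator and denominator are bias-corrected
separately and combined by the delta method including their covariance;
whether joint or component-wise correction is preferable is genuinely open,
and the component-wise route was chosen for its transparency.

Calibration, measured by the package's own simulations (500 replicates of
60,000 persons at generator defaults): the robust bias-corrected 95%
interval covers the true effect in roughly 93–95% of replicates. The small
shortfall from nominal is the familiar price of re-using a data-driven
bandwidth for inference and is shared by standard implementations of this
inference scheme; the conventional (non-corrected) interval under-covers
substantially under curvature, which the suite demonstrates directly.

## The synthetic cohort generator

The generator emulates the features of the linked-EHR extract that the
estimators rely on, with known ground truth:

- dates of birth uniform over September 1925 – September 1942, floored to
  Monday weeks;
- vaccine uptake 0 left of the threshold and 0.459 (0.287 for persons with
  baseline dementia) at the threshold, optionally sloped in the running
  variable; uptake timing uniform within the person's first eligibility year;
- binary 9-year outcomes drawn from risks that are logistic-linear
  (optionally quadratic) in the running variable, hence smooth across the
  threshold; baseline 9-year risks default to 0.073 for MCI and 0.42 for
  death due to dementia among those living with dementia, with per-week
  log-odds age trends of about −0.0013 (diagnosis outcomes) and −0.002
  (mortality outcomes);
- the treatment effect enters only through simulated receipt, as an additive
  risk change per treated person equal to the configured eligibility effect
  divided by the uptake jump, so the true complier effect satisfies the Wald
  identity by construction. Potential outcomes are coupled through a shared
  uniform draw (a protective effect only removes events) and stored in the
  table (`y0_*`, `y1_*`) for verification;
- the female/male effect ratio defaults to 8.4, the value implied by the
  per-gender point estimates of the motivating study, normalized so the
  gender-share-weighted mean effect equals the configured overall effect;
- mortality risks carry Charlson-comorbidity log-odds offsets (roughly 0.2
  to 1.3 per condition) so the severity score has real signal; event dates
  are uniform within the follow-up window, dementia typically lags an MCI
  diagnosis, and nothing postdates death;
- pre-period events (2004–2013) are drawn independently of the eligibility
  side, for placebo and pre-period tests; an optional birth-season risk
  shift injects the seasonal confound that the DID design differences out;
- utilization counts mix frequent and infrequent attenders so that roughly
  half the cohort qualifies under the visit-every-year restriction.

What the generator does not emulate: coded-diagnosis vocabularies,
registration churn and linkage error, time-varying hazards (event times are
uniform given occurrence), competing-risk structure beyond the death clamp,
and any real seasonality-of-birth health gradients. Passing tests therefore
establish the estimators' correctness and calibration under the design's
assumptions, not the robustness of the design to violations absent from the
simulation.

## Difference-in-differences

Linear probability models throughout, matching the linear estimating
equations of the design. The pretest regresses the outcome on month and
cohort fixed effects plus season-by-cohort interactions (reference cohort
1932/33); the 2SLS instruments receipt with the season-by-1933/34 cell.
Standard errors are heteroskedasticity-robust by default; clustering on
cohort-season cells is available but left off because those cells are few.
A failed pretest warns and flags the result rather than refusing to
estimate, since the flag itself is the scientifically interesting output.
February 29 births fall in the post-September season of their cohort by the
stated date ranges.

## Heterogeneity and relative effects

The gender model fully interacts the fuzzy design with a male indicator and
uses two instruments (eligibility and eligibility-by-male); because the
design is block-saturated by gender, the per-gender effects equal separate
single-gender fits at the same bandwidth, which the suite verifies exactly.
Interaction p-values use the conventional robust standard error.

Severity scores are maximum-likelihood logistic fits on ineligible persons
only, with age at program start and the 16 Charlson conditions (AIDS
excluded) as separate indicators — no summed index — plus dementia-specific
burden counts for the dementia-death variant. Predictions impute age 80 for
everyone. Constant predictors are dropped automatically; separation
triggers a small-ridge refit with a warning. The median split is computed
on the full scored cohort (not just within the bandwidth) with ties going
below; the split is invariant to monotone transforms of the score.

Relative effects divide the absolute effect by the predicted outcome level
just left of the threshold: the ITT fit's left intercept for eligibility
effects, and the untreated-complier left limit for receipt effects,
computed under one-sided noncompliance as (left limit of `Y` minus right
limit of `Y·(1−V)`) divided by the first-stage jump. The first-stage
divisor cancels between the receipt effect and its denominator, so the
ratio needs no extra variance term for it; the delta-method interval uses
the sandwich covariance of the underlying linear functionals and agrees
with a nonparametric bootstrap on moderate samples (verified at 2,000
draws). Dementia-type comparisons report relative point estimates only —
no rigorous interval exists for relative effects in this design — for
Alzheimer's, vascular and mixed dementia, by default among women, where the
observed effects concentrate.

## Falsification suite

Placebo thresholds (September 2 of 1930–1932 and 1934–1936) rebuild the
cohort and re-run the entire procedure — including bandwidth selection —
at each shifted threshold, with follow-up windows shifted congruently and
truncated to six years so all comparisons cover the same ages (equal up to
the within-week weekday drift of September 2 across years, under one week).
Pre-period tests shift the follow-up window nine years earlier. Balance and
negative-control tests are one sharp RD per covariate or control outcome,
deliberately unadjusted for multiplicity, with the expected-by-chance count
reported alongside. The robustness grid takes the Cartesian product of
bandwidth multipliers (0.5–2.0), grace periods, polynomial order, the
staggered-rollout adjustment, utilization covariates, and the
frequent-attender restriction; cells fail independently.

**Staggered-rollout adjustment.** When follow-up starts at each person's own
eligibility date, never-eligible persons receive the index date of the
person born equally far on the other side of the threshold (mirroring),
which preserves age at index; rollout-cohort fixed effects (with mirrored
labels on the left) absorb the cohort-specific window truncation that the
staggered windows create at the data's calendar end.

## Problem sizes

The simulation studies use the study conditions as defaults: 60,000 persons
per replicate, 500 replicates for parameter recovery and interval coverage
(plus 250 null replicates), 20 replicates × 7 tests for placebo error
rates, 6 replicates of the 36-test balance suite, and 16 replicates for the
DID recovery and RD/DID agreement checks. Simulation-heavy fixtures omit
outcomes that a given check does not analyze; all design parameters
(uptake, effects, sample size) are the defaults.
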
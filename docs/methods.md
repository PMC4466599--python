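# Methods

This note documents the models, numerical choices and design decisions
behind `childcheck`, and what the synthetic-data conditions do and do not
establish about behaviour on real data.

## Weight status (LMS method)

BMI is computed as weight/height² (kg, m). The growth reference stores per
sex a grid of ages with the LMS triple: Box–Cox power `L` (unitless),
median `M` (kg/m²) and coefficient of variation `S` (unitless). Between
grid ages each of L, M, S is interpolated **linearly**; no extrapolation is
permitted outside the tabulated range (requests raise an out-of-range
error). Linear interpolation is the simplest defensible choice for a grid
this dense (half-year steps); cubic alternatives change centiles by far
less than measurement error in height/weight.

The z-score uses the logarithmic limit form when |L| ≤ 1e-8. The switch
point sits where the general formula's cancellation error (of order
ε·z²·S/2 relative terms plus float cancellation ~1e-16/|L·S|) exceeds the
limit form's truncation error; at 1e-8 both are far below any clinically
meaningful digit, and the branch is continuous to ~1e-7 in z.

Centile boundaries classify upward: centile ≥ 91 → overweight, ≥ 98 →
obese; everything below 91 is reported "healthy" (no underweight band is
modelled). Ages are decimal years; date-to-age conversion is fixed at
(date − birthdate)/365.25.

The packaged reference is **synthetic**: smooth curves with plausible
shapes (median BMI rising from ≈15 kg/m² at age 5 to ≈21 at 18, mild
negative skewness, S growing with age). It exercises every code path and
test but carries no clinical meaning; the licensed UK90 tables must be
supplied by the user for real consultations.

### Ethnicity adjustment

The engine accepts an ethnicity-adjusted BMI z-score as the cardiometabolic
model's covariate. The adjustment is implemented as a configurable additive
per-ethnicity shift, defaulting to zero for every group. This is a hook,
not a claim about how any published adjustment was constructed; an additive
shift preserves within-group ranking and keeps the engine agnostic to the
adjustment's provenance.

## Risk models

Models are logistic regressions fitted by maximum likelihood (statsmodels
`Logit`, Newton, up to 200 iterations), with two-sided Wald p-values.
Perfect or quasi-separation is detected (solver exceptions, or standard
errors above 1e3 together with non-overlapping class-conditional supports)
and raised as an error naming the offending covariates; during stepwise
selection such candidates are dropped with a logged warning instead.

**Forward stepwise, AUC-gated.** Each round refits the current model with
every remaining candidate; candidates with Wald p < α (default 0.05) and
in-sample ROC AUC strictly above the current model's enter in order of
largest AUC gain, and selection stops when none qualifies. The intercept-only
model's AUC is 0.5 (a constant score ties every case–control pair). A
`min_auc_gain` option (default 0) lets callers demand a visible gain.

*Known error rates.* With a strict-zero gain gate, the AUC condition is
almost always satisfied in-sample, so retention is governed by the p-value
gate alone. Because unselected candidates are re-tested every round, a pure
noise covariate enters with probability noticeably above α per run (~10–15%
with two decoys at n = 2000 in our simulations), and its spurious in-sample
AUC gains (0.002–0.04) overlap the gains of genuinely weak covariates — no
gain threshold separates them cleanly. Exact recovery of the generating
covariate set therefore plateaus near 85% under these conditions, while
recovery of *all true* covariates exceeds 95%. Users wanting stricter
specificity should lower α or validate out-of-sample; the engine
deliberately reproduces the derivation procedure as described rather than a
modern penalised alternative.

**Scores.** Risk scores are predicted probabilities. Probabilities and
linear predictors are monotonically equivalent, so every quantile- or
NPV-based cut-off, and hence stratification, is unchanged by the choice;
probabilities read naturally in a consultation.

**High cut-off.** Given scores among overweight children and the outcome
prevalence p, the cut-off is the smallest observed score whose strict
exceedance count is ≤ n·p — the empirical (1 − p) quantile. For tie-free
scores exactly ⌊n·p⌋ scores exceed it; with ties the exceedance never
overshoots p. Prevalence 0 returns the maximum score (nobody High).

**Low cut-off.** Candidates are the distinct observed scores plus a
sentinel below the minimum (NPV is a step function that changes only at
observed scores). The cut-off maximising NPV of "score ≤ cut-off →
predicted negative" is returned; ties are broken towards the cut-off
classifying the most children Low, maximising the reach of the reassuring
message. An outcome-free sample has NPV 1 everywhere and returns the
maximal cut-off. If calibration produces low > high, the pair is clamped to
equality with a logged warning (an empty Medium band).

**Performance reporting.** Sensitivity, specificity, PPV and NPV are
computed under an explicit convention: `high-vs-outcome` (positive
prediction = High stratum, condition = outcome present) or
`low-vs-no-outcome` (positive prediction = Low stratum, condition = outcome
absent). Both are exposed because screening tools are quoted both ways in
the literature. Zero-denominator metrics are reported as undefined (None),
never as 0. AUC is the Mann–Whitney pair statistic and is
convention-independent.

## Synthetic cohorts

The generator emulates the *role* of the population-based derivation
cohorts: overweight/obese children with the covariates the two models use
and outcomes at controlled prevalence. Defaults (one choice, not revisited):

| parameter | default | rationale |
|---|---|---|
| outcome prevalence (both) | 0.10 | matches the worked calibration description (10% High) |
| adjusted BMI z | N(2.0, 0.6) truncated ≥ z₉₁ ≈ 1.34 | overweight-only derivation sample |
| bullied / victimised rates | 0.25 / 0.15 | typical school-age survey rates |
| sedentary hours | Gamma(3, 1) (mean 3 h/day) | right-skewed, plausible mean |
| cardio effect | adjusted BMI z: 0.9 log-odds/SD | strong single predictor, AUC ≈ 0.75 |
| EBD effects | bullied 0.9, victimised 0.7, sedentary 0.18 /h | Wald p ≈ 1e-3 at n = 2000, echoing the reported significance levels of the retained covariates |

Outcome intercepts are solved by Brent root-finding so the mean predicted
probability over the realised covariates equals the target prevalence;
targets of exactly 0 or 1 are rejected as unsatisfiable. Biomarkers are
drawn conditionally on the outcome flag via inverse-CDF truncated normals
(all randomness flows through the single `numpy` Generator seeded by
`seed`): outcome-positive children get one marker drawn above its
threshold (chosen uniformly among glucose, LDL, systolic, diastolic) and
the rest below; negatives get all markers below. The SDQ total is likewise
truncated at 17.5 on either side of the flag. This guarantees the
definitional operations reproduce the generated flags for every child — a
tested invariant.

**What passing tests do not show.** The generator's covariates are mutually
independent, effects are exactly logistic-linear, biomarker correlations
are absent, and there is no missingness, measurement error or clustering by
school/practice. Parameter-recovery and calibration results therefore
validate the *algorithms*, not the epidemiology: performance figures on
these cohorts (e.g. AUC ≈ 0.66–0.75) are properties of the chosen effect
sizes, and transfer to real cohorts only insofar as real data resemble the
generative model.

## Lifestyle engine

Rules are configuration, not code: each has a behaviour id, an `at_least`
or `at_most` comparator, a recommended level with units (optionally per age
band) and two message templates (`string.Template`, `$reported` /
`$recommended` / `$units` substitutions). Meeting the level is boundary
inclusive. Missing reports produce a "not assessed" entry rather than being
dropped. The packaged default ruleset (5-a-day fruit/veg, 60 min/day
activity, ≤2 h/day screens, ≤1 sugary drink/day, age-banded sleep, daily
breakfast) carries placeholder levels drawn from common public-health
guidance and is meant to be edited; age bands are closed intervals resolved
first-match in file order.

## Consultation and summaries

The consultation composes the three modules with no hidden coupling (a
tested identity): weight status, then per-outcome scoring and
stratification (High on any outcome adds a configurable referral
recommendation — its presence, not wording, is the contract), then advice.
Any component failure aborts with a section-labelled error; partial reports
are never emitted. Reports serialise to text, HTML and JSON; the
`normalised` mode omits the timestamp so identical inputs give
byte-identical output. Chart data are the reference's 2nd/9th/25th/50th/
75th/91st/98th centile BMI curves plus the child's (age, BMI) point.

Questionnaire summaries use counts with **half-up** rounding: integer
percent for satisfaction-style items (12/14 → 86%, 11/14 → 79%) and
one-decimal percent for categorical breakdowns (1/14 → 7.1%), implemented
with `decimal` to avoid float-rounding surprises. Responses outside the
declared ordinal scale raise row-numbered errors.

## Problem sizes used in the test suite

Oracle-equivalence suites run exhaustive enumeration at n ≤ 200 (cut-offs)
and n ≤ 50 (AUC pair counting); stepwise recovery uses 100 cohorts of
n = 2000; coefficient-bias checks use 20 cohorts of n = 10 000. These sizes
put Monte-Carlo error well below the asserted tolerances while keeping the
default suite in the tens of seconds on one CPU.

## Known limitations

- The synthetic growth reference is structurally, not clinically, valid.
- Forward selection's decoy-admission rate (above) is inherent to the
  specified procedure; no correction for multiple looks is applied.
- Calibration is in-derivation-sample only; no cross-validation or
  shrinkage is provided.
- The ethnicity adjustment is a zero-default configuration hook.
- Single consultations only: no longitudinal tracking, follow-up
  scheduling or EMR integration.
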
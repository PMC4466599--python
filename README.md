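# childcheck

A decision-support engine for the assessment and management of childhood
overweight in primary care. It implements the three-step consultation a
practitioner walks through with a family:

1. **Weight status** — BMI centile against an LMS growth reference
   (overweight at the ≥91st centile, obese at the ≥98th, the UK clinical
   convention);
2. **Risk assessment** — logistic risk scores for two comorbidity groups
   (cardiometabolic abnormality; emotional and behavioural difficulties),
   stratified into Low/Medium/High with a referral recommendation for High;
3. **Lifestyle advice** — patient-reported diet, activity, screen, sleep
   and breakfast behaviours compared against configurable recommended
   levels, rendered as printable personalised feedback.

It is aimed at developers and methodologists working on paediatric
weight-management tooling who need the full derivation pipeline — cohort
simulation, model selection, cut-off calibration, performance metrics —
reproducible end to end without access to licensed growth references or
restricted cohort data.

## The statistics in brief

**LMS z-scores.** A growth reference is summarised by age/sex curves
(L, M, S): the Box–Cox power, median and coefficient of variation. For a
BMI value *x*,

    z = ((x/M)^L − 1) / (L·S)   (L ≠ 0),    z = ln(x/M) / S   (L = 0),

and the centile is 100·Φ(z). The package ships a *synthetic* LMS reference
(the licensed UK90 tables cannot be redistributed); supply your own
reference CSV (`age_years,sex,L,M,S`) for clinical use.

**Risk models.** Logistic regressions fitted by maximum likelihood.
Covariates enter by forward stepwise selection: a candidate is retained
only if it is associated with the outcome (Wald p < 0.05) and strictly
improves the in-sample ROC AUC. Cut-offs are calibrated on the derivation
sample: the **High** cut-off is the empirical (1 − prevalence) quantile of
the scores — so the proportion of overweight children whose score exceeds
it equals the outcome prevalence — and the **Low** cut-off maximises the
negative predictive value of "score ≤ cut-off → no outcome".

**Synthetic cohorts.** A seeded generator produces overweight/obese
children (BMI z truncated above the 91st-centile deviate) with outcome
prevalences hit in expectation by numerically solving the logistic
intercept, and biomarkers drawn conditionally on the outcome flags so the
definitional thresholds (glucose ≥ 5.6 mmol/L, LDL ≥ 2.85 mmol/L, BP
centile ≥ 95; SDQ > 17.5) reproduce the flags exactly.

## Worked example

```bash
python examples/fit_and_calibrate.py
```

```
selection trace:
  + sedentary_hours  p=0.0000  AUC=0.598
  + bullied          p=0.0000  AUC=0.644
  + victimised       p=0.0000  AUC=0.664
low cut-off:  0.0390
high cut-off: 0.1792
High-vs-outcome: sensitivity=0.256 specificity=0.917 PPV=0.256 NPV=0.917 AUC=0.664
```

The trace shows the three covariates with true effects entering in order of
AUC gain while the two decoy covariates are rejected; the high cut-off
leaves ~10% of the cohort in the High stratum (the configured outcome
prevalence), and the performance block reports the confusion-matrix metrics
under the "High stratum vs outcome" convention. The other scripts in
`examples/` cover weight status, cohort simulation, lifestyle advice, the
full consultation report and questionnaire summaries.

A thin CLI wraps the same functions:

```bash
childcheck simulate --n 2000 --seed 1 --out cohort.csv
childcheck fit --cohort cohort.csv --outcome ebd_outcome \
    --covariate bullied --covariate victimised --covariate sedentary_hours \
    --out ebd.json
childcheck calibrate --model ebd.json --cohort cohort.csv --out ebd.json
childcheck assess --patient patient.json --model ebd.json --format text
```

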
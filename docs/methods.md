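# Methods

## Reference standard and rounding convention

Glycemic status is determined from the 75 g OGTT triplet (fasting, 1 h, 2 h
plasma glucose, mmol/L) with the IADPSG/WHO thresholds: GDM for FPG 5.1–6.9
and/or 1h-PG ≥ 10.0 and/or 2h-PG 8.5–11.0; DIP for FPG ≥ 7.0 and/or
2h-PG ≥ 11.1, DIP taking precedence. There is deliberately no 1 h DIP
criterion: a triplet (4.5, 15.0, 6.0) is GDM.

All threshold comparisons are applied to values rounded to one decimal
(half away from zero), the precision at which plasma glucose is clinically
reported. This makes the nominal bands exact and gap-free: after rounding,
"FPG 5.1–6.9" is equivalent to [5.1, 7.0) on raw values, and the triage
band "4.7–5.0" is [4.65, 5.05). A raw 6.95 is DIP-range; a raw 5.04 is
normal-range. The alternative — comparing raw floats to printed thresholds
— leaves the bands with zero-measure gaps and makes behaviour at 6.95
ambiguous; the rounding rule is documented, configurable nowhere, and
tested explicitly.

## Screening options and information discipline

The seven decision rules share three primitives: an FPG rule-in at ≥ 5.1
(labelled GDM below 7.0, DIP at or above), an FPG triage band 4.7–5.0 that
triggers a full OGTT read with the reference criteria, and a rule-out below
4.7. Option Sel performs the full OGTT in high-risk women only; Options
1/2/3 are universal and the `-Sel` variants restrict any rule to high-risk
women, counting the unscreened low-risk remainder as test-negative (they
enter the FN/TN cells). In Option 2 the history-of-HIP shortcut fires
before any glucose is examined, so a history-positive woman with FPG 4.2 is
labelled GDM with no test.

Every rule accesses glucose through a tracking view that records which
fields were read and raises if a post-load value is touched without an OGTT
being performed. This enforces, at run time, the core fidelity claim of the
simulation: a decision reported as "no OGTT" cannot have used information
an OGTT-sparing pathway would not possess. It also means fasting-only
records flow through Option 3 (and through Options 1/2 outside the band)
without error, and a missing post-load value only raises when genuinely
needed.

A consequence worth stating because the tests rely on it: for Options
Sel/1/1-Sel/3/3-Sel every positive call satisfies a reference-standard
criterion, so false positives are structurally impossible and PPV and
specificity are exactly 1 on any input. Only the history shortcut of
Options 2/2-Sel can produce false positives, and only among women with
previous HIP. Positive sets are nested (Opt3 ⊆ Opt1 ⊆ Opt2; X-Sel ⊆ X),
which orders sensitivities the same way on every cohort.

## Risk factors and eligibility

The Australian–New Zealand risk-factor rule flags: previous HIP, previous
neonatal death, age ≥ 40 years, family history of diabetes, pre-pregnancy
BMI strictly > 30, previous macrosomia, and high-risk ethnicity (North
African, Indian–Pakistani–Sri Lankan, Asian in this cohort's
classification). The cohort schema carries a history-of-fetal-death
variable rather than neonatal death specifically; it stands in for the
neonatal-death factor by default and can be switched off
(`fetal_death_as_neonatal_death=False`), since whether stillbirth should
count is genuinely ambiguous. Factors the schema cannot carry (previously
elevated glucose, PCOS, corticosteroid/antipsychotic use) are omitted from
the default rule; `RiskProfile.extra_flags` lets a caller add them without
changing the rule. Obstetric-history variables are three-level
(first child / no / yes) because a first pregnancy is not an absent answer;
"first child" counts as "no history" for risk and decision purposes.

Eligibility mirrors the emulated study population: OGTT at 22–30 weeks of
gestation, age 18–50, singleton, no pre-existing diabetes or bariatric
surgery, determinable risk status, and no early-pregnancy hyperglycemia
(first-trimester FPG < 5.1 mmol/L). Records failing any criterion are
excluded with all reasons listed.

## Performance metrics

Sensitivity, specificity, PPV and NPV are computed from the TN/FP/TP/FN
tallies with two-sided 95% binomial CIs. The default method is
Clopper–Pearson exact (conservative, never degenerate at 0/1 proportions);
Wilson is available by flag. Predictive values are taken at the cohort's
own prevalence. Any metric with an empty denominator is reported as
undefined rather than 0 — an all-negative cohort has undefined sensitivity,
not zero. Percentages are rendered to one decimal in written tables
(columns named `*_pct`); underlying values keep full precision and
round-trip through CSV to better than 1e-9.

Outcome rates are complete-case: a woman missing an outcome leaves that
outcome's denominator only. The composite adverse outcome is the
disjunction of preeclampsia, LGA infant, shoulder dystocia and neonatal
hypoglycemia, and is missing if any component is missing; it is always
derived, never simulated directly.

## Group comparisons

Case-class groups (TN/FP/TP/FN) are compared with one-way ANOVA for
continuous variables and chi-squared for categorical ones, switching to
Fisher's exact test when any expected cell count is below 5 (the
conventional rule; the choice is logged per variable). 2×2 Fisher tests
use full hypergeometric enumeration with the sum-of-less-probable-tables
two-sided definition (a tail-doubling variant is available by flag); larger
tables use a seeded Monte-Carlo sample of 10⁵ tables with the observed
margins, with the observed table included in the tally so p > 0. Pairwise
post-hocs are Welch t tests (continuous) or two-group sub-table tests
(categorical) with Bonferroni adjustment — adjusted p = min(1, 6·p) for the
six pairs among four groups — and significance at 0.05. All tests are
two-sided. The emitted report marks significant pairs with the a–f codes
conventional for four-group baseline tables.

Degenerate inputs: zero within-group variance flags the ANOVA result
rather than fabricating an F; groups with fewer than two observations are
excluded with a warning; all-zero contingency rows or columns are errors.

## Synthetic cohort generator

The generator emulates the joint structure the decision rules are
sensitive to, with defaults fixed to the emulated cohort's published
baseline characteristics:

| Parameter | Default | Source |
|---|---|---|
| glucose means (F, 1h, 2h) | 4.38, 6.76, 5.96 mmol/L | published cohort |
| glucose SDs | 0.45, 1.76, 1.43 | published cohort |
| glucose correlation | 0.40 (equicorrelated) | generator choice |
| history-of-HIP glucose shift | +1.0 SD per value | calibrated to ~50% recurrence |
| age, BMI | 30.25 (5.32) y; 24.36 (4.48) kg/m² | published cohort |
| OGTT gestational age | 26.22 (1.89), truncated 22–30 WG | published cohort |
| first-pregnancy fraction | 0.417 | published cohort |
| history of HIP / macrosomia / fetal death | 3.6% / 2.3% / 1.3% (marginal) | published cohort |
| family history of diabetes | 19.4% | published cohort |
| ethnicity mix | 7-category, published proportions | published cohort |
| early FPG | 4.25 (0.35), corr 0.5 with OGTT FPG, truncated < 5.1 | generator choice |
| treatment attenuation | 0.5 on glucose terms | generator choice |
| insulin rate among reference positives | 0.357 | published cohort |

Glucose triplets are drawn from an equicorrelated trivariate normal. No
between-timepoint correlations are published, so 0.4 is a choice in the
range typical of OGTT curves and is exposed in the config; the decision
rules themselves are distribution-agnostic. The configured means are
*marginal* targets: the base means are lowered by the population-expected
history shift so that history-positive women sit one SD higher without
inflating the cohort means. Under these defaults the reference-standard HIP
prevalence emerges near 12.5% (the emulated cohort's was 11.3%), and
roughly 46% of history-positive women are reference-positive, consistent
with the ~50% recurrence rate reported for HIP.

Outcomes are conditionally independent Bernoulli draws from per-outcome
logistic models in the glucose z-scores and the history flag. Slopes are
modest, plausibility-ordered choices (largest glycemic slopes for LGA and
neonatal hypoglycemia, negative for SGA); intercepts were fixed once by
`calibrate_intercepts` so marginal rates match the published cohort
(composite ≈ 11.6%, LGA 9.4%, preeclampsia 1.7%, …). Because the emulated
study *treated* every woman it diagnosed, a treatment-attenuation factor
(default 0.5) multiplies the glucose terms for reference-positive women,
reproducing the qualitative pattern that treated true positives have
outcome rates closer to normals than their glycemia alone would predict.
Insulin therapy is drawn only among reference positives.

`calibrate_intercepts` root-finds each intercept (Brent's method) against
the *expected* marginal rate over a fixed covariate draw of 200 000 women,
which is smooth and monotone in the intercept; a composite target is met by
a common offset on the four component intercepts. Truncations (glucose
floor at 1 mmol/L, early FPG below the eligibility cutoff) are enforced by
bounded resampling; an infeasible truncation raises rather than looping.

All randomness flows from one `numpy` Generator seeded from the config, and
draw order is fixed, so identical configs give byte-identical cohorts.

### What the generator does and does not show

The generator reproduces marginal moments, prevalences and the
history-glycemia link, so pipeline results on synthetic cohorts exercise
every branch of every rule with realistic frequencies. It does **not**
reproduce: the heavy right tail of real glucose distributions (normal
tails under-produce DIP — a few per 10⁵ women against 0.5% in the real
cohort), correlations among risk factors (age, BMI, parity and ethnicity
are drawn independently, so the high-risk fraction runs above the published
48.3%), between-ethnicity outcome differences, or any causal treatment
effect. Structural test results (zero false positives, sensitivity
orderings, oracle equivalence) are distribution-free; quantitative
synthetic results (e.g. Option 2 sensitivity ≈ 0.79 vs the published 0.72)
are indicative only and shift with the invented correlation parameters.

## Problem sizes

Default test and acceptance runs use cohorts of 5 000 (end-to-end option
evaluation), 20 000 (moment checks), and 100 000 (tight moment recovery),
with 200 000 covariate draws for intercept calibration — sizes at which
Monte-Carlo error is far below every stated tolerance while the whole
suite runs in well under a minute.

## Known limitations

* The FPG-only DIP label for FPG ≥ 7.0 without an OGTT follows the
  reference FPG criterion; a real pathway might confirm with a second test.
* The early-pregnancy screening pathway is represented only by its result
  (the early-FPG eligibility field); no early-diagnosis modelling.
* No preanalytical glucose variability (sample handling can shift FPG by
  more than the 0.1 mmol/L reporting precision).
* Group-comparison p-values on synthetic cohorts inherit the generator's
  simplifications and should not be read as clinical findings.
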
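# Methods

## Problem and data model

The package evaluates how well endogenous-biomarker GFR estimates (eGFR)
reproduce gold-standard measured GFR (mGFR) in living kidney donors, both
at evaluation (cross-sectional) and as a predictor of the 3-month
post-donation value (longitudinal). A donor record carries sex, age,
height, weight, plasma creatinine (µmol/l), plasma cystatin C (mg/l),
optional 24-h urinary creatinine excretion (mmol/24 h, the muscle-mass
surrogate), an optional cystatin assay label, and mGFR before and —
where available — after donation (ml/min/1.73 m²). Canonical units are
fixed at load; the CKD-EPI equations convert creatinine to mg/dl
internally (factor 88.4). Missing optional values are explicit nulls;
every stage works pairwise-complete and reports its effective n.

## Estimating equations

Five CKD-EPI equations (2009 creatinine; 2012 cystatin C; 2012 combined;
2021 race-free creatinine; 2021 race-free combined) and three EKFC
equations (creatinine; cystatin C; combined). The CKD-EPI form is a
product of two-branch power terms per marker, continuous at the
sex-specific threshold κ, times `age_base^age` and a sex multiplier. The
cohort this package targets is all-white and the analysis applies the
equations without any race term; no race field exists in the data model.

EKFC rescales each marker by a healthy-population value Q and applies
`107.3 · (m/Q)^(−0.322)` below m/Q = 1 and exponent −1.132 above, times
`0.990^(age−40)` beyond age 40. Creatinine Q is 62 (women) / 80 (men)
µmol/l from age 25, with the published age polynomial below 25. For
cystatin C the sex-free variant is used (Q = 0.83 mg/l below age 50,
rising 0.005 mg/l per year after); the source study does not state which
variant it used, and the sex-free form is the equation's published main
form. The combined EKFC estimate is the arithmetic mean of the two
single-marker estimates — again a choice the source literature supports
but does not pin down. All coefficients live in
`src/donorgfr/data/equations.yaml` for auditability.

## Measured GFR

Dual-tracer constant infusion: clearance = (U·V)/P urinary and (I·V)/P
plasma. The urinary iothalamate clearance is multiplied by the
plasma/urinary hippurate clearance ratio to cancel urine-collection
errors (incomplete collection depresses both urinary clearances
equally). Multiple steady-state periods are corrected per period and then
averaged arithmetically. Body surface area uses DuBois–DuBois
(`0.007184·h^0.725·w^0.425`); no formula is named by the source study,
but DuBois at the cohort-mean height/weight (174 cm, 80 kg) reproduces
the printed mean BSA of 1.94 m² within 0.01, which fixes the choice.
Indexing multiplies by 1.73/BSA.

## Agreement and association statistics

* Bias = estimate − measured (positive = overestimation); CI from the t
  distribution, mean ± t₀.₉₇₅,ₙ₋₁·SD/√n.
* RMSE of individual biases; note rmse² = mean² + population variance.
* IQR of bias: 25th/75th percentiles with linear interpolation.
* P30/P10: share of estimates strictly within 30%/10% of measured
  (boundary-exact errors count as failures); Wilson score CIs, which stay
  inside [0, 100] near the boundary where these metrics live.
* R² = squared Pearson correlation; the univariable standardized β equals
  Pearson r, its CI from the OLS standard error (and may exceed ±1).
* Post-donation prediction: pre-donation eGFR × compensation factor
  (default 0.66, the documented −34% mean change from pre- to 3-month
  post-donation mGFR reflecting single-kidney hyperfiltration). The
  factor estimator is the mean of per-donor ratios, 1 + mean((post−pre)/pre).
* Nested model: OLS of mGFR on creatinine + age + sex with and without
  cystatin C, partial F-test for the improvement.
* Threshold concordance at 90 and 60 ml/min/1.73 m² counts the 2×2
  classification of eGFR vs mGFR; ties go to the ≥ class.
* No multiplicity correction anywhere: p-values are reported unadjusted,
  as is conventional in this validation literature.

## Muscle-mass subgroup

24-h creatinine excretion indexed by height in meters (exponent
configurable, default 1; the indexing convention is not fully specified
in the source literature). Quartile cut-points are computed within sex
with linear-interpolation percentiles; donors at or beyond the 25th/75th
percentile (boundary ties included) form the extreme strata, and the
subgroup is their union across sexes — so the subgroup can slightly
exceed half the evaluable donors when ties straddle a cut. Donors
missing excretion form their own stratum and take no part in the cuts.
The subgroup rerun goes through the identical pipeline code path as the
full-cohort analysis.

## Synthetic cohort generator

The real cohort is private, so the generator reproduces its statistical
structure mechanistically rather than by drawing biomarkers marginally:

1. sex ~ Bernoulli(0.54 female); age ~ Normal(56, 11) truncated to
   [20, 80]; height ~ Normal(168/180 by sex, 7) cm; BMI ~ Normal(26, 5)
   truncated [17, 45], weight = BMI·(h/100)².
2. True indexed pre-donation mGFR ~ Normal(94, 16) with an age slope of
   −0.6 ml/min/1.73 m² per year inside the total SD (a realistic healthy-
   population decline; the source gives no joint distributions, so the
   slope is a documented calibration choice), floored at 20. Absolute
   GFR = indexed × BSA/1.73.
3. Muscle mass: excretion = sex base (10 women / 15 men mmol/24 h,
   population-typical values) × (BSA/1.94) × lognormal(sd 0.18) —
   independent of GFR given body size.
4. Plasma creatinine from steady-state mass balance: generation
   (= excretion, µmol/min) divided by renal + non-renal clearance, times
   lognormal noise (sd 0.08). The non-renal term (8.1 ml/min, absorbing
   tubular secretion and extrarenal elimination) was solved once, before
   any analysis, so the cohort mean lands on 77 µmol/l.
5. Cystatin C = production / (absolute GFR + 5 ml/min non-renal), times
   lognormal noise (sd 0.10); production 94.4 (mg/l)·ml/min solved the
   same way for a 0.89 mg/l cohort mean. Production is independent of the
   muscle variable by construction.
6. Post-donation mGFR = 0.66 × pre + Normal(0, 6). Additive mean-zero
   noise keeps the mean-of-ratios factor estimator unbiased at exactly
   0.66 in expectation.
7. Assay labels drawn 84%/16% (gentian/roche), stratification-only.

Each field draws from its own substream keyed by (seed, field name), so
adding a field never changes earlier draws and cohorts are
bit-reproducible.

**What the generator does and does not emulate.** Cohort means of age,
sex, anthropometrics, biomarkers and pre/post mGFR match the published
marginals to well under 1% at n = 10,000, and the creatinine–muscle
confound makes the subgroup analysis behave qualitatively like the real
cohort (creatinine-only equations lose association strength in the
extreme quartiles; cystatin-using equations do not). But biomarker SDs
run wider than the real cohort's (creatinine ≈ 24 vs 14 µmol/l) because
muscle mass here is independent of GFR given body size, whereas real
donors embed additional correlations; equation-level biases and P30/P10
on synthetic cohorts therefore do not reproduce the real cohort's table
values and are not meant to. Passing tests demonstrate correctness of
the computational machinery and of the qualitative mechanism, not
clinical performance figures.

## Numerical and design choices

* Percentiles everywhere use linear interpolation between order
  statistics (numpy default); alternates can be layered on if needed.
* Piecewise equations are evaluated with `min/max` so both branches agree
  at the breakpoint to floating-point precision.
* Degenerate inputs fail loudly: non-positive biomarkers/clearances/BSA,
  constant regressors, rank-deficient designs, sex strata with fewer than
  4 evaluable donors, duplicated donor ids.
* Agreement on constant vectors defines R² as 1 for exact equality and 0
  otherwise (correlation undefined).
* The pipeline treats per-stage failures as logged warnings and
  continues; only an empty cohort or an invalid configuration aborts.
* Analysis scripts use n = 486 (the study's cohort size) with seed 1;
  calibration checks use n = 10,000, where Monte-Carlo error on the
  means is ≈ 0.2–0.3%.

## Known limitations

* The generator encodes no assay-level measurement-error differences, no
  inflammation/thyroid non-GFR determinants of cystatin C, and no
  longitudinal trajectory beyond the single 3-month value.
* EKFC-combined as an arithmetic mean and the sex-free cystatin Q are
  literature-supported but unconfirmed choices for this cohort.
* The compensation-factor approach assumes proportional post-donation
  compensation with additive error; donors with unusual single-kidney
  adaptation are not modelled.
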
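# donorgfr

Validation of creatinine- and cystatin C–based GFR estimating equations
against iothalamate-measured GFR in living kidney donors.

Candidate kidney donors need an accurate glomerular filtration rate (GFR)
twice over: to confirm that their current kidney function is sufficient,
and to predict how much function will remain after one kidney is removed.
Measured GFR (mGFR, from exogenous-tracer clearance) is the gold standard
but rarely available; creatinine-based estimates (eGFR) are cheap but
confounded by muscle mass, because plasma creatinine at steady state is
generation (∝ muscle) over clearance (∝ GFR). Cystatin C is produced by
all nucleated cells and is far less muscle-dependent. This package
implements the full evaluation of eight estimating equations against
dual-tracer mGFR in a donor cohort — cross-sectionally before donation and
longitudinally for the 3-month post-donation value — with a dedicated look
at donors with extreme muscle mass.

## What is implemented

- **Equations** (`donorgfr.equations`): CKD-EPI 2009 (creatinine), 2012
  (cystatin C), 2012 (combined), 2021 race-free (creatinine), 2021
  race-free (combined) — each of the form
  `eGFR = a · min(m/κ,1)^α · max(m/κ,1)^β · c^age · (sex factor)` — and the
  EKFC creatinine / cystatin C / combined equations,
  `eGFR = 107.3 · (m/Q)^(−0.322 or −1.132) · 0.990^(age−40)` for ages over
  40, with the biomarker rescaled by the healthy-population value Q.
  Coefficients are shipped as an auditable YAML table
  (`src/donorgfr/data/equations.yaml`). No race term anywhere.
- **Measured GFR** (`donorgfr.clearance`): constant-infusion dual-tracer
  clearance, `(U·V)/P` and `(I·V)/P`, with the urinary ¹²⁵I-iothalamate
  clearance corrected for urine-collection errors by the plasma/urinary
  ¹³¹I-hippurate clearance ratio, and DuBois body-surface-area indexing to
  1.73 m².
- **Agreement statistics** (`donorgfr.metrics`): bias (eGFR − mGFR) with
  t-based CI, RMSE, IQR of bias, P30/P10 with Wilson CIs, R², standardized
  β (= Pearson r) with CI, the ×0.66 compensation-factor prediction of
  post-donation GFR, a partial-F nested-model test for the added value of
  cystatin C, threshold concordance at 90/60 ml/min/1.73 m², and
  Bland–Altman data.
- **Muscle-mass subgroup** (`donorgfr.subgroup`): sex-stratified extreme
  quartiles of height-indexed 24-h urinary creatinine excretion.
- **Synthetic cohorts** (`donorgfr.simulate`): a mechanistic generator —
  true GFR → steady-state creatinine (muscle-dependent) and cystatin C
  (muscle-independent) → post-donation compensation — calibrated to the
  published cohort marginals, so every analysis runs without the private
  data.
- **Pipeline** (`donorgfr.pipeline`, CLI `donorgfr`): one-call orchestration
  with deterministic outputs, subgroup and stratified sensitivity reruns.

## Worked example

```python
from donorgfr import evaluate_equation, predict_post, agreement

# 56-year-old woman, creatinine 80 umol/l, cystatin C 0.89 mg/l
for eq in ("ckdepi_2009_creat", "ckdepi_2012_cys", "ckdepi_2021_comb"):
    print(eq, round(evaluate_equation(eq, "female", 56, creatinine=80.0,
                                      cystatin_c=0.89), 1))
# ckdepi_2009_creat 71.0
# ckdepi_2012_cys 86.0
# ckdepi_2021_comb 83.6
print(round(predict_post(94.0, 0.66), 2))   # 62.04  expected post-donation GFR
```

The creatinine-only estimate (71) sits 15 ml/min/1.73 m² below the
cystatin C one (86) for the same person — the kind of muscle-mass-driven
divergence the combined equations are meant to resolve. Multiplying a
pre-donation GFR of 94 by the 0.66 compensation factor predicts
62 ml/min/1.73 m² three months after nephrectomy.

The scripted analysis (run in order; outputs land under `results/`):

```sh
python analysis/01_generate_cohort.py     # 486-donor synthetic cohort
python analysis/02_run_validation.py      # association + accuracy reports
python analysis/03_muscle_subgroup.py     # extreme-quartile subgroup rerun
python analysis/04_sensitivity_strata.py  # sex / assay stratified reruns
python analysis/05_calibration_check.py   # generator vs published marginals
```

On the default cohort, `02_run_validation.py` prints e.g. a cross-sectional
bias of +0.4 ml/min/1.73 m² with P30 98.8% for the combined 2021 equation
versus −5.7 and 87.2% for the 2009 creatinine equation, and
`03_muscle_subgroup.py` shows the creatinine-only equations' Sβ dropping to
≈0.51 in the extreme muscle-mass subgroup while cystatin-using equations
hold ≈0.72 — the qualitative signature the study design probes.

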
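#!/usr/bin/env python
"""Run the full equation-validation analysis on the generated cohort.

Evaluates all eight eGFR equations per donor, then computes the
association report (standardized β of each equation and raw biomarker vs
pre- and post-donation measured GFR), the accuracy report (bias, RMSE,
IQR of bias, P30/P10 — cross-sectional and with the ×0.66 post-donation
prediction), threshold concordance at 90/60 ml/min/1.73 m², Bland–Altman
data, and the nested-model test of adding cystatin C to a
creatinine + age + sex model.

Reads results/cohort.csv (run 01 first); writes under results/validation/.
"""

from donorgfr import RunConfig, run_analysis

if __name__ == "__main__":
    config = RunConfig(cohort_path="results/cohort.csv", subgroup=False,
                       output_dir="results/validation")
    bundle = run_analysis(config)
    acc = bundle["accuracy"]
    print("cross-sectional accuracy (eGFR vs pre-donation mGFR):")
    for _, row in acc[acc.block == "cross_sectional"].iterrows():
        print(f"  {row.equation:18s} bias {row.bias:+6.2f}  rmse {row.rmse:5.2f}  "
              f"P30 {row.p30:5.1f}%  P10 {row.p10:5.1f}%  R2 {row.r2:.2f}")
    print("longitudinal accuracy (0.66 x eGFR vs post-donation mGFR):")
    for _, row in acc[acc.block == "longitudinal"].iterrows():
        print(f"  {row.equation:18s} bias {row.bias:+6.2f}  rmse {row.rmse:5.2f}  "
              f"P30 {row.p30:5.1f}%  P10 {row.p10:5.1f}%")
    nm = bundle["nested_model"]
    for _, row in nm.iterrows():
        print(f"adding cystatin C to creatinine+age+sex for {row.outcome}: "
              f"R2 {row.r2_base:.2f} -> {row.r2_full:.2f} (p={row.p_improvement:.2g})")
    print("reports written to results/validation/")
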
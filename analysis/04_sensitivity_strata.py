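#!/usr/bin/env python
"""Sensitivity analyses: stratified reruns by sex and cystatin C assay.

Repeats the univariable association analysis within each sex and within
each assay label and prints a side-by-side Sβ comparison; results should
be similar across strata when the equations behave homogeneously.

Reads results/cohort.csv; writes under results/sensitivity/.
"""

from donorgfr import RunConfig, stratified_rerun

if __name__ == "__main__":
    for column in ("sex", "cystatin_assay"):
        config = RunConfig(cohort_path="results/cohort.csv", subgroup=False,
                           output_dir=f"results/sensitivity/{column}")
        bundles = stratified_rerun(config, column)
        comp = bundles["comparison"]
        pre = comp[(comp.outcome == "mgfr_pre")]
        pivot = pre.pivot(index="predictor", columns="stratum", values="sbeta").round(3)
        print(f"\nSbeta vs pre-donation mGFR, stratified by {column}:")
        print(pivot.to_string())
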
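"""End-to-end analysis: equations → agreement reports → subgroup/strata.

``run_analysis`` produces, from one cohort and one configuration:

(a) an association report — univariable standardized β, R² and p of each
    equation (and of the raw biomarkers) against pre-donation measured
    GFR, and against post-donation measured GFR where available;
(b) an accuracy report — bias ± CI, RMSE, IQR of bias, P30/P10 ± CI and
    R² per equation, cross-sectionally (eGFR vs pre-donation mGFR) and
    longitudinally (compensation factor × eGFR vs post-donation mGFR);
(c) threshold-concordance counts at 90 and 60 ml/min/1.73 m²;
(d) Bland–Altman data per equation;
(e) the nested-model comparison (creatinine + age + sex, with vs without
    cystatin C) for both outcomes;
(f) a run log with the effective n of every stage and a machine-readable
    manifest.

All stages use pairwise-complete rows and report their effective n; a
stage that cannot run (e.g. no post-donation values) is logged and
skipped, the remaining stages continue.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import FEMALE, CohortTable, read_cohort
from .equations import ALL_EQUATIONS, apply_all_equations, equation_markers
from .metrics import (AnalysisConfig, agreement, bland_altman_data,
                      estimate_compensation_factor, nested_model_test,
                      predict_post, threshold_concordance,
                      univariable_regression)
from .simulate import SyntheticParams, generate_cohort
from .subgroup import extreme_subgroup

log = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """One analysis run: input source, analysis knobs, outputs."""

    cohort_path: str | None = None
    synthetic: SyntheticParams | None = None
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)
    subgroup: bool = True
    stratify_columns: tuple[str, ...] = ()
    output_dir: str = "results/run"

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.synthetic is None):
            raise PipelineError("exactly one of cohort_path or synthetic must be set")


def _load(config: RunConfig) -> CohortTable:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    return generate_cohort(config.synthetic)


def _association_block(cohort: CohortTable, egfr_wide: pd.DataFrame,
                       outcome: str, cfg: AnalysisConfig) -> pd.DataFrame:
    """Sβ/R²/p of every equation and raw biomarker against one mGFR outcome."""
    df = cohort.df.set_index("donor_id")
    y_all = df[outcome]
    rows = []
    predictors = {name: egfr_wide[name] if name in egfr_wide else None
                  for name in ALL_EQUATIONS}
    predictors["plasma_cystatin_c"] = df["plasma_cystatin_c"]
    predictors["plasma_creatinine"] = df["plasma_creatinine"]
    for name, x in predictors.items():
        if x is None:
            continue
        pair = pd.concat([x, y_all], axis=1, keys=["x", "y"]).dropna()
        if len(pair) < 3:
            log.warning("association %s vs %s skipped (n=%d)", name, outcome, len(pair))
            continue
        s = univariable_regression(pair["x"], pair["y"], cfg.ci_level)
        rows.append({"predictor": name, "outcome": outcome, "sbeta": s.sbeta,
                     "sbeta_ci_low": s.sbeta_ci[0], "sbeta_ci_high": s.sbeta_ci[1],
                     "r2": s.r2, "p_value": s.p_value, "n": s.n})
    return pd.DataFrame(rows)


def _accuracy_block(cohort: CohortTable, egfr_wide: pd.DataFrame,
                    cfg: AnalysisConfig, longitudinal: bool) -> pd.DataFrame:
    df = cohort.df.set_index("donor_id")
    outcome = "mgfr_post" if longitudinal else "mgfr_pre"
    rows = []
    for name in ALL_EQUATIONS:
        if name not in egfr_wide:
            continue
        pred = egfr_wide[name].dropna()
        if longitudinal:
            pred = pd.Series(predict_post(pred.to_numpy(), cfg.compensation_factor),
                             index=pred.index)
        pair = pd.concat([pred, df[outcome]], axis=1, keys=["pred", "obs"]).dropna()
        if len(pair) < 2:
            log.warning("accuracy %s vs %s skipped (n=%d)", name, outcome, len(pair))
            continue
        rep = agreement(pair["pred"], pair["obs"], cfg.ci_level)
        rows.append({"equation": name, "block": "longitudinal" if longitudinal else "cross_sectional",
                     **rep.as_row()})
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig, cohort: CohortTable | None = None) -> dict:
    """Run the full validation and write the report bundle to ``output_dir``.

    Returns the bundle as a dict of DataFrames/dicts (also written as CSV
    and JSON files).  ``cohort`` can be passed directly to bypass loading.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    loglines: list[str] = []

    def note(msg: str) -> None:
        loglines.append(f"{datetime.now(timezone.utc).isoformat()} {msg}")
        log.info(msg)

    if cohort is None:
        cohort = _load(config)
    if len(cohort) == 0:
        raise PipelineError("empty cohort")
    note(f"cohort loaded: n={len(cohort)} ({cohort.provenance})")

    cfg = config.analysis
    long_egfr = apply_all_equations(cohort)
    egfr_wide = long_egfr.pivot(index="donor_id", columns="equation", values="egfr") \
        .reindex(cohort.df["donor_id"])
    note(f"equations evaluated: {len(long_egfr)} donor×equation values")

    df = cohort.df.set_index("donor_id")
    bundle: dict = {}

    # (a) association report, pre and post
    assoc = [_association_block(cohort, egfr_wide, "mgfr_pre", cfg)]
    n_post = int(df["mgfr_post"].notna().sum())
    if n_post >= 3:
        assoc.append(_association_block(cohort, egfr_wide, "mgfr_post", cfg))
    else:
        note("longitudinal association block absent: no post-donation mGFR")
    bundle["association"] = pd.concat(assoc, ignore_index=True)
    note(f"association report: {len(bundle['association'])} rows "
         f"(effective n pre={int(df['mgfr_pre'].notna().sum())}, post={n_post})")

    # compensation factor observed in this cohort, for the log
    paired = df[["mgfr_pre", "mgfr_post"]].dropna()
    if len(paired) >= 2:
        fac, pct = estimate_compensation_factor(paired["mgfr_pre"], paired["mgfr_post"])
        note(f"observed compensation factor {fac:.4f} (mean change {pct:+.1f}%), n={len(paired)}; "
             f"configured factor {cfg.compensation_factor}")
        bundle["compensation"] = {"estimated_factor": fac, "mean_percent_change": pct,
                                  "configured_factor": cfg.compensation_factor, "n": len(paired)}

    # (b) accuracy report
    acc = [_accuracy_block(cohort, egfr_wide, cfg, longitudinal=False)]
    if n_post >= 2:
        acc.append(_accuracy_block(cohort, egfr_wide, cfg, longitudinal=True))
    else:
        note("longitudinal accuracy block absent: no post-donation mGFR")
    bundle["accuracy"] = pd.concat(acc, ignore_index=True)

    # (c) threshold concordance, per equation, pre-donation
    conc_rows = []
    for name in ALL_EQUATIONS:
        pair = pd.concat([egfr_wide[name], df["mgfr_pre"]], axis=1).dropna()
        if len(pair) == 0:
            continue
        tab = threshold_concordance(pair[name], pair["mgfr_pre"], cfg.thresholds)
        tab.insert(0, "equation", name)
        conc_rows.append(tab)
    bundle["threshold_concordance"] = pd.concat(conc_rows, ignore_index=True)

    # (d) Bland–Altman data
    ba_frames = []
    for name in ALL_EQUATIONS:
        pair = pd.concat([egfr_wide[name], df["mgfr_pre"]], axis=1).dropna()
        if len(pair) == 0:
            continue
        tab, summ = bland_altman_data(pair[name], pair["mgfr_pre"])
        tab.insert(0, "equation", name)
        tab.insert(1, "donor_id", pair.index)
        for k, v in summ.items():
            tab[k] = v
        ba_frames.append(tab)
    bundle["bland_altman"] = pd.concat(ba_frames, ignore_index=True)

    # (e) nested model: creatinine + age + sex, +/- cystatin C
    nested_rows = []
    for outcome in ("mgfr_pre", "mgfr_post"):
        cols = df[["plasma_creatinine", "age", "sex", "plasma_cystatin_c", outcome]].dropna()
        if len(cols) < 6:
            note(f"nested-model block for {outcome} absent (n={len(cols)})")
            continue
        base_cols = [cols["plasma_creatinine"], cols["age"]]
        if cols["sex"].nunique() > 1:
            base_cols.append((cols["sex"] == FEMALE).astype(float))
        else:
            note(f"nested model for {outcome}: sex constant in this cohort, term dropped")
        try:
            r2b, r2f, pval = nested_model_test(cols[outcome], np.column_stack(base_cols),
                                               cols["plasma_cystatin_c"])
        except Exception as exc:
            note(f"nested-model stage for {outcome} failed: {exc}")
            continue
        nested_rows.append({"outcome": outcome, "r2_base": r2b, "r2_full": r2f,
                            "p_improvement": pval, "n": len(cols)})
    bundle["nested_model"] = pd.DataFrame(nested_rows)

    # subgroup rerun through the identical code path
    if config.subgroup:
        try:
            sub = extreme_subgroup(cohort)
            note(f"muscle-mass extreme-quartile subgroup: n={len(sub)}")
            subcfg = dataclasses.replace(config, subgroup=False, stratify_columns=(),
                                         output_dir=str(out / "subgroup"))
            bundle["subgroup"] = run_analysis(subcfg, cohort=sub)
        except Exception as exc:  # stage failures logged, run continues
            note(f"subgroup stage failed: {exc}")

    # sensitivity strata
    for column in config.stratify_columns:
        try:
            bundle[f"strata_{column}"] = stratified_rerun(config, column, cohort=cohort)
        except Exception as exc:
            note(f"stratified rerun on {column!r} failed: {exc}")

    # write everything
    for key in ("association", "accuracy", "threshold_concordance", "bland_altman", "nested_model"):
        bundle[key].to_csv(out / f"{key}.csv", index=False)
    manifest = {
        "package_version": __version__,
        "provenance": cohort.provenance,
        "n_cohort": len(cohort),
        "n_post": n_post,
        "compensation_factor": cfg.compensation_factor,
        "thresholds": list(cfg.thresholds),
        "seed": config.synthetic.seed if config.synthetic else None,
        "artifacts": ["association.csv", "accuracy.csv", "threshold_concordance.csv",
                      "bland_altman.csv", "nested_model.csv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "run_log.txt").write_text("\n".join(loglines) + "\n")
    bundle["manifest"] = manifest
    bundle["log"] = loglines
    return bundle


def stratified_rerun(config: RunConfig, column: str,
                     cohort: CohortTable | None = None) -> dict:
    """Re-run the analysis within each level of ``column`` (e.g. sex, assay).

    Returns ``{stratum: bundle}`` plus a ``comparison`` table of Sβ across
    strata.  Strata with fewer than 3 donors are skipped with a warning.
    """
    if cohort is None:
        cohort = _load(config)
    if column not in cohort.df.columns:
        raise PipelineError(f"stratification column {column!r} not in cohort")
    levels = cohort.df[column].dropna().unique()
    if len(levels) < 2:
        raise PipelineError(f"column {column!r} has fewer than 2 strata")
    out = Path(config.output_dir)
    bundles: dict = {}
    for level in sorted(map(str, levels)):
        mask = cohort.df[column].astype(str) == level
        if int(mask.sum()) < 3:
            log.warning("stratum %s=%s skipped (n=%d)", column, level, int(mask.sum()))
            continue
        sub = CohortTable(cohort.df[mask.values],
                          provenance=f"{cohort.provenance} | {column}={level}")
        subcfg = dataclasses.replace(config, subgroup=False, stratify_columns=(),
                                     output_dir=str(out / f"stratum_{column}_{level}"))
        bundles[level] = run_analysis(subcfg, cohort=sub)
    comparison = []
    for level, bundle in bundles.items():
        assoc = bundle["association"].copy()
        assoc.insert(0, "stratum", level)
        comparison.append(assoc)
    if comparison:
        comp = pd.concat(comparison, ignore_index=True)
        comp.to_csv(out / f"strata_comparison_{column}.csv", index=False)
        bundles["comparison"] = comp
    return bundles
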
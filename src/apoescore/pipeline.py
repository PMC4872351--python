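"""End-to-end analysis pipeline: simulate/load -> QC -> association ->
LD -> preventive score -> multivariable models -> consolidated report.

Each stage writes its tables (plain TSV) and a machine-readable JSON
summary before the next stage starts, so partial output survives a
failing stage; the final ``report.txt`` only restates stage outputs.
Given the same seed and input the whole bundle is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (
    GROUP_CASE,
    GROUP_CONTROL,
    Cohort,
    SNPSummary,
    UndefinedStatisticError,
    ValidationError,
    filter_by_maf,
    summarize_panel,
)
from .io import read_cohort_tsv, write_cohort_tsv
from .ld import compound_genotype_or, pairwise_ld_matrix, risk_genotype_predicate
from .model import (
    DEFAULT_CANDIDATES,
    DesignSpec,
    Predictor,
    best_subsets,
    build_features,
    stratified_fits,
)
from .score import (
    DEFAULT_SCORE_TABLE,
    ScoreTable,
    max_score,
    score_cohort,
    score_correlations,
    score_group_comparison,
)
from .simulate import SimulationConfig, default_config, simulate_cohort
from .stats import adjust_family, hwe_test, marker_association

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input source)."""

    input_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    maf_threshold: float = 0.05
    bonferroni_m: Optional[int] = None
    score_table: ScoreTable = field(default_factory=lambda: DEFAULT_SCORE_TABLE)
    candidates: list[Predictor] = field(
        default_factory=lambda: list(DEFAULT_CANDIDATES))
    criterion: str = "aic"
    out_dir: str = "apoescore_out"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValidationError(
                "exactly one of input_path / simulation must be given")
        if not 0 < self.maf_threshold <= 0.5:
            raise ValidationError("maf_threshold must be in (0, 0.5]")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True)
                    + "\n")


def _fmt(x, digits=4):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.{digits}g}" if isinstance(x, float) else str(x)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the consolidated summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed}
    report: list[str] = [f"apoescore {__version__} analysis report", ""]

    # --- stage: input -----------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None:
            from dataclasses import replace
            sim = replace(sim, seed=config.seed)
        cohort = simulate_cohort(sim)
        write_cohort_tsv(cohort, out / "cohort.tsv",
                         header_comments=[f"simulated cohort, seed={sim.seed}",
                                          f"apoescore {__version__}"])
        sim.to_yaml(out / "simulation_config.yaml")
        source = f"simulated (seed={sim.seed})"
    else:
        cohort = read_cohort_tsv(config.input_path)
        source = str(config.input_path)
    summary["input"] = {"source": source, "n_case": cohort.n_case,
                        "n_control": cohort.n_control,
                        "n_markers": len(cohort.panel)}
    report += [f"Input: {source}",
               f"Subjects: {cohort.n_case} cases / {cohort.n_control} controls; "
               f"{len(cohort.panel)} markers", ""]

    # --- stage: QC (summaries, HWE, MAF filter) ---------------------------
    summaries = summarize_panel(cohort)
    retained, excluded = filter_by_maf(summaries, config.maf_threshold)
    qc_rows = []
    for s in summaries:
        hwe = {}
        for group in (GROUP_CASE, GROUP_CONTROL):
            try:
                hwe[group] = hwe_test(s.genotype_counts[group], mode="auto")
            except UndefinedStatisticError:
                hwe[group] = None
        qc_rows.append({
            "rsid": s.snp.rsid, "label": s.snp.label,
            "minor_allele": s.snp.minor_allele,
            "maf_case": s.maf_case, "maf_control": s.maf_control,
            "maf_pooled": s.maf_pooled, "call_rate": s.call_rate,
            "retained": s in retained,
            "hwe_p_case": hwe[GROUP_CASE].p_value if hwe[GROUP_CASE] else np.nan,
            "hwe_p_control": (hwe[GROUP_CONTROL].p_value
                              if hwe[GROUP_CONTROL] else np.nan),
        })
    qc_df = pd.DataFrame(qc_rows)
    qc_df.to_csv(out / "qc.tsv", sep="\t", index=False, float_format="%.6g")
    summary["qc"] = {"n_retained": len(retained), "n_excluded": len(excluded),
                     "retained": [s.snp.rsid for s in retained],
                     "excluded": [s.snp.rsid for s in excluded],
                     "maf_threshold": config.maf_threshold}
    report += [f"QC: {len(retained)} of {len(summaries)} markers retained at "
               f"pooled MAF >= {config.maf_threshold:.0%}: "
               + ", ".join(s.snp.rsid for s in retained), ""]

    retained_snps = [s.snp for s in retained]
    if not retained_snps:
        log.warning("no markers retained; downstream marker stages skipped")
        report.append("No markers retained: association, LD and score stages "
                      "skipped.")
        pd.DataFrame(columns=["marker", "model", "odds_ratio", "ci_low",
                              "ci_high", "p_raw", "p_adjusted", "test",
                              "notes"]).to_csv(out / "assoc.tsv", sep="\t",
                                               index=False)
        summary["association"] = {"rows": []}
        summary["warnings"] = ["empty retained panel"]
        _finalize(out, summary, report)
        return summary

    # --- stage: association ----------------------------------------------
    assoc_rows = []
    allele_results = []
    for snp in retained_snps:
        for model_name in ("allele", "genotypic", "dominant"):
            try:
                res = marker_association(cohort, snp, model=model_name)
            except UndefinedStatisticError as exc:
                log.info("association %s (%s) undefined: %s",
                         snp.rsid, model_name, exc)
                continue
            if model_name == "allele":
                allele_results.append(res)
            assoc_rows.append(res)
    adjust_family(allele_results,
                  m=config.bonferroni_m or len(allele_results))
    assoc_df = pd.DataFrame([{
        "marker": r.marker_or_factor, "model": r.model,
        "odds_ratio": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "p_raw": r.p_raw, "p_adjusted": r.p_adjusted, "test": r.test_used,
        "notes": ";".join(r.notes),
    } for r in assoc_rows])
    assoc_df.to_csv(out / "assoc.tsv", sep="\t", index=False,
                    float_format="%.6g")
    summary["association"] = {"rows": assoc_df.to_dict(orient="records")}
    report.append("Per-marker association (allele model):")
    for r in allele_results:
        report.append(
            f"  {r.marker_or_factor}: OR {_fmt(r.odds_ratio, 3)} "
            f"(95% CI {_fmt(r.ci_low, 3)}-{_fmt(r.ci_high, 3)}), "
            f"p {_fmt(r.p_raw, 3)} (adj {_fmt(r.p_adjusted, 3)})")
    report.append("")

    # --- stage: LD ---------------------------------------------------------
    ld_rows = []
    if len(retained_snps) >= 2:
        ld = pairwise_ld_matrix(cohort, retained_snps)
        for (a, b), st in ld.items():
            ld_rows.append({
                "marker1": a, "marker2": b,
                "D": st.D if st else np.nan,
                "D_prime": st.D_prime if st else np.nan,
                "r2": st.r2 if st else np.nan,
                "lod": st.lod if st else np.nan,
                "n": st.n if st else 0,
            })
    ld_df = pd.DataFrame(ld_rows)
    ld_df.to_csv(out / "ld.tsv", sep="\t", index=False, float_format="%.6g")
    summary["ld"] = {"n_pairs": len(ld_rows)}
    try:
        comp = compound_genotype_or(cohort, risk_genotype_predicate,
                                    name="-491AA/-219TT/E4")
        summary["ld"]["compound_genotype"] = {
            "name": comp.marker_or_factor, "odds_ratio": comp.odds_ratio,
            "ci_low": comp.ci_low, "ci_high": comp.ci_high,
            "notes": comp.notes}
        report.append(f"Compound genotype -491AA/-219TT/E4: OR "
                      f"{_fmt(comp.odds_ratio, 3)} (95% CI "
                      f"{_fmt(comp.ci_low, 3)}-{_fmt(comp.ci_high, 3)})")
    except UndefinedStatisticError as exc:
        log.info("compound genotype OR undefined: %s", exc)
        summary["ld"]["compound_genotype"] = None
    report.append(f"LD pairs computed: {len(ld_rows)}")
    report.append("")

    # --- stage: score -------------------------------------------------------
    scores = score_cohort(cohort, config.score_table)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False,
                  float_format="%.6g")
    score_summary: dict = {"max_score": max_score(config.score_table)}
    try:
        comparison = score_group_comparison(cohort, config.score_table)
        correlations = score_correlations(cohort, config.score_table)
        score_summary.update({
            "mean_case": comparison.mean_case,
            "mean_control": comparison.mean_control,
            "sd_case": comparison.sd_case, "sd_control": comparison.sd_control,
            "mann_whitney_p": comparison.test.p_value,
            "n_scored": comparison.n_scored,
            "correlations": {k: {"rho": t.effect, "p": t.p_value,
                                 "note": t.note}
                             for k, t in correlations.items()},
        })
        report.append(
            f"Preventive score: mean {comparison.mean_case:.3f} (cases) vs "
            f"{comparison.mean_control:.3f} (controls), Mann-Whitney p "
            f"{_fmt(comparison.test.p_value, 3)}")
        for k, t in correlations.items():
            report.append(f"  Spearman rho(score, {k}) = {_fmt(t.effect, 3)}"
                          f" (p {_fmt(t.p_value, 3)}) {t.note}")
    except UndefinedStatisticError as exc:
        log.info("score comparison undefined: %s", exc)
        score_summary["error"] = str(exc)
    summary["score"] = score_summary
    _write_json(out / "score_summary.json", score_summary)
    report.append("")

    # --- stage: multivariable model ----------------------------------------
    features = build_features(cohort, config.score_table)
    available = [p for p in config.candidates if p.name in features.columns]
    search = best_subsets(features, available, criterion=config.criterion)
    models_df = pd.DataFrame([{
        "terms": "+".join(terms) if terms else "(intercept only)",
        "k": len(terms), "loglik": fit.loglik,
        config.criterion: fit.criterion, "n_used": fit.n_used,
        "converged": fit.converged, "warnings": ";".join(fit.warnings),
    } for terms, fit in search.ranking])
    models_df.to_csv(out / "models.tsv", sep="\t", index=False,
                     float_format="%.6g")
    best = search.best
    best_payload = {
        "terms": list(search.best_terms),
        "criterion_name": best.criterion_name,
        "criterion": best.criterion, "loglik": best.loglik,
        "n_used": best.n_used, "converged": best.converged,
        "warnings": best.warnings,
        "estimates": {t: {"coefficient": best.coefficients[t],
                          "odds_ratio": best.or_per_term[t],
                          "ci_low": best.ci_per_term[t][0],
                          "ci_high": best.ci_per_term[t][1],
                          "p": best.p_per_term[t]}
                      for t in best.terms},
    }
    _write_json(out / "best_model.json", best_payload)
    design = DesignSpec(predictors=[p for p in available
                                    if p.name in search.best_terms])
    strata = stratified_fits(cohort, design, criterion=config.criterion,
                             score_table=config.score_table)
    strata_payload = {
        name: None if fit is None else {
            "n_used": fit.n_used,
            "or_per_term": fit.or_per_term,
            "warnings": fit.warnings,
        } for name, fit in strata.items()}
    _write_json(out / "strata.json", strata_payload)
    summary["model"] = {"n_models": len(search.ranking),
                        "best": best_payload, "strata": strata_payload}
    report.append(f"Best-subsets search ({config.criterion.upper()}, "
                  f"{len(search.ranking)} models): best = "
                  + (" + ".join(search.best_terms) or "(intercept only)"))
    for t in best.terms:
        if t == "intercept":
            continue
        lo, hi = best.ci_per_term[t]
        report.append(f"  {t}: OR {_fmt(best.or_per_term[t], 3)} "
                      f"(95% CI {_fmt(lo, 3)}-{_fmt(hi, 3)}), "
                      f"p {_fmt(best.p_per_term[t], 3)}")
    report.append("")

    _finalize(out, summary, report)
    return summary


def _finalize(out: Path, summary: dict, report: list[str]) -> None:
    _write_json(out / "summary.json", summary)
    (out / "report.txt").write_text("\n".join(report) + "\n")


def default_run_config(seed: int = 0, out_dir: str = "apoescore_out",
                       n_case: int = 110, n_control: int = 110) -> RunConfig:
    return RunConfig(simulation=default_config(n_case, n_control, seed=seed),
                     out_dir=out_dir, seed=seed)
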
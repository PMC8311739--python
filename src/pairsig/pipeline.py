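"""End-to-end orchestration and the run report.

:func:`run_pipeline` chains the stages — screen -> differential
expression -> pair matrix -> prevalence filter -> selection funnel ->
risk model -> clinical validation -> external associations — on
in-memory objects, collecting the stage counts (the funnel) into a
``RunReport``.  The CLI wraps this around file I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import associations as assoc_mod
from .io import ClinicalTable, ExpressionMatrix
from .pairs import build_pairs, prevalence_filter
from .risk import build_assignment
from .screen import de_screen, screen_irlncrnas
from .selection import PRESETS, select_signature
from .validate import (
    chisq_association,
    independence_cox,
    score_by_stratum,
    survival_comparison,
)

logger = logging.getLogger("pairsig")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, echoed into the run report."""

    r_threshold: float = 0.6
    coexpr_p_threshold: float = 0.001
    coexpr_mode: str = "absolute"
    coexpr_samples: str = "all"
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    de_method: str = "wilcoxon"
    min_frac: float = 0.2
    screen_p: float = 0.01
    repetitions: int = 1000
    folds: int = 10
    freq_threshold: int = 100
    cutpoint_horizon: float = 5.0
    horizons: tuple = (1.0, 3.0, 5.0)
    alpha: float = 0.05
    days_per_year: float = 365.25
    seed: int = 0

    @classmethod
    def preset(cls, name: str, **overrides) -> "PipelineConfig":
        reps, freq = PRESETS[name]
        return cls(repetitions=reps, freq_threshold=freq, **overrides)


@dataclass
class RunReport:
    """Stage-count funnel plus thresholds and seeds, for the run log."""

    config: PipelineConfig
    counts: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["# pairsig run report", "## thresholds"]
        for k, v in vars(self.config).items():
            lines.append(f"{k}\t{v}")
        lines.append("## stage counts")
        for k, v in self.counts.items():
            lines.append(f"{k}\t{v}")
        return "\n".join(lines) + "\n"


def run_pipeline(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    immune_genes,
    config: PipelineConfig | None = None,
    infiltration: pd.DataFrame | None = None,
    ic50: pd.DataFrame | None = None,
    ici: pd.DataFrame | None = None,
) -> dict:
    """Run every stage; returns a dict of results keyed by stage.

    Keys: ``coexpression``, ``de``, ``pair_matrix``, ``model``,
    ``trace``, ``signature_report``, ``assignment``, ``km``,
    ``clin_assoc``, ``score_strata``, ``cox_univariate``,
    ``cox_multivariate``, ``report`` and (when the optional tables are
    given) ``immune_assoc``/``immune_spearman``/``chemo_assoc``/
    ``ici_assoc``.
    """
    cfg = config or PipelineConfig()
    report = RunReport(config=cfg)
    counts = report.counts

    coexpr = screen_irlncrnas(
        expr,
        immune_genes,
        r_threshold=cfg.r_threshold,
        p_threshold=cfg.coexpr_p_threshold,
        mode=cfg.coexpr_mode,
        samples=cfg.coexpr_samples,
    )
    irlnc = [r.lncrna for r in coexpr if r.passed]
    counts["n_lncrna_tested"] = len(coexpr)
    counts["n_irlncrna"] = len(irlnc)
    if not irlnc:
        raise ValueError("screen stage: no immune-related lncRNA passed")

    de = de_screen(
        expr,
        lncrnas=irlnc,
        lfc_threshold=cfg.lfc_threshold,
        fdr_threshold=cfg.fdr_threshold,
        method=cfg.de_method,
    )
    de_genes = [r.lncrna for r in de if r.passed]
    counts["n_deirlncrna"] = len(de_genes)
    counts["n_de_up"] = sum(1 for r in de if r.passed and r.direction == "up")
    counts["n_de_down"] = sum(1 for r in de if r.passed and r.direction == "down")
    if len(de_genes) < 2:
        raise ValueError("DE stage: fewer than 2 DEirlncRNAs")

    tumor_samples = [s for s in expr.sample_ids if expr.sample_condition[s] == "tumor"]
    pm_all = build_pairs(expr, de_genes, samples=tumor_samples)
    counts["n_pairs"] = len(pm_all.pair_ids)
    pm = prevalence_filter(pm_all, min_frac=cfg.min_frac)
    counts["n_valid_pairs"] = len(pm.pair_ids)

    model, trace, sig_report = select_signature(
        pm,
        clinical,
        p_threshold=cfg.screen_p,
        repetitions=cfg.repetitions,
        folds=cfg.folds,
        freq_threshold=cfg.freq_threshold,
        seed=cfg.seed,
    )
    counts["n_univariate_pass"] = len(trace.stage1_pairs)
    counts["n_lasso_pass"] = len(trace.stage2_pairs)
    counts["k_signature"] = model.k

    assignment = build_assignment(
        model,
        pm,
        clinical,
        cutpoint_horizon=cfg.cutpoint_horizon,
        horizons=cfg.horizons,
        days_per_year=cfg.days_per_year,
    )
    counts["cutpoint"] = round(assignment.cutpoint, 6)
    counts["n_high_risk"] = assignment.n_high
    counts["n_low_risk"] = assignment.n_low

    km = survival_comparison(assignment, clinical)
    counts["logrank_p"] = float(km.p)

    clin_assoc_rows = []
    strata_frames = []
    common = [s for s in assignment.group.index if s in clinical.data.index]
    for cov in ("age", "sex", "grade", "stage"):
        if cov not in clinical.data.columns:
            continue
        series = clinical.data.loc[common, cov]
        if cov == "age":
            series = pd.cut(series, bins=[0, 65, 200], labels=["<=65", ">65"]).rename("age")
        try:
            clin_assoc_rows.append(
                {
                    k: v
                    for k, v in chisq_association(
                        assignment.group.loc[common], series
                    ).items()
                    if k != "table"
                }
            )
        except ValueError as exc:
            logger.warning("chi-square for %s skipped: %s", cov, exc)
        try:
            strata_frames.append(
                score_by_stratum(assignment.scores.loc[common], series)
            )
        except ValueError as exc:
            logger.warning("score-by-stratum for %s skipped: %s", cov, exc)
    clin_assoc = pd.DataFrame(clin_assoc_rows)
    score_strata = (
        pd.concat(strata_frames, ignore_index=True) if strata_frames else pd.DataFrame()
    )

    cox_uni, cox_multi = independence_cox(assignment.scores, clinical)

    results = {
        "coexpression": coexpr,
        "de": de,
        "pair_matrix": pm,
        "model": model,
        "trace": trace,
        "signature_report": sig_report,
        "assignment": assignment,
        "km": km,
        "clin_assoc": clin_assoc,
        "score_strata": score_strata,
        "cox_univariate": cox_uni,
        "cox_multivariate": cox_multi,
    }

    if infiltration is not None:
        tbl = assoc_mod.read_feature_table(infiltration, source="infiltration")
        imm = assoc_mod.group_feature_tests(tbl, assignment, alpha=cfg.alpha)
        results["immune_assoc"] = assoc_mod.add_consensus(imm)
        results["immune_spearman"] = assoc_mod.spearman_risk_correlation(
            tbl, assignment.scores, alpha=cfg.alpha
        )
        counts["n_immune_significant"] = int(imm["significant"].sum())
    if ic50 is not None:
        tbl = assoc_mod.read_feature_table(ic50, source="ic50")
        results["chemo_assoc"] = assoc_mod.group_feature_tests(
            tbl, assignment, alpha=cfg.alpha
        )
        counts["n_chemo_significant"] = int(results["chemo_assoc"]["significant"].sum())
    if ici is not None:
        tbl = assoc_mod.read_feature_table(ici, source="ici_gene")
        results["ici_assoc"] = assoc_mod.group_feature_tests(
            tbl, assignment, alpha=cfg.alpha
        )
        counts["n_ici_significant"] = int(results["ici_assoc"]["significant"].sum())

    results["report"] = report
    return results
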
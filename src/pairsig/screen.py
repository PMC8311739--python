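"""Immune-related lncRNA screens.

Two sequential filters:

1. :func:`screen_irlncrnas` — a lncRNA is immune-related when its
   log2(x+1) expression correlates (Pearson) with at least one immune
   gene above ``r_threshold`` at ``p < p_threshold`` (raw p from the
   t transform of r with n-2 df; correlation p-values are deliberately
   not multiplicity-adjusted).
2. :func:`de_screen` — an immune-related lncRNA is differentially
   expressed when |logFC| (difference of mean log2(x+1) between tumor
   and normal) exceeds ``lfc_threshold`` with Benjamini-Hochberg FDR
   below ``fdr_threshold``.  The default test is the Wilcoxon rank-sum;
   a moderated pooled-variance t-test is available via ``method``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, TUMOR, NORMAL, log2p1

logger = logging.getLogger("pairsig")

__all__ = ["CoexpressionResult", "DEResult", "screen_irlncrnas", "de_screen"]


@dataclass
class CoexpressionResult:
    lncrna: str
    best_partner: str
    r: float
    p: float
    passed: bool


@dataclass
class DEResult:
    lncrna: str
    log_fc: float
    p: float
    fdr: float
    direction: str
    passed: bool


def _corr_pvalue(r, n):
    """Two-sided p for a Pearson r via the t transform with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def screen_irlncrnas(
    expr: ExpressionMatrix,
    immune_genes,
    r_threshold: float = 0.6,
    p_threshold: float = 0.001,
    mode: str = "absolute",
    samples: str = "all",
) -> list[CoexpressionResult]:
    """Coexpression screen of every lncRNA against every immune gene.

    ``mode='absolute'`` passes on |r| > r_threshold, ``'positive'`` on
    signed r > r_threshold.  ``samples`` is 'all' (default) or 'tumor'.
    Constant-expression genes have undefined correlation and are
    skipped with a log entry.  Returns one result per testable lncRNA
    with its best partner (largest |r| or r according to mode).
    """
    if mode not in ("absolute", "positive"):
        raise ValueError(f"unknown mode {mode!r}")
    lnc_genes = expr.genes_of_biotype("lncRNA")
    immune_in = sorted(set(g.upper() for g in immune_genes) & set(expr.gene_ids))
    if not lnc_genes:
        raise ValueError("expression matrix contains no lncRNA-biotype genes")
    if not immune_in:
        raise ValueError("no immune genes found in the expression matrix")

    cols = expr.sample_ids if samples == "all" else expr.samples_of(TUMOR)
    n = len(cols)
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")

    L = log2p1(expr.values.loc[lnc_genes, cols].to_numpy())
    M = log2p1(expr.values.loc[immune_in, cols].to_numpy())

    l_sd = L.std(axis=1)
    m_sd = M.std(axis=1)
    skip_l = l_sd == 0
    if skip_l.any():
        logger.info("screen_irlncrnas: %d constant lncRNAs skipped", skip_l.sum())
    keep_m = m_sd > 0
    if (~keep_m).any():
        logger.info("screen_irlncrnas: %d constant immune genes skipped", (~keep_m).sum())
    M = M[keep_m]
    immune_in = [g for g, k in zip(immune_in, keep_m) if k]
    if len(immune_in) == 0:
        raise ValueError("all immune genes constant; cannot correlate")

    Lz = (L - L.mean(axis=1, keepdims=True)) / np.where(l_sd == 0, 1.0, l_sd)[:, None]
    Mz = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)
    R = (Lz @ Mz.T) / n  # lnc x immune correlation matrix

    results = []
    for i, g in enumerate(lnc_genes):
        if skip_l[i]:
            continue
        row = R[i]
        key = np.abs(row) if mode == "absolute" else row
        j = int(np.argmax(key))
        r = float(np.clip(row[j], -1.0, 1.0))
        p = float(_corr_pvalue(r, n))
        stat = abs(r) if mode == "absolute" else r
        passed = bool(stat > r_threshold and p < p_threshold)
        results.append(CoexpressionResult(g, immune_in[j], r, p, passed))
    return results


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (scipy-backed)."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float), method="bh")


def de_screen(
    expr: ExpressionMatrix,
    lncrnas=None,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    method: str = "wilcoxon",
) -> list[DEResult]:
    """Tumor-vs-normal differential-expression screen.

    ``logFC`` is the difference of mean log2(x+1) expression (tumor
    minus normal).  P-values come from the Wilcoxon rank-sum test
    (default) or a moderated pooled-variance t-test (``method='modt'``,
    variances shrunk toward their common mean with prior df equal to
    the residual df), then BH-adjusted across the tested genes.  A gene
    passes when |logFC| > lfc_threshold (strict) and FDR <
    fdr_threshold.
    """
    tumor = expr.samples_of(TUMOR)
    normal = expr.samples_of(NORMAL)
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >=2 samples per condition (tumor={len(tumor)}, normal={len(normal)})"
        )
    genes = list(lncrnas) if lncrnas is not None else expr.genes_of_biotype("lncRNA")
    genes = [g for g in genes if g in expr.values.index]
    if not genes:
        raise ValueError("no genes to test")

    Xt = log2p1(expr.values.loc[genes, tumor].to_numpy())
    Xn = log2p1(expr.values.loc[genes, normal].to_numpy())
    log_fc = Xt.mean(axis=1) - Xn.mean(axis=1)

    if method == "wilcoxon":
        res = stats.mannwhitneyu(Xt, Xn, axis=1, alternative="two-sided")
        pvals = np.asarray(res.pvalue, dtype=float)
    elif method == "modt":
        nt, nn = Xt.shape[1], Xn.shape[1]
        df_res = nt + nn - 2
        s2 = ((nt - 1) * Xt.var(axis=1, ddof=1) + (nn - 1) * Xn.var(axis=1, ddof=1)) / df_res
        s2_prior = s2.mean()
        d0 = df_res  # prior weight equal to residual df
        s2_mod = (d0 * s2_prior + df_res * s2) / (d0 + df_res)
        t = log_fc / np.sqrt(s2_mod * (1 / nt + 1 / nn))
        pvals = 2.0 * stats.t.sf(np.abs(t), df=df_res + d0)
    else:
        raise ValueError(f"unknown DE method {method!r}")

    fdr = bh_adjust(pvals)
    results = []
    for g, lfc, p, q in zip(genes, log_fc, pvals, fdr):
        passed = bool(abs(lfc) > lfc_threshold and q < fdr_threshold)
        direction = "up" if lfc > 0 else "down"
        results.append(DEResult(g, float(lfc), float(p), float(q), direction, passed))
    return results


def coexpression_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.lncrna, r.best_partner, r.r, r.p, r.passed) for r in results],
        columns=["lncrna", "best_partner", "r", "p", "passed"],
    )


def de_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.lncrna, r.log_fc, r.p, r.fdr, r.direction, r.passed) for r in results],
        columns=["lncrna", "log_fc", "p", "fdr", "direction", "passed"],
    )
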
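"""Associations between risk and external per-sample estimate tables.

Consumes immune-infiltration estimates (TIMER2.0-style long format or
a plain wide matrix), predicted drug log-IC50 tables and immune
checkpoint gene expression — all computed elsewhere — and tests each
feature against the risk groups (rank-sum) and the continuous risk
score (Spearman).

Features are reported per estimation method; a ``consensus`` column
marks cell types whose significant directions agree across at least
two methods, rather than silently removing inconsistent ones.  Raw
p-values are thresholded at ``alpha`` (default 0.05); a BH-adjusted
column is emitted alongside for transparency.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .risk import RiskAssignment
from .screen import bh_adjust
from .validate import _mannwhitney

logger = logging.getLogger("pairsig")

__all__ = [
    "read_feature_table",
    "group_feature_tests",
    "spearman_risk_correlation",
    "add_consensus",
]

ICI_GENES = ("TNFRSF9", "CTLA4", "LAG3", "HAVCR2", "PDCD1")


def read_feature_table(path_or_df, source: str = "infiltration") -> pd.DataFrame:
    """Normalize a feature table to long format (feature, method, sample, value).

    Accepts a long DataFrame/TSV with columns (cell_type|feature,
    [method], sample, value) or a wide matrix (features x samples).
    """
    df = (
        pd.read_csv(path_or_df, sep="\t")
        if not isinstance(path_or_df, pd.DataFrame)
        else path_or_df.copy()
    )
    cols = {c.lower(): c for c in df.columns}
    long_keys = {"sample", "value"}
    if long_keys <= set(cols):
        feat_col = cols.get("cell_type") or cols.get("feature") or cols.get("drug")
        if feat_col is None:
            raise ValueError("long table needs a cell_type/feature/drug column")
        out = pd.DataFrame(
            {
                "feature": df[feat_col].astype(str),
                "method": df[cols["method"]].astype(str) if "method" in cols else "NA",
                "sample": df[cols["sample"]].astype(str),
                "value": pd.to_numeric(df[cols["value"]]),
            }
        )
    else:  # wide: first column (or index) = feature
        if not isinstance(path_or_df, pd.DataFrame):
            df = df.set_index(df.columns[0])
        out = (
            df.stack()
            .rename_axis(["feature", "sample"])
            .reset_index(name="value")
            .assign(method="NA")
        )
    dup = out.duplicated(["feature", "method", "sample"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (feature, method, sample) rows")
    out["source"] = source
    return out


def group_feature_tests(
    table: pd.DataFrame,
    assignment: RiskAssignment,
    alpha: float = 0.05,
    min_per_group: int = 5,
) -> pd.DataFrame:
    """Per feature: rank-sum test of values between high- and low-risk groups.

    Direction is the sign of the high-minus-low median difference.
    Features with fewer than ``min_per_group`` samples in either group
    after the join are skipped (counted in the log).
    """
    long = table if "feature" in table.columns else read_feature_table(table)
    group = assignment.group
    rows = []
    n_skipped = 0
    for (feat, method), sub in long.groupby(["feature", "method"], sort=True):
        merged = sub.set_index("sample")["value"]
        common = merged.index.intersection(group.index)
        g = group.loc[common]
        hi = merged.loc[common][(g == "high").to_numpy()].to_numpy(float)
        lo = merged.loc[common][(g == "low").to_numpy()].to_numpy(float)
        if len(hi) < min_per_group or len(lo) < min_per_group:
            n_skipped += 1
            continue
        if np.ptp(np.concatenate([hi, lo])) == 0:
            u, p = np.nan, 1.0
        else:
            u, p = _mannwhitney(hi, lo)
        med_diff = float(np.median(hi) - np.median(lo))
        rows.append(
            {
                "feature": feat,
                "method": method,
                "test": "mannwhitney",
                "statistic": u,
                "p": p,
                "direction": "higher_in_high_risk" if med_diff > 0 else (
                    "lower_in_high_risk" if med_diff < 0 else "none"
                ),
                "median_diff": med_diff,
                "n_high": len(hi),
                "n_low": len(lo),
            }
        )
    if n_skipped:
        logger.info("group_feature_tests: %d features skipped (insufficient overlap)", n_skipped)
    if not rows:
        raise ValueError("no feature had sufficient overlap with the risk groups")
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] < alpha
    return out


def spearman_risk_correlation(
    table: pd.DataFrame,
    scores: pd.Series,
    alpha: float = 0.05,
    min_paired: int = 5,
) -> pd.DataFrame:
    """Per feature: Spearman correlation with the continuous risk score.

    Constant features have undefined rank correlation and are skipped
    with a warning.  Output is sorted by rho (lollipop-plot ready).
    """
    long = table if "feature" in table.columns else read_feature_table(table)
    rows = []
    for (feat, method), sub in long.groupby(["feature", "method"], sort=True):
        vals = sub.set_index("sample")["value"]
        common = vals.index.intersection(scores.index)
        if len(common) < min_paired:
            continue
        v = vals.loc[common].to_numpy(float)
        s = scores.loc[common].to_numpy(float)
        if np.ptp(v) == 0:
            logger.warning("spearman: feature %r constant, skipped", feat)
            continue
        rho, p = stats.spearmanr(s, v)
        rows.append(
            {
                "feature": feat,
                "method": method,
                "rho": float(rho),
                "p": float(p),
                "n": len(common),
            }
        )
    if not rows:
        raise ValueError("no feature with enough paired observations")
    out = pd.DataFrame(rows).sort_values("rho", ascending=False).reset_index(drop=True)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] < alpha
    return out


def add_consensus(assoc: pd.DataFrame) -> pd.DataFrame:
    """Mark features whose significant directions agree across >=2 methods."""
    out = assoc.copy()
    consensus = {}
    for feat, sub in out[out["significant"]].groupby("feature"):
        dirs = set(sub["direction"]) if "direction" in sub else set(np.sign(sub["rho"]))
        consensus[feat] = len(sub) >= 2 and len(dirs) == 1
    out["consensus"] = np.array(
        [consensus.get(f, False) for f in out["feature"]], dtype=bool
    )
    return out
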
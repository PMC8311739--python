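"""Clinical validation of the risk groups.

Four checks mirror the standard validation battery for a prognostic
signature: (1) Kaplan-Meier curves and the log-rank test between risk
groups; (2) chi-square association between risk group and each
categorical clinicopathological characteristic; (3) rank-sum
comparison of the continuous risk score across clinical strata; and
(4) univariate plus multivariate Cox regression of survival on the
risk score and the clinical covariates, establishing whether the score
is an independent prognostic factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable
from .risk import RiskAssignment
from .survival import cox_fit, km_estimate, logrank_test

logger = logging.getLogger("pairsig")

__all__ = [
    "survival_comparison",
    "chisq_association",
    "score_by_stratum",
    "independence_cox",
]


@dataclass
class SurvivalComparison:
    curves: dict  # group -> SurvivalCurve
    chi2: float
    p: float
    group_sizes: dict
    per_sample: pd.DataFrame | None = None  # rank/score/survival scatter table


def survival_comparison(assignment: RiskAssignment, clinical: ClinicalTable):
    """Per-group Kaplan-Meier curves and the two-group log-rank test.

    Also emits a per-sample table (samples ranked by risk score with
    their group, follow-up time and event flag) — the standard
    score-rank vs survival scatter pair of plots.
    """
    common = [s for s in assignment.group.index if s in clinical.data.index]
    group = assignment.group.loc[common]
    sizes = group.value_counts().to_dict()
    for g, n in sizes.items():
        if n < 2:
            raise ValueError(f"risk group {g!r} has {n} sample(s); cannot compare")
    if len(sizes) != 2:
        raise ValueError(f"expected 2 risk groups, got {sorted(sizes)}")
    times = clinical.data.loc[common, "os_time"].to_numpy(float)
    events = clinical.data.loc[common, "os_event"].to_numpy(int)
    curves = {
        g: km_estimate(times[(group == g).to_numpy()], events[(group == g).to_numpy()])
        for g in sorted(sizes)
    }
    chi2, p = logrank_test(times, events, (group == "high").to_numpy().astype(int))
    per_sample = (
        pd.DataFrame(
            {
                "risk_score": assignment.scores.loc[common],
                "group": group,
                "os_time": clinical.data.loc[common, "os_time"],
                "os_event": clinical.data.loc[common, "os_event"],
            }
        )
        .sort_values("risk_score")
        .assign(rank=lambda d: np.arange(1, len(d) + 1))
    )
    return SurvivalComparison(
        curves=curves, chi2=chi2, p=p, group_sizes=sizes, per_sample=per_sample
    )


def chisq_association(group: pd.Series, category: pd.Series, yates: bool = False):
    """Pearson chi-square for a risk-group x category contingency table.

    Returns one association row (dict).  Default is without continuity
    correction; an expected count of zero is a hard error advising a
    category merge.
    """
    common = group.index.intersection(category.dropna().index)
    tab = pd.crosstab(group.loc[common], category.loc[common])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table needs >=2 rows and columns")
    expected = stats.contingency.expected_freq(tab.to_numpy())
    if (expected == 0).any():
        raise ValueError(
            f"zero expected count in {category.name!r} table; merge sparse categories"
        )
    chi2, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=yates)
    return {
        "feature": category.name,
        "test": "chi2" + ("_yates" if yates else ""),
        "statistic": float(chi2),
        "p": float(p),
        "df": int(dof),
        "n": int(tab.to_numpy().sum()),
        "table": tab,
    }


def _mannwhitney(x, y):
    """Two-sided Mann-Whitney U; exact enumeration when both groups <= 8."""
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    if method == "exact" and (len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)):
        method = "asymptotic"  # ties: fall back to tie-corrected normal approx
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def score_by_stratum(scores: pd.Series, category: pd.Series) -> pd.DataFrame:
    """Pairwise rank-sum tests of the risk score between clinical strata.

    Strata with fewer than 2 samples are skipped with a warning; strata
    with fewer than 5 are reported but flagged ``low_n``.
    """
    common = scores.index.intersection(category.dropna().index)
    cat = category.loc[common]
    strata = [s for s in sorted(cat.unique())]
    usable = []
    for s in strata:
        n = int((cat == s).sum())
        if n < 2:
            logger.warning("score_by_stratum: stratum %r has %d sample(s), skipped", s, n)
        else:
            usable.append(s)
    if len(usable) < 2:
        raise ValueError("need >=2 strata with >=2 samples")
    rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            xa = scores.loc[common][cat == a].to_numpy(float)
            xb = scores.loc[common][cat == b].to_numpy(float)
            u, p = _mannwhitney(xa, xb)
            rows.append(
                {
                    "feature": category.name,
                    "stratum_a": a,
                    "stratum_b": b,
                    "test": "mannwhitney",
                    "statistic": u,
                    "p": p,
                    "median_diff": float(np.median(xa) - np.median(xb)),
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "low_n": len(xa) < 5 or len(xb) < 5,
                }
            )
    return pd.DataFrame(rows)


def independence_cox(
    scores: pd.Series,
    clinical: ClinicalTable,
    covariates=("age", "sex", "grade", "stage"),
):
    """Univariate and multivariate Cox models for score + clinical covariates.

    Each covariate (numeric-coded) and the risk score get a univariate
    fit; one multivariate fit includes them all.  Perfectly collinear
    covariates are dropped with a warning.  Returns
    ``(univariate_table, multivariate_table)`` in forest-plot shape.
    """
    common = [s for s in scores.index if s in clinical.data.index]
    df = clinical.data.loc[common].copy()
    df["risk_score"] = scores.loc[common]
    times = df["os_time"].to_numpy(float)
    events = df["os_event"].to_numpy(int)

    names = ["risk_score"] + [c for c in covariates if c in df.columns]
    X = df[names].apply(pd.to_numeric, errors="coerce")
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"non-numeric covariate values in {bad}")

    # drop exact collinearity (duplicated or constant columns)
    keep = []
    for c in names:
        col = X[c].to_numpy(float)
        if np.ptp(col) == 0:
            warnings.warn(f"constant covariate {c!r} dropped")
            continue
        dup = any(
            np.allclose(col, X[k].to_numpy(float))
            or np.corrcoef(col, X[k].to_numpy(float))[0, 1] > 1 - 1e-12
            for k in keep
        )
        if dup:
            warnings.warn(f"collinear covariate {c!r} dropped")
            continue
        keep.append(c)

    def rowify(fit, name):
        i = fit.names.index(name)
        return {
            "covariate": name,
            "HR": fit.hr[i],
            "ci_low": fit.ci_low[i],
            "ci_high": fit.ci_high[i],
            "p": fit.p[i],
            "beta": fit.beta[i],
        }

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        uni_rows = []
        for c in keep:
            fit = cox_fit(times, events, X[[c]].to_numpy(float), names=[c])
            uni_rows.append(rowify(fit, c))
        multi = cox_fit(times, events, X[keep].to_numpy(float), names=keep)
    multi_rows = [rowify(multi, c) for c in keep]
    return (
        pd.DataFrame(uni_rows).set_index("covariate"),
        pd.DataFrame(multi_rows).set_index("covariate"),
    )
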
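"""Risk scoring, AIC-optimal dichotomization and time-dependent AUC.

``RiskScore(sample) = sum_i beta_i * S_i(sample)`` over the signature
pairs.  The cohort is split into high/low risk at the cut-point whose
dichotomized single-covariate Cox model minimizes the AIC; candidates
are midpoints between consecutive distinct scores inside the 10th-90th
percentile band (a guard against degenerate tiny groups).  Model
discrimination is summarized by IPCW cumulative/dynamic AUC at 1-, 3-
and 5-year horizons, with the same horizon-1 AUC computed for each
numeric-coded clinical comparator covariate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable
from .pairs import PairIndicatorMatrix
from .selection import SignatureModel
from .survival import cox_fit, td_roc, TimeDependentROC

logger = logging.getLogger("pairsig")

__all__ = [
    "RiskAssignment",
    "risk_score",
    "aic_cutpoint",
    "youden_cutpoint",
    "evaluate_auc",
    "assign_groups",
]

DAYS_PER_YEAR = 365.25


@dataclass
class RiskAssignment:
    """Per-sample risk scores and the dichotomized groups."""

    scores: pd.Series
    cutpoint: float
    group: pd.Series  # 'high' iff score > cutpoint
    auc: dict = field(default_factory=dict)  # horizon (years) -> AUC
    roc: dict = field(default_factory=dict)  # horizon (years) -> TimeDependentROC
    comparator_auc: dict = field(default_factory=dict)
    cutpoint_fallback: bool = False

    @property
    def n_high(self) -> int:
        return int((self.group == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.group == "low").sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"risk_score": self.scores, "group": self.group})


def risk_score(model: SignatureModel, pm: PairIndicatorMatrix) -> pd.Series:
    """Weighted sum of pair indicators; missing signature pairs are fatal."""
    missing = [p for p in model.pairs if p not in pm.indicators.index]
    if missing:
        raise ValueError(f"pair matrix lacks signature pairs: {missing}")
    S = pm.indicators.loc[model.pairs].to_numpy(float)
    scores = model.beta @ S
    return pd.Series(scores, index=pm.sample_ids, name="risk_score")


def _cut_candidates(scores: np.ndarray, band=(0.10, 0.90), min_side: int = 10):
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    lo, hi = np.quantile(scores, band)
    mids = mids[(mids >= lo) & (mids <= hi)]
    keep = [
        c
        for c in mids
        if (scores > c).sum() >= min_side and (scores <= c).sum() >= min_side
    ]
    return np.array(keep)


def aic_cutpoint(scores, times, events, band=(0.10, 0.90), min_side: int = 10):
    """AIC-minimizing dichotomization threshold.

    For each candidate cut the single-covariate Cox model on the
    indicator ``score > c`` is fitted; the returned cut-point minimizes
    its AIC (ties break toward the smaller cut).  If no candidate is
    feasible the median split is returned, flagged via the second
    element of the result tuple.

    Returns ``(cutpoint, scan, fallback)`` where ``scan`` is a
    DataFrame of candidate cuts with their AIC, for inspection.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    cands = _cut_candidates(scores, band=band, min_side=min_side)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in cands:
            ind = (scores > c).astype(float)
            fit = cox_fit(times, events, ind[:, None], names=["high"])
            if fit.converged:
                rows.append((c, fit.aic, fit.beta[0]))
    if not rows:
        logger.warning("aic_cutpoint: no feasible candidate; falling back to median")
        return float(np.median(scores)), pd.DataFrame(columns=["cut", "aic", "beta"]), True
    scan = pd.DataFrame(rows, columns=["cut", "aic", "beta"])
    best = scan.loc[scan["aic"].idxmin()]
    # ties toward smaller cut: idxmin returns the first (cands ascending)
    return float(best["cut"]), scan, False


def youden_cutpoint(scores, times, events, horizon) -> float:
    """ROC-based alternative cut: maximize Youden's J = sens + spec - 1.

    Uses the IPCW time-dependent ROC at ``horizon`` (same time unit as
    ``times``); ties break toward the smaller threshold.  Provided for
    sensitivity analysis alongside the AIC rule.
    """
    scores = np.asarray(scores, dtype=float)
    r = td_roc(np.asarray(times, float), np.asarray(events), scores, horizon)
    finite = np.isfinite(r.thresholds)
    j = r.sensitivity[finite] + r.specificity[finite] - 1.0
    cands = r.thresholds[finite]
    order = np.argsort(cands, kind="stable")  # ascending; first max wins ties
    cands, j = cands[order], j[order]
    return float(cands[np.argmax(j)])


def assign_groups(scores: pd.Series, cutpoint: float) -> pd.Series:
    return pd.Series(
        np.where(scores.to_numpy() > cutpoint, "high", "low"),
        index=scores.index,
        name="group",
    )


def evaluate_auc(
    scores: pd.Series,
    clinical: ClinicalTable,
    horizons=(1.0, 3.0, 5.0),
    comparators=("age", "grade", "stage", "sex"),
    days_per_year: float = DAYS_PER_YEAR,
):
    """IPCW AUC of the risk score per horizon plus 1-year comparator AUCs.

    Horizons are in years and converted to the clinical time unit via
    ``days_per_year`` (no conversion if the unit is already years).
    Comparator covariates are used directly as numeric-coded scores at
    the first horizon.  Returns ``(auc, roc, comparator_auc)`` dicts.
    """
    common = [s for s in scores.index if s in clinical.data.index]
    sc = scores.loc[common].to_numpy(float)
    times = clinical.data.loc[common, "os_time"].to_numpy(float)
    events = clinical.data.loc[common, "os_event"].to_numpy(int)
    scale = 1.0 if clinical.time_unit == "years" else days_per_year

    auc: dict = {}
    roc: dict = {}
    for h in horizons:
        try:
            r = td_roc(times, events, sc, h * scale)
        except ValueError as exc:
            logger.warning("evaluate_auc: horizon %gy skipped (%s)", h, exc)
            continue
        auc[h] = r.auc
        roc[h] = r

    comparator_auc: dict = {}
    h1 = horizons[0] * scale
    for cov in comparators:
        if cov not in clinical.data.columns:
            continue
        vals = pd.to_numeric(clinical.data.loc[common, cov], errors="coerce")
        if vals.isna().any() or vals.nunique() < 2:
            continue
        try:
            comparator_auc[cov] = td_roc(times, events, vals.to_numpy(float), h1).auc
        except ValueError:
            continue
    return auc, roc, comparator_auc


def build_assignment(
    model: SignatureModel,
    pm: PairIndicatorMatrix,
    clinical: ClinicalTable,
    cutpoint_horizon: float = 5.0,
    horizons=(1.0, 3.0, 5.0),
    days_per_year: float = DAYS_PER_YEAR,
    cutpoint_method: str = "aic",
) -> RiskAssignment:
    """Score, choose the cut-point, assign groups, compute AUCs.

    The cut-point is estimated on the samples with clinical data (the
    dichotomized Cox needs survival); ``cutpoint_horizon`` is recorded
    on the model for provenance.  ``cutpoint_method`` is ``'aic'``
    (default) or ``'youden'`` (ROC-based sensitivity analysis at the
    cut-point horizon).
    """
    scores = risk_score(model, pm)
    common = [s for s in scores.index if s in clinical.data.index]
    times = clinical.data.loc[common, "os_time"].to_numpy(float)
    events = clinical.data.loc[common, "os_event"].to_numpy(int)
    fallback = False
    if cutpoint_method == "aic":
        cut, _scan, fallback = aic_cutpoint(
            scores.loc[common].to_numpy(float), times, events
        )
    elif cutpoint_method == "youden":
        scale = 1.0 if clinical.time_unit == "years" else days_per_year
        cut = youden_cutpoint(
            scores.loc[common].to_numpy(float),
            times,
            events,
            cutpoint_horizon * scale,
        )
    else:
        raise ValueError(f"unknown cutpoint_method {cutpoint_method!r}")
    model.cutpoint = cut
    model.cutpoint_horizon = cutpoint_horizon
    group = assign_groups(scores, cut)
    auc, roc, comp = evaluate_auc(
        scores.loc[common],
        clinical,
        horizons=horizons,
        days_per_year=days_per_year,
    )
    return RiskAssignment(
        scores=scores,
        cutpoint=cut,
        group=group,
        auc=auc,
        roc=roc,
        comparator_auc=comp,
        cutpoint_fallback=fallback,
    )
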
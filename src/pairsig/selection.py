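"""Signature selection: univariate screen, repeated CV Lasso-Cox, stepwise Cox.

The funnel mirrors the construction of the pair signature:

1. :func:`univariate_screen` drops pairs whose single-covariate Cox
   Wald p is above ``p_threshold`` (default 0.01).
2. :func:`repeated_lasso` runs the cross-validated Lasso-Cox many
   times, each repetition redrawing its own fold partition; a pair's
   selection frequency is the number of repetitions in which it keeps a
   nonzero coefficient at the CV-deviance-minimizing lambda.  Pairs
   with frequency strictly greater than ``freq_threshold`` survive.
   The canonical preset is 1000 repetitions / threshold 100; the `fast`
   preset (100 / 10) scales both together.
3. :func:`stepwise_multivariate` fits the multivariate Cox model and
   performs bidirectional stepwise selection minimizing AIC, starting
   from the full model; the surviving pairs and their coefficients form
   the :class:`SignatureModel`.

Stages are nested by construction: signature pairs ⊆ lasso survivors ⊆
univariate survivors ⊆ input pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairs import PairIndicatorMatrix
from .io import ClinicalTable
from .survival import cox_fit, cv_lasso_cox, lasso_cox_path

logger = logging.getLogger("pairsig")

__all__ = [
    "SelectionTrace",
    "SignatureModel",
    "univariate_screen",
    "repeated_lasso",
    "stepwise_multivariate",
    "select_signature",
]

PRESETS = {"paper": (1000, 100), "fast": (100, 10)}


@dataclass
class SelectionTrace:
    """Bookkeeping of the selection funnel (nested surviving pair lists)."""

    univariate_p: pd.Series | None = None
    stage1_pairs: list = field(default_factory=list)
    lasso_frequency: pd.Series | None = None
    repetitions: int = 0
    stage2_pairs: list = field(default_factory=list)
    stepwise_order: list = field(default_factory=list)
    final_pairs: list = field(default_factory=list)
    seed: int | None = None


@dataclass
class SignatureModel:
    """The fitted pair signature: pairs, Cox coefficients and cut-point."""

    pairs: list
    beta: np.ndarray
    aic: float
    n: int
    n_events: int
    cutpoint: float | None = None
    cutpoint_horizon: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pair_id": self.pairs, "beta": self.beta}).set_index(
            "pair_id"
        )


def _aligned(pm: PairIndicatorMatrix, clinical: ClinicalTable):
    common = [s for s in pm.sample_ids if s in clinical.data.index]
    n_miss = len(pm.sample_ids) - len(common)
    if n_miss:
        logger.info("sample alignment: %d pair-matrix samples lack clinical data", n_miss)
    if len(common) < 10:
        raise ValueError("fewer than 10 samples with both pairs and clinical data")
    S = pm.indicators[common]
    times = clinical.data.loc[common, "os_time"].to_numpy(float)
    events = clinical.data.loc[common, "os_event"].to_numpy(int)
    return S, times, events


def univariate_screen(
    pm: PairIndicatorMatrix,
    clinical: ClinicalTable,
    p_threshold: float = 0.01,
) -> SelectionTrace:
    """Single-covariate Cox per pair; keep Wald p < p_threshold."""
    S, times, events = _aligned(pm, clinical)
    pvals = {}
    skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid, row in zip(S.index, S.to_numpy(float)):
            if row.min() == row.max():
                skipped += 1
                continue
            fit = cox_fit(times, events, row[:, None], names=[pid])
            pvals[pid] = fit.p[0]
    if skipped:
        logger.warning("univariate_screen: %d constant pairs skipped", skipped)
    pseries = pd.Series(pvals, name="univariate_p")
    survivors = [p for p, v in pseries.items() if v < p_threshold]
    logger.info(
        "univariate_screen: %d of %d pairs pass p<%g",
        len(survivors),
        len(pseries),
        p_threshold,
    )
    if not survivors:
        raise ValueError(
            f"no pair passes the univariate screen at p<{p_threshold}; "
            "consider relaxing the threshold"
        )
    trace = SelectionTrace(univariate_p=pseries, stage1_pairs=survivors)
    return trace


def repeated_lasso(
    pm: PairIndicatorMatrix,
    clinical: ClinicalTable,
    trace: SelectionTrace,
    repetitions: int = 1000,
    folds: int = 10,
    freq_threshold: int = 100,
    seed: int = 0,
    n_lambda: int = 25,
    lambda_min_ratio: float = 0.08,
    lambda_rule: str = "min",
) -> SelectionTrace:
    """Repeated cross-validated Lasso-Cox selection frequencies.

    Each repetition draws its own fold partition from a child stream of
    ``seed``, picks lambda minimizing the CV partial-likelihood
    deviance, and counts the pairs with nonzero coefficients there.
    Pairs selected in strictly more than ``freq_threshold`` repetitions
    survive to the stepwise stage.
    """
    if len(trace.stage1_pairs) < 2:
        raise ValueError("repeated_lasso needs >=2 stage-1 survivors")
    pm1 = pm.subset_pairs(trace.stage1_pairs)
    S, times, events = _aligned(pm1, clinical)
    X = S.to_numpy(float).T
    counts = pd.Series(0, index=pd.Index(trace.stage1_pairs, name="pair_id"))

    # the full-data path only depends on the grid; compute it once
    _, full_path, _ = lasso_cox_path(
        times,
        events,
        X,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
    )

    streams = np.random.SeedSequence(seed).spawn(repetitions)
    n_empty = 0
    for rep in range(repetitions):
        rng = np.random.default_rng(streams[rep])
        _, beta, _, _ = cv_lasso_cox(
            times,
            events,
            X,
            folds=folds,
            rng=rng,
            n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio,
            fold_irls_tol=1e-3,
            full_path=full_path,
            lambda_rule=lambda_rule,
        )
        nz = np.flatnonzero(beta != 0)
        if len(nz) == 0:
            n_empty += 1
            continue
        counts.iloc[nz] += 1
    if n_empty == repetitions:
        raise ValueError("every Lasso repetition selected the empty model")

    survivors = counts.index[counts > freq_threshold].tolist()
    logger.info(
        "repeated_lasso: %d of %d pairs with frequency > %d over %d repetitions",
        len(survivors),
        len(counts),
        freq_threshold,
        repetitions,
    )
    trace.lasso_frequency = counts
    trace.repetitions = repetitions
    trace.stage2_pairs = survivors
    trace.seed = seed
    if not survivors:
        raise ValueError(
            f"no pair exceeded the selection-frequency threshold {freq_threshold}"
        )
    return trace


def stepwise_multivariate(
    pm: PairIndicatorMatrix,
    clinical: ClinicalTable,
    trace: SelectionTrace,
) -> tuple[SignatureModel, pd.DataFrame]:
    """Bidirectional stepwise Cox on the lasso survivors, minimizing AIC.

    Starts from the full multivariate model and accepts single add/drop
    moves until none lowers the AIC.  Moves are prescreened cheaply —
    drops by the Wald statistic of the coefficient, additions by the
    Rao score statistic at the current fit — and only the most
    promising ``exact_top`` moves are refit exactly; the accept/stop
    decision always uses exact AICs.  If the full model fails to
    converge, falls back to forward-only selection (flagged).  Returns
    the signature model and a per-pair table of univariate and
    multivariate hazard ratios.
    """
    candidates = list(trace.stage2_pairs)
    if not candidates:
        raise ValueError("stepwise stage requires >=1 stage-2 survivor")
    exact_top = 8
    pm2 = pm.subset_pairs(candidates)
    S, times, events = _aligned(pm2, clinical)
    Sarr = S.to_numpy(float)
    idx_of = {p: i for i, p in enumerate(candidates)}

    from .survival import _eta_derivatives, _sort_survival

    t_sorted, d_sorted, Sall_sorted, _ = _sort_survival(times, events, Sarr.T)

    cache: dict[frozenset, "object"] = {}
    coef_hint: dict[str, float] = {}

    def fit_subset(subset):
        key = frozenset(subset)
        if key in cache:
            return cache[key]
        sub = sorted(subset, key=idx_of.get)
        X = Sarr[[idx_of[p] for p in sub]].T
        init = np.array([coef_hint.get(p, 0.0) for p in sub])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cox_fit(times, events, X, names=sub, beta_init=init)
        cache[key] = fit
        if fit.converged:
            for p, b in zip(sub, fit.beta):
                coef_hint[p] = b
        return fit

    full = fit_subset(candidates)
    forward_only = not full.converged
    if forward_only:
        logger.warning("stepwise: full model did not converge; forward-only fallback")
        current: list = []
        current_aic = np.inf
        current_fit = None
    else:
        current = list(candidates)
        current_aic = full.aic
        current_fit = full

    order = []
    while True:
        # cheap surrogate ranking of every move by its approximate AIC change
        ranked = []
        if current_fit is not None and len(current) > 1 and not forward_only:
            for name, b, se in zip(current_fit.names, current_fit.beta, current_fit.se):
                z2 = (b / se) ** 2 if se > 0 else np.inf
                ranked.append((z2 - 2.0, "drop", name))
        excluded = [p for p in candidates if p not in current]
        if excluded:
            if current_fit is not None:
                beta_map = dict(zip(current_fit.names, current_fit.beta))
                eta = sum(
                    beta_map[p] * Sall_sorted[:, idx_of[p]] for p in current
                ) if current else np.zeros(len(t_sorted))
            else:
                eta = np.zeros(len(t_sorted))
            g, curv = _eta_derivatives(t_sorted, d_sorted, np.asarray(eta, float))
            for p in excluded:
                x = Sall_sorted[:, idx_of[p]]
                xc = x - np.average(x, weights=curv)
                V = float(curv @ xc**2)
                score = float(xc @ g) ** 2 / V if V > 0 else 0.0
                ranked.append((2.0 - score, "add", p))
        if not ranked:
            break
        ranked.sort(key=lambda m: m[0])

        best = None
        for _approx, action, pair in ranked[:exact_top]:
            subset = (
                [q for q in current if q != pair]
                if action == "drop"
                else current + [pair]
            )
            fit = fit_subset(subset)
            if best is None or fit.aic < best[0].aic:
                best = (fit, action, pair, subset)
        fit, action, pair, subset = best
        if fit.aic < current_aic - 1e-10:
            current, current_aic, current_fit = subset, fit.aic, fit
            order.append(f"{action}:{pair}")
        else:
            break

    if not current:
        raise ValueError("stepwise selection retained no pair")
    final_fit = fit_subset(current)
    final_sorted = sorted(current, key=idx_of.get)

    # per-candidate univariate + multivariate report (forest-plot shape)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in candidates:
            uni = cox_fit(times, events, Sarr[idx_of[p]][:, None], names=[p])
            rows.append(
                {
                    "pair_id": p,
                    "uni_HR": uni.hr[0],
                    "uni_ci_low": uni.ci_low[0],
                    "uni_ci_high": uni.ci_high[0],
                    "uni_p": uni.p[0],
                    "in_model": p in current,
                }
            )
    report = pd.DataFrame(rows).set_index("pair_id")
    for name, b, hr, lo, hi, pv in zip(
        final_fit.names,
        final_fit.beta,
        final_fit.hr,
        final_fit.ci_low,
        final_fit.ci_high,
        final_fit.p,
    ):
        report.loc[name, "multi_beta"] = b
        report.loc[name, "multi_HR"] = hr
        report.loc[name, "multi_ci_low"] = lo
        report.loc[name, "multi_ci_high"] = hi
        report.loc[name, "multi_p"] = pv

    beta_by_pair = dict(zip(final_fit.names, final_fit.beta))
    model = SignatureModel(
        pairs=final_sorted,
        beta=np.array([beta_by_pair[p] for p in final_sorted]),
        aic=final_fit.aic,
        n=final_fit.n,
        n_events=final_fit.n_events,
        metadata={"forward_only": forward_only, "stepwise_order": order},
    )
    trace.stepwise_order = order
    trace.final_pairs = final_sorted
    return model, report


def select_signature(
    pm: PairIndicatorMatrix,
    clinical: ClinicalTable,
    p_threshold: float = 0.01,
    repetitions: int = 1000,
    folds: int = 10,
    freq_threshold: int = 100,
    seed: int = 0,
):
    """Run the three-stage funnel; returns (model, trace, report)."""
    trace = univariate_screen(pm, clinical, p_threshold=p_threshold)
    trace = repeated_lasso(
        pm,
        clinical,
        trace,
        repetitions=repetitions,
        folds=folds,
        freq_threshold=freq_threshold,
        seed=seed,
    )
    model, report = stepwise_multivariate(pm, clinical, trace)
    return model, trace, report
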
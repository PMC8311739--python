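"""Rank-based 0/1 pair-indicator matrix.

For every unordered pair of differentially expressed immune-related
lncRNAs (A, B) with A < B lexicographically, the indicator
``S(A,B; sample) = 1`` iff A's expression strictly exceeds B's in that
sample, else 0 (ties score 0).  Because S only compares two genes
within the same sample, it is invariant to any strictly increasing
per-sample transform of the expression values — no normalization is
required across cohorts.

The prevalence filter keeps pairs whose 0s and 1s each cover at least
``min_frac`` of samples (boundary inclusive): near-constant indicators
carry no prognostic contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger("pairsig")

__all__ = ["PairIndicatorMatrix", "build_pairs", "prevalence_filter"]

PAIR_SEP = "|"


@dataclass
class PairIndicatorMatrix:
    """Binary pairs x samples matrix.

    ``indicators`` is indexed by pair id ``"A|B"`` (A < B); ``freq1``
    is the per-pair fraction of samples scoring 1.
    """

    indicators: pd.DataFrame

    def __post_init__(self):
        vals = self.indicators.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("pair indicators must be 0/1")
        if self.indicators.index.duplicated().any():
            raise ValueError("duplicate pair ids")

    @property
    def pair_ids(self) -> list:
        return list(self.indicators.index)

    @property
    def sample_ids(self) -> list:
        return list(self.indicators.columns)

    @property
    def pairs(self) -> list:
        return [tuple(p.split(PAIR_SEP)) for p in self.indicators.index]

    @property
    def freq1(self) -> pd.Series:
        return self.indicators.mean(axis=1)

    def subset_pairs(self, pair_ids) -> "PairIndicatorMatrix":
        return PairIndicatorMatrix(self.indicators.loc[list(pair_ids)])

    def subset_samples(self, samples) -> "PairIndicatorMatrix":
        return PairIndicatorMatrix(self.indicators[list(samples)])


def build_pairs(expr: ExpressionMatrix, genes, samples=None) -> PairIndicatorMatrix:
    """All C(m,2) pair indicators over the given genes.

    Genes absent from the expression matrix are excluded first (logged,
    mirroring the removal of pairs with no expression values).  Pair
    orientation is canonical: A < B by symbol; equal expression scores 0.
    """
    genes = sorted(dict.fromkeys(genes))
    present = [g for g in genes if g in expr.values.index]
    dropped = len(genes) - len(present)
    if dropped:
        logger.info("build_pairs: %d genes absent from expression, excluded", dropped)
    if len(present) < 2:
        raise ValueError(f"need >=2 usable genes to build pairs, got {len(present)}")
    cols = list(samples) if samples is not None else expr.sample_ids
    X = expr.values.loc[present, cols].to_numpy()

    ia, ib = np.array(list(combinations(range(len(present)), 2))).T
    S = (X[ia] > X[ib]).astype(np.int8)
    ids = [f"{present[a]}{PAIR_SEP}{present[b]}" for a, b in zip(ia, ib)]
    return PairIndicatorMatrix(pd.DataFrame(S, index=ids, columns=cols))


def pair_indicators_for(expr: ExpressionMatrix, pair_ids, samples=None) -> PairIndicatorMatrix:
    """Indicators for a fixed pair list (e.g. scoring a new cohort).

    Every gene of every pair must be present in the expression matrix.
    """
    cols = list(samples) if samples is not None else expr.sample_ids
    rows = {}
    for pid in pair_ids:
        a, b = pid.split(PAIR_SEP)
        if a not in expr.values.index or b not in expr.values.index:
            raise ValueError(f"pair {pid!r}: gene missing from expression matrix")
        rows[pid] = (
            expr.values.loc[a, cols].to_numpy() > expr.values.loc[b, cols].to_numpy()
        ).astype(np.int8)
    return PairIndicatorMatrix(pd.DataFrame(rows, index=cols).T)


def prevalence_filter(pm: PairIndicatorMatrix, min_frac: float = 0.2) -> PairIndicatorMatrix:
    """Keep pairs with ``min_frac <= freq1 <= 1 - min_frac`` (inclusive)."""
    f = pm.freq1
    keep = (f >= min_frac) & (f <= 1.0 - min_frac)
    logger.info(
        "prevalence_filter: %d of %d pairs kept (min_frac=%g)",
        int(keep.sum()),
        len(f),
        min_frac,
    )
    if not keep.any():
        raise ValueError(
            "prevalence filter removed every pair; review min_frac or the input pairs"
        )
    return PairIndicatorMatrix(pm.indicators.loc[keep])


def write_pairs(pm: PairIndicatorMatrix, path) -> None:
    out = pm.indicators.copy()
    out.insert(0, "freq1", pm.freq1.round(6))
    out.to_csv(path, sep="\t", index_label="pair_id")


def read_pairs(path) -> PairIndicatorMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PairIndicatorMatrix(df.drop(columns=["freq1"]).astype(np.int8))
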
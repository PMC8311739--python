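import numpy as np
import pandas as pd
import pytest

from pairsig.io import ExpressionMatrix
from pairsig.simulate import SimulationConfig, simulate_dataset


def small_config(seed=0, **overrides):
    """A scaled-down cohort for unit tests (fast, still recoverable)."""
    kw = dict(
        n_tumor=150,
        n_normal=15,
        n_lnc=80,
        n_immune_genes=60,
        n_other_genes=40,
        n_coexpressed_lnc=40,
        n_de_lnc=30,
        n_planted_pairs=5,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config(seed=11))


@pytest.fixture(scope="session")
def immune_symbols(small_dataset):
    return {g for g in small_dataset["expression"].gene_ids if g.startswith("IMM")}


@pytest.fixture()
def tiny_expr():
    """3 genes x 4 samples, hand-checkable."""
    values = pd.DataFrame(
        [[5.0, 1.0, 2.0, 7.0], [3.0, 3.0, 3.0, 3.0], [0.0, 4.0, 1.0, 2.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(
        values=values,
        gene_biotype={"GA": "lncRNA", "GB": "lncRNA", "GC": "protein_coding"},
        sample_condition={"s1": "tumor", "s2": "tumor", "s3": "normal", "s4": "normal"},
    )


def exponential_cohort(rng, n=200, beta=None, X=None, censor_scale=2.0):
    """Simple PH cohort for survival-engine tests."""
    if X is None:
        X = rng.normal(size=(n, 3))
    if beta is None:
        beta = np.zeros(X.shape[1])
    eta = X @ beta
    T = rng.exponential(1.0 / np.exp(eta - eta.mean()))
    C = rng.exponential(censor_scale, size=len(T))
    return np.minimum(T, C), (T <= C).astype(int), X
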
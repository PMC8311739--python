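"""Synthetic cohorts with planted, recoverable structure.

The generator emulates the statistical features the pair-signature
analysis assumes, each with a known ground truth:

* a genes x samples abundance matrix on a log2-normal model in which a
  configurable subset of lncRNAs shares a latent factor with an immune
  gene (so they pass the coexpression screen) and a subset of those is
  mean-shifted in tumors (so they pass the differential-expression
  screen);
* proportional-hazards survival in which the hazard of each tumor
  sample is driven by the planted pair indicators
  ``S_i = 1[expr(A) > expr(B)]`` through a linear predictor
  ``eta = sum_i beta_true_i * S_i``, with uniform administrative
  censoring calibrated to a target rate and clinical covariates (age,
  stage, grade) coupled to ``eta``;
* immune-infiltration fractions, drug log-IC50 values and immune
  checkpoint gene expression coupled to ``eta`` with configurable signs,
  so downstream association stages have planted directions to recover.

Identical ``SimulationConfig`` (including seed) gives bit-identical
output.  Randomness for the expression, survival and association
stages comes from independent child streams of the master seed, so
regenerating one stage does not shift another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import ExpressionMatrix, ClinicalTable, TUMOR, NORMAL

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_survival",
    "simulate_associations",
    "simulate_dataset",
]

# planted association couplings: sign = direction of coupling with risk.
# Macrophage/fibroblast-like populations enrich with risk, CD4/dendritic-like
# deplete; two uncoupled cell types serve as negative controls.
DEFAULT_CELL_COUPLINGS = {
    "Macrophage": 1.0,
    "Fibroblast": 1.0,
    "Endothelial cell": 0.8,
    "Monocyte": 0.6,
    "Neutrophil": 0.8,
    "T cell CD4+": -0.8,
    "Myeloid dendritic cell activated": -0.6,
    "Eosinophil": -0.5,
    "B cell": 0.0,
    "T cell CD8+": 0.0,
}

# log-IC50 couplings: positive = higher risk, higher IC50 (less sensitive)
DEFAULT_DRUG_COUPLINGS = {
    "gefitinib": 0.6,
    "cisplatin": -0.6,
    "docetaxel": -0.8,
    "gemcitabine": 0.0,
}

DEFAULT_ICI_COUPLINGS = {
    "TNFRSF9": 0.6,
    "CTLA4": 0.0,
    "LAG3": 0.0,
    "HAVCR2": 0.0,
    "PDCD1": 0.0,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults give the study conditions.

    The cohort scale (400 tumors, 19 normals), screen margins
    (coexpression loading 0.75 vs the 0.6 screen; differential shift
    1.5 vs the logFC>1 screen), the ten planted pairs with effect sizes
    in [0.5, 1], and ~35% censoring define the default recovery
    setting; ``threshold_effect`` switches the hazard to a jump at a
    planted risk cut-point instead of a linear term.
    """

    n_tumor: int = 400
    n_normal: int = 19
    n_lnc: int = 300
    n_immune_genes: int = 150
    n_other_genes: int = 500
    n_coexpressed_lnc: int = 120
    n_de_lnc: int = 100
    n_planted_pairs: int = 10
    planted_betas: tuple | None = None  # default: alternating-sign 0.5..1.0
    coexpression_rho: float = 0.75
    de_log2fc: float = 1.5
    de_up_fraction: float = 0.75
    noise_sd: float = 1.0
    baseline_hazard: float = np.log(2) / 1826.25  # median 5 years (days) at eta=0
    weibull_shape: float = 1.0
    censoring_target: float = 0.35
    threshold_effect: tuple | None = None  # (cutpoint c, log-HR gamma)
    age_coupling: float = 3.0
    stage_coupling: float = 0.8
    grade_coupling: float = 0.8
    assoc_noise_sd: float = 1.0
    cell_couplings: dict = field(default_factory=lambda: dict(DEFAULT_CELL_COUPLINGS))
    drug_couplings: dict = field(default_factory=lambda: dict(DEFAULT_DRUG_COUPLINGS))
    ici_couplings: dict = field(default_factory=lambda: dict(DEFAULT_ICI_COUPLINGS))
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.censoring_target < 1:
            raise ValueError("censoring_target must be in [0, 1)")
        if self.n_coexpressed_lnc > self.n_lnc:
            raise ValueError("more coexpressed lncRNAs requested than lncRNAs")
        if self.n_de_lnc > self.n_coexpressed_lnc:
            raise ValueError("more DE lncRNAs requested than coexpressed lncRNAs")
        if 2 * self.n_planted_pairs > self.n_de_lnc:
            raise ValueError("planted pairs need 2*k distinct DE lncRNAs")
        if self.n_coexpressed_lnc > self.n_immune_genes:
            raise ValueError("each coexpressed lncRNA needs its own immune partner")
        if not 0 <= self.coexpression_rho <= 1:
            raise ValueError("coexpression_rho must be in [0, 1]")

    def betas(self) -> np.ndarray:
        if self.planted_betas is not None:
            b = np.asarray(self.planted_betas, dtype=float)
            if len(b) != self.n_planted_pairs:
                raise ValueError("planted_betas length must equal n_planted_pairs")
            return b
        mags = np.linspace(0.5, 1.0, self.n_planted_pairs)
        signs = np.where(np.arange(self.n_planted_pairs) % 2 == 0, 1.0, -1.0)
        return mags * signs


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring; serialized with every dataset."""

    irlncrna_set: list
    de_set: list
    planted_pairs: list  # (lncA, lncB, beta_true), A < B lexicographically
    true_risk: pd.Series | None = None  # per tumor sample, set by simulate_survival
    true_cutpoint: float | None = None
    seed: int = 0

    def to_text(self) -> str:
        lines = [f"seed\t{self.seed}"]
        lines.append("irlncrna\t" + ",".join(self.irlncrna_set))
        lines.append("de_irlncrna\t" + ",".join(self.de_set))
        for a, b, beta in self.planted_pairs:
            lines.append(f"planted_pair\t{a}\t{b}\t{beta:.6g}")
        if self.true_cutpoint is not None:
            lines.append(f"true_cutpoint\t{self.true_cutpoint:.6g}")
        if self.true_risk is not None:
            for s, v in self.true_risk.items():
                lines.append(f"true_risk\t{s}\t{v:.6g}")
        return "\n".join(lines) + "\n"


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def simulate_expression(config: SimulationConfig):
    """Generate the abundance matrix and its ground truth.

    Log2-scale model: coexpressed lncRNA j and its immune partner both
    load sqrt(rho) on a shared standard-normal factor, giving expected
    Pearson correlation rho; DE lncRNAs additionally get a tumor-mean
    shift of at least ``de_log2fc`` in absolute value.  Values are
    returned as ``2**x - 1`` clipped at zero (FPKM-like scale).

    Returns ``(ExpressionMatrix, GroundTruth)``; the ground truth has
    no survival information yet.
    """
    cfg = config
    rng = _rng(cfg.seed, 0)
    n = cfg.n_tumor + cfg.n_normal
    samples = [f"T{i+1:04d}" for i in range(cfg.n_tumor)] + [
        f"N{i+1:03d}" for i in range(cfg.n_normal)
    ]
    is_tumor = np.concatenate(
        [np.ones(cfg.n_tumor, bool), np.zeros(cfg.n_normal, bool)]
    )

    lnc = [f"LNC{i+1:04d}" for i in range(cfg.n_lnc)]
    imm = [f"IMM{i+1:04d}" for i in range(cfg.n_immune_genes)]
    other = [f"PCG{i+1:04d}" for i in range(cfg.n_other_genes)]

    rho = cfg.coexpression_rho
    a = np.sqrt(rho)
    b = np.sqrt(1.0 - rho)
    sd = cfg.noise_sd

    # baseline log2 means
    mu_lnc = rng.normal(4.0, 1.0, cfg.n_lnc)
    mu_imm = rng.normal(5.0, 1.0, cfg.n_immune_genes)
    mu_other = rng.normal(5.0, 2.0, cfg.n_other_genes)

    # tumor shifts for the DE lncRNAs (first n_de_lnc of the coexpressed set)
    delta = np.zeros(cfg.n_lnc)
    signs = np.where(rng.random(cfg.n_de_lnc) < cfg.de_up_fraction, 1.0, -1.0)
    delta[: cfg.n_de_lnc] = signs * (
        cfg.de_log2fc + np.abs(rng.normal(0.0, 0.25, cfg.n_de_lnc))
    )

    # planted pairs: consecutive DE lncRNAs, forced onto a common tumor-side
    # mean so the pair indicator is informative (~50% prevalence)
    betas = cfg.betas()
    pairs = []
    for k in range(cfg.n_planted_pairs):
        ia, ib = 2 * k, 2 * k + 1
        mu_lnc[ib] = mu_lnc[ia]
        delta[ib] = delta[ia]
        pairs.append((lnc[ia], lnc[ib], float(betas[k])))

    # latent factors shared lncRNA <-> immune partner
    z = rng.standard_normal((cfg.n_coexpressed_lnc, n))

    lnc_log = np.empty((cfg.n_lnc, n))
    nco = cfg.n_coexpressed_lnc
    lnc_log[:nco] = sd * (a * z + b * rng.standard_normal((nco, n)))
    lnc_log[nco:] = sd * rng.standard_normal((cfg.n_lnc - nco, n))
    lnc_log += mu_lnc[:, None]
    lnc_log += np.outer(delta, is_tumor.astype(float))

    imm_log = np.empty((cfg.n_immune_genes, n))
    imm_log[:nco] = sd * (a * z + b * rng.standard_normal((nco, n)))
    imm_log[nco:] = sd * rng.standard_normal((cfg.n_immune_genes - nco, n))
    imm_log += mu_imm[:, None]

    other_log = mu_other[:, None] + sd * rng.standard_normal((cfg.n_other_genes, n))

    log_all = np.vstack([lnc_log, imm_log, other_log])
    values = np.clip(np.exp2(log_all) - 1.0, 0.0, None)

    genes = lnc + imm + other
    biotype = {g: "lncRNA" for g in lnc}
    biotype.update({g: "protein_coding" for g in imm + other})
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        gene_biotype=biotype,
        sample_condition={
            s: (TUMOR if t else NORMAL) for s, t in zip(samples, is_tumor)
        },
    )
    truth = GroundTruth(
        irlncrna_set=lnc[:nco],
        de_set=lnc[: cfg.n_de_lnc],
        planted_pairs=pairs,
        seed=cfg.seed,
    )
    return expr, truth


def true_pair_indicators(expr: ExpressionMatrix, truth: GroundTruth, samples=None):
    """0/1 indicator rows for the planted pairs over the given samples."""
    if samples is None:
        samples = expr.samples_of(TUMOR)
    rows = {}
    for a, b, _beta in truth.planted_pairs:
        rows[f"{a}|{b}"] = (
            expr.values.loc[a, samples].to_numpy()
            > expr.values.loc[b, samples].to_numpy()
        ).astype(int)
    return pd.DataFrame(rows, index=samples).T


def simulate_survival(expr: ExpressionMatrix, truth: GroundTruth, config: SimulationConfig):
    """Survival and clinical covariates for the tumor samples.

    Hazard model: ``h(t) = h0 * nu * t**(nu-1) * exp(eta)`` with
    ``eta = sum beta_true * S_i`` (or, in ``threshold_effect`` mode,
    ``gamma * 1[eta_raw > c]``).  Censoring is uniform on (0, tau) with
    tau solved so the realized censoring fraction matches the target.
    Age gets an additive ``age_coupling * eta`` term; stage (ordinal
    1-4) and grade (1-2) shift with eta through latent-logistic models;
    sex is independent of risk.

    Updates ``truth.true_risk`` in place and returns a ClinicalTable.
    """
    cfg = config
    rng = _rng(cfg.seed, 1)
    tumor_samples = expr.samples_of(TUMOR)
    S = true_pair_indicators(expr, truth, tumor_samples)
    betas = np.array([b for _, _, b in truth.planted_pairs])
    eta_raw = betas @ S.to_numpy()
    truth.true_risk = pd.Series(eta_raw, index=tumor_samples, name="true_risk")

    if cfg.threshold_effect is not None:
        c, gamma = cfg.threshold_effect
        eta = gamma * (eta_raw > c).astype(float)
        truth.true_cutpoint = float(c)
    else:
        eta = eta_raw

    nu = cfg.weibull_shape
    lam = cfg.baseline_hazard * np.exp(eta)
    u = rng.random(len(tumor_samples))
    T = (-np.log(u) / lam) ** (1.0 / nu)

    if cfg.censoring_target == 0:
        os_time, os_event = T, np.ones(len(T), int)
    else:
        def cens_rate(tau):
            # P(C < T) with C ~ U(0, tau) equals E[min(T, tau)] / tau
            return np.mean(np.minimum(T, tau)) / tau

        lo, hi = np.min(T) * 1e-3, np.max(T) * 1e3
        tau = optimize.brentq(
            lambda x: cens_rate(x) - cfg.censoring_target, lo, hi
        )
        C = rng.uniform(0.0, tau, len(T))
        os_event = (T <= C).astype(int)
        os_time = np.minimum(T, C)
    os_time = np.maximum(os_time, 1e-6)

    eta_c = eta_raw - eta_raw.mean()
    age = np.clip(
        rng.normal(68.0, 10.0, len(T)) + cfg.age_coupling * eta_c, 30, 95
    ).round(1)
    sex = rng.integers(0, 2, len(T))
    # ordinal stage via latent logistic shifted by risk
    lat = cfg.stage_coupling * eta_c + rng.logistic(0.0, 1.0, len(T))
    # logistic quantiles for base stage frequencies 20/30/30/20%
    cuts = np.log(np.array([0.2, 0.5, 0.8]) / (1 - np.array([0.2, 0.5, 0.8])))
    stage = 1 + np.searchsorted(cuts, lat)
    lat_g = cfg.grade_coupling * eta_c + rng.logistic(0.0, 1.0, len(T))
    grade = 1 + (lat_g > 0).astype(int)

    data = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "age": age,
            "sex": sex,
            "grade": grade,
            "stage": stage,
        },
        index=pd.Index(tumor_samples, name="sample_id"),
    )
    return ClinicalTable(data=data, time_unit="days")


def simulate_associations(truth: GroundTruth, config: SimulationConfig):
    """Infiltration, IC50 and checkpoint-gene tables coupled to true risk.

    Returns ``(infiltration, ic50, ici)``:

    * infiltration: long DataFrame (cell_type, method, sample, value),
      values from a per-sample softmax of ``base + w*eta + noise`` over
      cell types, independently per estimation method tag;
    * ic50: drugs x samples DataFrame of ``base + v*eta + noise``;
    * ici: genes x samples DataFrame, same linear coupling model.
    """
    if truth.true_risk is None:
        raise ValueError("simulate_survival must run first (true risk needed)")
    cfg = config
    rng = _rng(cfg.seed, 2)
    samples = list(truth.true_risk.index)
    eta = truth.true_risk.to_numpy()
    eta_c = (eta - eta.mean()) / (eta.std() + 1e-12)

    cells = list(cfg.cell_couplings)
    w = np.array([cfg.cell_couplings[c] for c in cells])
    base = rng.normal(0.0, 0.5, len(cells))
    records = []
    for method in ("XCELL", "EPIC"):
        logits = (
            base[:, None]
            + np.outer(w, eta_c)
            + rng.normal(0.0, cfg.assoc_noise_sd, (len(cells), len(samples)))
        )
        fr = np.exp(logits - logits.max(axis=0))
        fr = fr / fr.sum(axis=0)
        for ci, cell in enumerate(cells):
            for si, s in enumerate(samples):
                records.append((cell, method, s, fr[ci, si]))
    infiltration = pd.DataFrame(
        records, columns=["cell_type", "method", "sample", "value"]
    )

    drugs = list(cfg.drug_couplings)
    v = np.array([cfg.drug_couplings[d] for d in drugs])
    ic50 = pd.DataFrame(
        rng.normal(2.0, 0.3, len(drugs))[:, None]
        + np.outer(v, eta_c)
        + rng.normal(0.0, cfg.assoc_noise_sd, (len(drugs), len(samples))),
        index=drugs,
        columns=samples,
    )

    genes = list(cfg.ici_couplings)
    u = np.array([cfg.ici_couplings[g] for g in genes])
    ici = pd.DataFrame(
        rng.normal(3.0, 0.5, len(genes))[:, None]
        + np.outer(u, eta_c)
        + rng.normal(0.0, cfg.assoc_noise_sd, (len(genes), len(samples))),
        index=genes,
        columns=samples,
    )
    return infiltration, ic50, ici


def simulate_dataset(config: SimulationConfig):
    """End-to-end convenience: expression, clinical, associations, truth."""
    expr, truth = simulate_expression(config)
    clinical = simulate_survival(expr, truth, config)
    infiltration, ic50, ici = simulate_associations(truth, config)
    return {
        "expression": expr,
        "clinical": clinical,
        "truth": truth,
        "infiltration": infiltration,
        "ic50": ic50,
        "ici": ici,
        "config": config,
    }
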
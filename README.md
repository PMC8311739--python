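# pairsig

Rank-based lncRNA-**pair** signatures for survival prognosis from bulk
tumor transcriptomes.

Single-gene expression signatures are fragile across cohorts because
they depend on normalization and platform. A pair signature instead
scores each patient by *within-sample expression ordering*: for a pair
of genes (A, B), the indicator

&nbsp;&nbsp;&nbsp;&nbsp;S<sub>i</sub> = 1 if expr(A) > expr(B) in that sample, else 0

is invariant to any monotone per-sample transform, so the fitted model
transfers without renormalization (the k-TSP idea applied to survival).
`pairsig` implements the full workflow for immune-related lncRNA pairs
in tumor cohorts (developed around TCGA-style bladder-cancer data):

1. **Screen** — lncRNAs correlated with an immune gene list
   (Pearson |r| > 0.6, p < 0.001 on log₂(x+1)), then differentially
   expressed between tumor and normal (|logFC| > 1, BH FDR < 0.05).
2. **Pair matrix** — all C(m,2) pair indicators over the screened
   lncRNAs; pairs whose 0s and 1s each cover ≥ 20 % of samples are kept.
3. **Selection** — univariate Cox screen (p < 0.01) → repeated
   cross-validated Lasso-Cox (1000 repetitions × 10-fold CV; pairs with
   selection frequency > 100 survive) → bidirectional stepwise Cox
   minimizing AIC. The survivors and their multivariate coefficients
   β<sub>i</sub> form the signature.
4. **Risk model** — RiskScore = Σ β<sub>i</sub> S<sub>i</sub>; patients are split at
   the cut-point c\* whose dichotomized Cox model minimizes the AIC;
   discrimination is reported as IPCW cumulative/dynamic AUC at 1, 3
   and 5 years, against numeric-coded clinical comparators.
5. **Validation & downstream** — Kaplan-Meier + log-rank between risk
   groups, chi-square and rank-sum tests against clinicopathological
   covariates, independence in multivariate Cox, and association of the
   risk groups with externally computed immune-infiltration,
   drug-IC50 and immune-checkpoint-gene tables.

The survival machinery (Efron-tie Cox by Newton-Raphson, Kaplan-Meier,
log-rank, IPCW time-dependent ROC, coordinate-descent L1 Cox paths) is
implemented in `pairsig.survival` and cross-checked in the test suite
against lifelines and scikit-survival. A synthetic-data module
(`pairsig.simulate`) generates cohorts with planted signature pairs,
proportional-hazards survival, censoring, and coupled clinical/immune/
drug variables so every stage has a recoverable ground truth.

## Worked example

Simulate a default-scale cohort (400 tumors, 19 normals, 300 lncRNAs,
10 planted pairs) and run the whole pipeline with the fast selection
preset (100 Lasso repetitions, frequency threshold 10):

```bash
pairsig simulate --seed 7 --out demo/
cd demo
pairsig run-all \
  --expression expression.tsv --conditions conditions.tsv \
  --biotypes biotypes.tsv --immune immune_genes.txt \
  --clinical clinical.tsv --infiltration infiltration.tsv \
  --ic50 ic50.tsv --ici ici_expr.tsv \
  --out results --preset fast --seed 7
```

This finishes in about two minutes and prints the run report, whose
stage-count funnel reads:

```
n_lncrna_tested    300
n_irlncrna         119
n_deirlncrna        99
n_pairs           4851
n_valid_pairs     2047
n_univariate_pass   93
n_lasso_pass        56
k_signature         34
cutpoint        -1.520953
n_high_risk        240
n_low_risk         160
logrank_p       1.95e-49
```

Reading the funnel: of 300 lncRNAs, 119 pass the immune-coexpression
screen and 99 of those are differentially expressed; their 4851 pairs
reduce to 2047 after the prevalence filter, 93 after the univariate
Cox screen, 56 after repeated Lasso-Cox, and stepwise AIC keeps a
34-pair signature. The AIC-optimal cut-point −1.52 splits the cohort
into 240 high-risk and 160 low-risk patients whose survival separates
at log-rank p ≈ 2×10⁻⁴⁹. The accompanying `results/auc.tsv` reports
1/3/5-year IPCW AUCs of 0.888 / 0.894 / 0.897, against 1-year
comparator AUCs of 0.64 (age), 0.60 (grade), 0.69 (stage) and 0.50
(sex); `results/chemo_assoc.tsv` recovers the planted drug couplings
(higher gefitinib IC50 and lower cisplatin/docetaxel IC50 in the
high-risk group, gemcitabine null). All outputs are tab-separated
tables ready for plotting.

Each stage is also available as its own subcommand (`screen`, `pairs`,
`select`, `fit`, `validate`, `associate`), resumable from the TSV
artifacts of the previous stage, and as library calls
(`pairsig.run_pipeline` on in-memory objects).

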
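# Methods

## The model

A patient's risk is modeled through binary *relative-ordering*
features. For an ordered gene pair (A, B) with A < B alphabetically,
the indicator S(A,B) is 1 when A's abundance strictly exceeds B's
within the sample and 0 otherwise — ties score 0. Because S compares
two genes inside one sample, it is unchanged by any strictly
increasing per-sample transform of the abundances; the signature
therefore needs no cross-cohort normalization. The hazard model is
Cox proportional hazards on the selected indicators,

    h(t | S) = h0(t) · exp( Σ_i beta_i · S_i ),

and the reported RiskScore is the linear predictor Σ beta_i S_i. The
key assumptions are proportional hazards, independent (conditionally
non-informative) right censoring, and that prognostic information is
captured by orderings rather than magnitudes.

## Pipeline stages and their parameters

**Immune-coexpression screen.** Pearson correlation on log2(x+1)
between every lncRNA-biotype gene and every immune-list gene, over all
samples by default (`coexpr_samples` can restrict to tumors). A lncRNA
passes if any partner reaches `r_threshold` (default 0.6; `mode`
`absolute` uses |r|, `positive` uses signed r) at raw p <
`coexpr_p_threshold` (default 1e-3; the p comes from the t transform
of r with n−2 df and is deliberately not multiplicity-adjusted — the
screen is a generous pre-filter, and later stages carry the error
control). Constant genes have undefined correlation and are skipped,
never propagated as NaN.

**Differential expression.** logFC is the difference in mean log2(x+1)
between tumor and normal samples; the default test is the Wilcoxon
rank-sum with BH adjustment (`fdr_threshold` 0.05) and a strict
|logFC| > `lfc_threshold` (1.0) cut. The rank-sum default is
dependency-light and robust to the heavy tails of abundance data; a
moderated pooled-variance t-test (prior df equal to the residual df)
is available via `de_method=modt`. The downstream pipeline is agnostic
to the DE engine.

**Pair matrix.** All C(m,2) unordered pairs of the surviving lncRNAs,
canonical orientation alphabetical (coefficient signs absorb
orientation, so results are orientation-invariant). The prevalence
filter keeps pairs with `min_frac` ≤ freq1 ≤ 1−`min_frac`
(default 0.2, boundaries inclusive, symmetric by construction): an
indicator that is almost always 0 or almost always 1 carries no
contrast for model fitting.

**Selection funnel.** (1) Per-pair univariate Cox, keep Wald p <
`screen_p` (default 0.01). (2) Repeated cross-validated Lasso-Cox:
each repetition draws its own `folds`-fold partition (default 10) from
a child stream of the master seed, picks lambda minimizing the
Verweij-van Houwelingen cross-validated partial-likelihood deviance,
and the pairs with nonzero coefficients at that lambda increment a
frequency counter; pairs with frequency strictly greater than
`freq_threshold` survive. A one-standard-error lambda rule
(`lambda_rule='1se'`: the largest lambda whose fold deviance is within
one SE of the minimum) is available for sparser selections; the
default is the minimizer. The canonical preset is 1000 repetitions /
threshold 100 (`paper`); the `fast` preset (100/10) scales both
together and is used throughout the test suite. (3) Bidirectional
stepwise Cox minimizing AIC from the full model; the selected pairs
and their multivariate coefficients form the signature. The stages are
nested by construction.

**Cut-point and discrimination.** Candidate cut-points are midpoints
between consecutive distinct scores inside the 10th-90th percentile
band with at least 10 samples on each side (guards against degenerate
splits); each candidate's dichotomized single-covariate Cox model is
fitted and the AIC-minimizing cut wins, ties toward the smaller value;
if no candidate is feasible the median split is used and flagged. A
ROC-based alternative (`cutpoint_method='youden'`, maximizing
sensitivity + specificity − 1 on the IPCW ROC at the cut-point
horizon) is available for sensitivity analysis.
Discrimination uses the cumulative/dynamic time-dependent ROC with
inverse-probability-of-censoring weights from the Kaplan-Meier
estimate of the censoring distribution; horizons default to 1/3/5
years with `days_per_year` = 365.25 converting to the clinical time
unit. Clinical comparators (age, grade, stage, sex) enter the 1-year
ROC as numeric-coded scores.

**Validation and associations.** Risk groups are compared by log-rank
(the companion test to the Kaplan-Meier curves); clinicopathological
association uses Pearson chi-square without continuity correction
(large-count 2×C tables; a Yates flag exists), the risk score across
clinical strata uses two-sided Mann-Whitney rank-sum tests (exact
enumeration when both groups ≤ 8 and untied, tie-corrected normal
approximation otherwise) — rank-sum rather than signed-rank because
the strata are independent groups. External estimate tables
(infiltration in TIMER2.0-style long format or wide matrices, IC50,
checkpoint-gene expression) are tested per feature by rank-sum between
risk groups (raw p against `alpha` = 0.05, BH column emitted
alongside) and by Spearman correlation against the continuous score;
a `consensus` flag marks cell types whose significant directions agree
across ≥ 2 estimation methods instead of silently dropping
inconsistent ones.

## The survival engine

Cox models maximize the Efron-tie-corrected log partial likelihood by
Newton-Raphson with step-halving; convergence when the scaled step
falls below 1e-9 or 100 iterations; standard errors from the inverse
observed information; Wald p-values and CIs (matching forest-plot
conventions). Monotone likelihood (perfect separation) is detected by
|beta| exceeding 15, capped and flagged; constant covariates are
dropped with a warning and reported with beta = 0. The L1-penalized
path minimizes −(1/n)·logPL + λ‖β‖₁ on internally standardized
covariates by coordinate descent on the IRLS quadratic approximation
(per-subject gradient and positive-part diagonal curvature of the
Efron likelihood), warm-started down a log-spaced grid from λmax
(inflated by 1e-6 so the first point is strictly all-zero);
coordinate-descent tolerance 1e-7 on standardized coefficients, IRLS
tolerance 1e-6 on the linear predictor. Cross-validation fold fits use
relaxed tolerances (1e-5 / 1e-3) — the deviance curve and selection
frequencies are insensitive at that level, which was verified against
tightly-converged references before adoption. The kernel is compiled
with numba when available; a pure-Python fallback with identical
semantics is used otherwise.

The stepwise search ranks candidate moves by cheap surrogates — the
Wald statistic of each coefficient for drops, the Rao score statistic
at the current fit for additions — and exactly refits only the eight
most promising moves per iteration, accepting the best exact AIC
improvement and stopping when none improves. This keeps the search
near-exact (accept/stop decisions always use exact AICs and the final
model's AIC can never exceed the full model's) at a fraction of the
fit count.

## The synthetic cohorts

The generator emulates exactly the structure the analysis assumes, at
the default scale of 400 tumors and 19 normals. On the log2 scale,
each of 120 coexpressed lncRNAs shares a latent standard-normal factor
with its own immune-gene partner with loading sqrt(rho) (rho = 0.75,
comfortably above the 0.6 screen); the first 100 of them receive a
tumor-mean shift of at least 1.5 log2 units (above the logFC > 1
screen), 75 % upward; 10 planted pairs are formed from consecutive DE
lncRNAs whose tumor-side means are equalized so the indicator sits
near 50 % prevalence; effect sizes |beta_true| run 0.5-1.0 with
alternating signs. Survival is Weibull (default exponential) with
baseline median five years at eta = 0 and hazard multiplier exp(eta),
eta = Σ beta_true·S; censoring is administrative-uniform on (0, tau)
with tau solved by root-finding so the realized censoring fraction
matches the 35 % target, mimicking heavy administrative censoring of
registry cohorts. Age gains an additive 3·eta term, stage and grade
shift with eta through latent-logistic ordinal models, sex is
independent. Infiltration fractions are a per-sample softmax of
base + w·eta + noise per cell type (macrophage/fibroblast-like
positive, CD4/dendritic-like negative, two null controls), drug
log-IC50 and checkpoint-gene values are linear in eta with
configurable signs (gefitinib-like positive, cisplatin/docetaxel-like
negative, gemcitabine null). A `threshold_effect` mode replaces the
linear hazard term with a jump exp(gamma) where eta exceeds a planted
cut, making cut-point recovery well-posed.

What the generator does **not** emulate: library-size artifacts, batch
effects, count noise, gene-gene correlation beyond the planted
factors, non-proportional hazards, or informative censoring. Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct under its own assumptions — not that those assumptions hold in
any particular real cohort.

## Problem sizes used in the checks

Unit tests run on scaled-down cohorts (≈150 tumors, 80 lncRNAs, 5
planted pairs). The recovery study — also what
`scripts/acceptance.py` reports — uses five independent cohorts at the
full default scale with the `fast` selection preset, plus five
held-out cohorts for external-cohort AUC and five hazard-jump cohorts
for cut-point recovery; these sizes give stable aggregate metrics
while a study stays within a few minutes on one CPU. Null-calibration
checks use 200 simulation seeds per statistic.

## Known limitations

- The pair count grows quadratically in the DE set; cohorts with
  thousands of DE lncRNAs would need pre-thinning (out of scope).
- The AIC cut-point is estimated on the same cohort used to fit the
  signature; like the original workflow it carries optimism, which the
  held-out-cohort AUC in the recovery study quantifies under
  simulation.
- Correlated pairs that share genes with true signature pairs can
  enter the model as proxies; the selection frequency and stepwise AIC
  reduce but do not eliminate this, so recovered signatures are
  supersets of the planted pairs more often than misses.
- IC50 and infiltration tables are consumed, never computed;
  deconvolution and drug-response imputation live upstream.
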
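import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairsig.screen import screen_irlncrnas
from pairsig.simulate import (
    SimulationConfig,
    simulate_associations,
    simulate_dataset,
    simulate_expression,
    simulate_survival,
    true_pair_indicators,
)
from pairsig.survival import logrank_test

from conftest import small_config


class TestConfigValidation:
    def test_more_de_than_coexpressed_rejected(self):
        with pytest.raises(ValueError, match="DE lncRNAs"):
            SimulationConfig(n_coexpressed_lnc=10, n_de_lnc=20)

    def test_pairs_need_enough_genes(self):
        with pytest.raises(ValueError, match="planted pairs"):
            small_config(n_planted_pairs=20)

    def test_censoring_target_bounds(self):
        with pytest.raises(ValueError, match="censoring"):
            SimulationConfig(censoring_target=1.0)


class TestExpression:
    def test_bit_identical_reproducibility(self):
        cfg = small_config(seed=42)
        e1, t1 = simulate_expression(cfg)
        e2, t2 = simulate_expression(cfg)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        assert t1.planted_pairs == t2.planted_pairs

    def test_rho_one_gives_exact_unit_correlation(self):
        cfg = small_config(seed=1, coexpression_rho=1.0)
        expr, truth = simulate_expression(cfg)
        # use a coexpressed but non-DE lncRNA: a tumor mean shift would
        # offset the two conditions and break exact affinity
        idx = cfg.n_de_lnc
        lnc = truth.irlncrna_set[idx]
        imm = f"IMM{idx + 1:04d}"  # partner shares the whole latent factor
        x = np.log2(expr.values.loc[lnc].to_numpy() + 1)
        y = np.log2(expr.values.loc[imm].to_numpy() + 1)
        # clipping at zero abundance can break exact affinity; restrict to
        # samples where neither gene was clipped
        ok = (expr.values.loc[lnc].to_numpy() > 0) & (expr.values.loc[imm].to_numpy() > 0)
        r = np.corrcoef(x[ok], y[ok])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_planted_coexpression_passes_screen(self):
        cfg = SimulationConfig(seed=1)
        expr, truth = simulate_expression(cfg)
        res = screen_irlncrnas(expr, [g for g in expr.gene_ids if g.startswith("IMM")])
        passed = {r.lncrna for r in res if r.passed}
        frac = len(passed & set(truth.irlncrna_set)) / len(truth.irlncrna_set)
        assert frac >= 0.9

    def test_values_non_negative_fpkm_like(self, small_dataset):
        assert (small_dataset["expression"].values.to_numpy() >= 0).all()


class TestSurvival:
    def test_zero_censoring_target_all_events(self):
        cfg = small_config(seed=2, censoring_target=0.0)
        expr, truth = simulate_expression(cfg)
        clin = simulate_survival(expr, truth, cfg)
        assert (clin.data["os_event"] == 1).all()

    def test_censoring_rate_near_target(self):
        cfg = small_config(seed=3, n_tumor=400)
        expr, truth = simulate_expression(cfg)
        clin = simulate_survival(expr, truth, cfg)
        rate = 1.0 - clin.data["os_event"].mean()
        assert abs(rate - cfg.censoring_target) < 0.08

    def test_strong_pair_shortens_survival_every_seed(self):
        for seed in range(10):
            cfg = small_config(
                seed=seed, n_planted_pairs=1, planted_betas=(2.0,), censoring_target=0.0
            )
            expr, truth = simulate_expression(cfg)
            clin = simulate_survival(expr, truth, cfg)
            S = true_pair_indicators(expr, truth).iloc[0]
            t1 = clin.data.loc[S[S == 1].index, "os_time"].median()
            t0 = clin.data.loc[S[S == 0].index, "os_time"].median()
            assert t1 < t0

    def test_null_betas_logrank_uniform(self):
        # with no planted effect, a random split's log-rank p is U(0,1)
        pvals = []
        for seed in range(120):
            cfg = small_config(
                seed=seed,
                n_tumor=60,
                n_planted_pairs=1,
                planted_betas=(0.0,),
            )
            expr, truth = simulate_expression(cfg)
            clin = simulate_survival(expr, truth, cfg)
            rng = np.random.default_rng(seed + 1000)
            g = rng.integers(0, 2, len(clin.data))
            if g.sum() in (0, len(g)):
                continue
            _, p = logrank_test(
                clin.data["os_time"].to_numpy(),
                clin.data["os_event"].to_numpy(),
                g,
            )
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_logrank_power_monotone_in_beta(self):
        # planted-effect monotonicity over a 3-point effect grid
        power = []
        for beta in (0.0, 0.8, 2.0):
            hits = 0
            runs = 30
            for seed in range(runs):
                cfg = small_config(
                    seed=seed,
                    n_tumor=100,
                    n_planted_pairs=1,
                    planted_betas=(beta,),
                )
                expr, truth = simulate_expression(cfg)
                clin = simulate_survival(expr, truth, cfg)
                S = true_pair_indicators(expr, truth).iloc[0].to_numpy()
                if S.sum() in (0, len(S)):
                    continue
                _, p = logrank_test(
                    clin.data["os_time"].to_numpy(),
                    clin.data["os_event"].to_numpy(),
                    S,
                )
                hits += p < 0.05
            power.append(hits / runs)
        assert power[0] <= power[1] <= power[2]
        assert power[2] > 0.9

    def test_covariates_coupled_to_risk(self):
        cfg = small_config(seed=5, n_tumor=400)
        expr, truth = simulate_expression(cfg)
        clin = simulate_survival(expr, truth, cfg)
        eta = truth.true_risk
        assert np.corrcoef(clin.data["age"], eta)[0, 1] > 0.1
        assert stats.spearmanr(clin.data["stage"], eta).statistic > 0.1
        # sex independent of risk
        assert abs(np.corrcoef(clin.data["sex"], eta)[0, 1]) < 0.15


class TestAssociations:
    def test_extreme_coupling_gives_perfect_spearman(self):
        cfg = small_config(
            seed=6,
            cell_couplings={"OnlyCell": 5.0, "Other": 0.0},
            assoc_noise_sd=0.0,
        )
        expr, truth = simulate_expression(cfg)
        simulate_survival(expr, truth, cfg)
        infl, _, _ = simulate_associations(truth, cfg)
        sub = infl[(infl["cell_type"] == "OnlyCell") & (infl["method"] == "XCELL")]
        merged = sub.set_index("sample")["value"].loc[truth.true_risk.index]
        rho = stats.spearmanr(truth.true_risk, merged).statistic
        assert rho == pytest.approx(1.0)

    def test_drug_coupling_direction(self):
        ups, downs = 0, 0
        for seed in range(10):
            cfg = small_config(seed=seed, n_tumor=200)
            expr, truth = simulate_expression(cfg)
            simulate_survival(expr, truth, cfg)
            _, ic50, _ = simulate_associations(truth, cfg)
            hi = truth.true_risk > truth.true_risk.median()
            gef = ic50.loc["gefitinib"]
            cis = ic50.loc["cisplatin"]
            ups += gef[hi.values].median() > gef[~hi.values].median()
            downs += cis[hi.values].median() < cis[~hi.values].median()
        assert ups >= 9 and downs >= 9

    def test_requires_survival_first(self):
        cfg = small_config(seed=7)
        _, truth = simulate_expression(cfg)
        with pytest.raises(ValueError, match="survival"):
            simulate_associations(truth, cfg)


def test_dataset_bundle_is_reproducible():
    d1 = simulate_dataset(small_config(seed=9))
    d2 = simulate_dataset(small_config(seed=9))
    pd.testing.assert_frame_equal(d1["expression"].values, d2["expression"].values)
    pd.testing.assert_frame_equal(d1["clinical"].data, d2["clinical"].data)
    pd.testing.assert_frame_equal(d1["infiltration"], d2["infiltration"])
    assert d1["truth"].to_text() == d2["truth"].to_text()
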
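"""Oracle tests for the survival-statistics engine.

Every estimator is checked against an independent route: explicit
partial-likelihood formulas evaluated by grid search or hand-coded
sums, manual product-limit and risk-set tables, enumeration AUC, and
the lifelines implementations on random cohorts.
"""

import numpy as np
import pytest

from pairsig.survival import (
    cox_fit,
    cox_loglik,
    cv_lasso_cox,
    km_estimate,
    lasso_cox_path,
    logrank_test,
    td_roc,
)

from conftest import exponential_cohort


# ---------------------------------------------------------------------------
# Cox regression

# 4 subjects, no ties, covariate interleaved in time so the likelihood
# has an interior maximum (a time-monotone 0/1 covariate would separate)
T4 = np.array([1.0, 2.0, 3.0, 4.0])
E4 = np.array([1, 1, 1, 1])
X4 = np.array([0.0, 1.0, 0.0, 1.0])


def _pl4(beta):
    """Explicit log partial likelihood for the 4-subject fixture."""
    w = np.exp(beta * X4)
    ll = 0.0
    for i in range(4):
        ll += beta * X4[i] - np.log(w[i:].sum())
    return ll


class TestCoxFit:
    def test_matches_grid_search_maximizer(self):
        grid = np.arange(-5.0, 5.0 + 1e-12, 1e-4)
        beta_grid = grid[np.argmax([_pl4(b) for b in grid])]
        fit = cox_fit(T4, E4, X4)
        assert fit.converged
        assert abs(fit.beta[0] - beta_grid) < 1e-3

    def test_efron_loglik_on_tied_fixture(self):
        # two events tied at t=2; hand-evaluated Efron sum
        t = np.array([1.0, 2.0, 2.0, 3.0])
        e = np.array([1, 1, 1, 0])
        x = np.array([0.5, 1.0, 0.0, -1.0])

        def efron_ll(beta):
            w = np.exp(beta * x)
            ll = beta * x[0] - np.log(w.sum())  # event at t=1
            risk = w[1:].sum()  # risk set at t=2: subjects 1,2,3
            dsum = w[1] + w[2]
            ll += beta * (x[1] + x[2])
            ll -= np.log(risk) + np.log(risk - 0.5 * dsum)
            return ll

        fit = cox_fit(t, e, x)
        assert np.isclose(fit.loglik, efron_ll(fit.beta[0]), atol=1e-10)
        # and the engine's standalone evaluator agrees off-optimum too
        for b in (-0.7, 0.0, 1.3):
            assert np.isclose(cox_loglik(t, e, x, [b]), efron_ll(b), atol=1e-10)

    def test_constant_covariate_reports_null_effect(self):
        with pytest.warns(UserWarning, match="constant"):
            fit = cox_fit(T4, E4, np.zeros(4))
        assert fit.beta[0] == 0.0
        assert fit.hr[0] == 1.0

    def test_matches_lifelines_untied_and_tied(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(42)
        times, events, X = exponential_cohort(rng, n=250, beta=np.array([0.8, -0.5, 0.0]))
        fit = cox_fit(times, events, X)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["t"], df["e"] = times, events
        ref = lifelines.CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.beta, ref.params_.values, atol=1e-4)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.values, atol=1e-4)
        # tied times
        tt = np.array([1.0, 2, 2, 3, 4, 4, 4, 5])
        ee = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        xx = np.array([0.0, 1, 0, 1, 1, 0, 1, 0])
        f2 = cox_fit(tt, ee, xx)
        df2 = pd.DataFrame({"x": xx, "t": tt, "e": ee})
        r2 = lifelines.CoxPHFitter().fit(df2, "t", "e")
        assert abs(f2.beta[0] - r2.params_.values[0]) < 1e-5
        assert abs(f2.loglik - r2.log_likelihood_) < 1e-8

    def test_score_equation_zero_at_optimum(self):
        rng = np.random.default_rng(3)
        times, events, X = exponential_cohort(rng, n=150, beta=np.array([0.5, 0.0, -0.3]))
        fit = cox_fit(times, events, X)
        eps = 1e-6
        for j in range(3):
            b1 = fit.beta.copy()
            b1[j] += eps
            b0 = fit.beta.copy()
            b0[j] -= eps
            deriv = (
                cox_loglik(times, events, X, b1) - cox_loglik(times, events, X, b0)
            ) / (2 * eps)
            assert abs(deriv) < 1e-5

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        times, events, X = exponential_cohort(rng, n=120, beta=np.array([0.6, -0.4, 0.2]))
        fit = cox_fit(times, events, X)
        X2 = X.copy()
        X2[:, 0] = 10.0 * X[:, 0] + 3.0
        fit2 = cox_fit(times, events, X2)
        assert abs(fit2.beta[0] - fit.beta[0] / 10.0) < 1e-7
        np.testing.assert_allclose(fit2.beta[1:], fit.beta[1:], atol=1e-7)

    def test_ridge_penalty_shrinks_toward_zero(self):
        fit0 = cox_fit(T4, E4, X4)
        fitr = cox_fit(T4, E4, X4, penalty=5.0)
        assert abs(fitr.beta[0]) < abs(fit0.beta[0])


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


class TestKaplanMeier:
    def test_uncensored_empirical_survival(self):
        km = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_stays_at_one(self):
        km = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        np.testing.assert_allclose(km.survival, [1.0, 1.0, 1.0])

    def test_mixed_fixture_hand_product_limit(self):
        # 8 subjects; hand-computed product-limit steps
        t = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        e = np.array([1, 1, 0, 1, 0, 1, 0, 1])
        km = km_estimate(t, e)
        # risk sets: t=1 n=8 d=1 -> 7/8; t=2 n=7 d=1 -> *6/7; t=3 n=5 d=1 -> *4/5
        # t=5 n=3 d=1 -> *2/3; t=7 n=1 d=1 -> *0
        expected = {
            1.0: 7 / 8,
            2.0: 7 / 8 * 6 / 7,
            3.0: 7 / 8 * 6 / 7 * 4 / 5,
            5.0: 7 / 8 * 6 / 7 * 4 / 5 * 2 / 3,
            7.0: 0.0,
        }
        got = dict(zip(km.times, km.survival))
        for time, s in expected.items():
            assert np.isclose(got[time], s)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        times, events, _ = exponential_cohort(rng, n=80)
        km = km_estimate(times, events)
        ref = lifelines.KaplanMeierFitter().fit(times, events)
        ours = km.evaluate(km.times)
        theirs = ref.survival_function_at_times(km.times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_risk_set_table(self):
        # group A events at 1,2; group B events at 3,4
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        g = np.array([0, 0, 1, 1])
        # per event time (nA at risk, n at risk): E_A = sum d*nA/n
        # t=1: 2/4; t=2: 1/3; t=3: 0; t=4: 0 -> E_A = 5/6, O_A = 2
        # V = sum d*(nA/n)(1-nA/n)(n-d)/(n-1):
        # t=1: (2/4)(2/4)(3/3)=1/4 ; t=2: (1/3)(2/3)(2/2)=2/9 ; t=3: (0)(1)(1)=0; t=4: 0
        O_A, E_A, V = 2.0, 5 / 6, 1 / 4 + 2 / 9
        chi2, p = logrank_test(t, e, 1 - g)  # label order irrelevant for chi2
        assert chi2 == pytest.approx((O_A - E_A) ** 2 / V)

    def test_matches_lifelines_statistic(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(9)
        times, events, X = exponential_cohort(rng, n=100, beta=np.array([1.0, 0, 0]))
        g = (X[:, 0] > 0).astype(int)
        chi2, p = logrank_test(times, events, g)
        ref = ll_logrank(times[g == 0], times[g == 1], events[g == 0], events[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            logrank_test(np.array([1.0, 2.0]), np.array([1, 1]), np.array([0, 0]))


# ---------------------------------------------------------------------------
# time-dependent ROC


class TestTdRoc:
    def test_perfect_ranking_auc_one(self):
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6)
        score = -t  # earlier death = higher score
        r = td_roc(t, e, score, horizon=5.0)
        assert r.auc == 1.0

    def test_uncensored_equals_enumeration(self):
        # no censoring: IPCW weights are all 1, AUC = case/control win fraction
        t = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 9.0])
        e = np.ones(6, dtype=int)
        score = np.array([2.0, 0.5, 1.5, 1.5, 0.0, 1.0])
        horizon = 5.0
        cases = score[t <= horizon]
        controls = score[t > horizon]
        wins = sum(
            1.0 if c > d else (0.5 if c == d else 0.0)
            for c in cases
            for d in controls
        )
        r = td_roc(t, e, score, horizon)
        assert r.auc == pytest.approx(wins / (len(cases) * len(controls)))
        assert r.n_cases == 3 and r.n_controls == 3

    def test_roc_endpoints(self):
        rng = np.random.default_rng(2)
        times, events, X = exponential_cohort(rng, n=60, beta=np.array([1.0, 0, 0]))
        r = td_roc(times, events, X[:, 0], np.median(times))
        assert r.sensitivity[0] == 0.0 and r.specificity[0] == 1.0
        assert r.sensitivity[-1] == 1.0 and r.specificity[-1] == 0.0

    def test_no_cases_raises(self):
        t = np.array([5.0, 6.0, 7.0])
        e = np.array([1, 1, 1])
        with pytest.raises(ValueError, match="horizon"):
            td_roc(t, e, t, horizon=1.0)

    def test_matches_sksurv_cumulative_dynamic_auc(self):
        sksurv = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(31)
        times, events, X = exponential_cohort(rng, n=150, beta=np.array([1.0, 0, 0]))
        score = X[:, 0]
        horizon = np.quantile(times, 0.4)
        y = np.array(
            [(bool(e_), t_) for e_, t_ in zip(events, times)],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        ref_auc, _ = sksurv.cumulative_dynamic_auc(y, y, score, [horizon])
        r = td_roc(times, events, score, horizon)
        assert r.auc == pytest.approx(float(ref_auc[0]), abs=5e-3)


# ---------------------------------------------------------------------------
# lasso path


class TestLassoPath:
    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(1)
        times, events, X = exponential_cohort(rng, n=100, beta=np.array([0.8, -0.5, 0.0]))
        lambdas, coefs, _ = lasso_cox_path(times, events, X, n_lambda=10)
        assert np.all(coefs[0] == 0.0)

    def test_lambda_zero_matches_unpenalized_fit(self):
        rng = np.random.default_rng(1)
        times, events, X = exponential_cohort(rng, n=100, beta=np.array([0.8, -0.5, 0.0]))
        fit = cox_fit(times, events, X)
        _, coefs, flags = lasso_cox_path(times, events, X, lambda_grid=[1e-10])
        assert not flags
        np.testing.assert_allclose(coefs[0], fit.beta, atol=1e-4)

    def test_strong_covariate_enters_first(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 6))
        beta = np.zeros(6)
        beta[2] = 1.5
        T = rng.exponential(1.0 / np.exp(X @ beta - (X @ beta).mean()))
        C = rng.exponential(2.0, 300)
        times, events = np.minimum(T, C), (T <= C).astype(int)
        _, coefs, _ = lasso_cox_path(times, events, X, n_lambda=60)
        first_nonzero = next(
            set(np.flatnonzero(row)) for row in coefs if np.any(row != 0)
        )
        assert first_nonzero == {2}

    def test_cv_selects_informative_covariates(self):
        rng = np.random.default_rng(8)
        X = (rng.random((250, 12)) < 0.5).astype(float)
        beta = np.zeros(12)
        beta[:2] = [1.2, -1.2]
        T = rng.exponential(1.0 / np.exp(X @ beta - (X @ beta).mean()))
        C = rng.exponential(2.0, 250)
        times, events = np.minimum(T, C), (T <= C).astype(int)
        lam, b, lambdas, dev = cv_lasso_cox(times, events, X, folds=5, rng=0, n_lambda=25)
        assert b[0] > 0 and b[1] < 0
        assert np.isfinite(dev).all()

    def test_one_se_rule_is_sparser_or_equal(self):
        rng = np.random.default_rng(11)
        X = (rng.random((250, 12)) < 0.5).astype(float)
        beta = np.zeros(12)
        beta[:2] = [1.2, -1.2]
        T = rng.exponential(1.0 / np.exp(X @ beta - (X @ beta).mean()))
        C = rng.exponential(2.0, 250)
        times, events = np.minimum(T, C), (T <= C).astype(int)
        lam_min, b_min, _, _ = cv_lasso_cox(
            times, events, X, folds=5, rng=2, n_lambda=25
        )
        lam_1se, b_1se, _, _ = cv_lasso_cox(
            times, events, X, folds=5, rng=2, n_lambda=25, lambda_rule="1se"
        )
        assert lam_1se >= lam_min
        assert np.count_nonzero(b_1se) <= np.count_nonzero(b_min)
        assert b_1se[0] > 0 and b_1se[1] < 0  # strong effects survive

    def test_determinism_same_rng_seed(self):
        rng = np.random.default_rng(6)
        times, events, X = exponential_cohort(rng, n=120, beta=np.array([0.8, 0, 0]))
        out1 = cv_lasso_cox(times, events, X, folds=5, rng=123, n_lambda=15)
        out2 = cv_lasso_cox(times, events, X, folds=5, rng=123, n_lambda=15)
        assert out1[0] == out2[0]
        np.testing.assert_array_equal(out1[1], out2[1])
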
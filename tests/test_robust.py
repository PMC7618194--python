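"""ROI statistics: robust regression against OLS/statsmodels oracles, effect
sizes and their printed-value checks, correlation comparison tests, the
moderation model, and BH-FDR behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import qsmpet as q
from qsmpet.robust import (
    RobustLinearRegression,
    bh_fdr,
    build_design_matrix,
    cohens_d_ci,
    pearson_p_from_r,
)


class TestRobustLinearRegression:
    def test_noiseless_fit_is_exact(self):
        x = np.linspace(0, 1, 30)
        X = np.column_stack([np.ones(30), x])
        est = RobustLinearRegression().fit(X, 2 + 3 * x)
        assert np.allclose(est.coef_, [2, 3], atol=1e-10)
        assert est.scale_ < 1e-8

    def test_agrees_with_ols_on_clean_gaussian_data(self, rng):
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        beta = np.array([1.0, 2.0, -0.5])
        y = X @ beta + rng.normal(size=n)
        est = RobustLinearRegression().fit(X, y)
        ols_coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        ols_resid = y - X @ ols_coef
        ols_se = np.sqrt(
            np.diag(np.linalg.inv(X.T @ X)) * (ols_resid @ ols_resid) / (n - 3)
        )
        comb = np.sqrt(est.se_**2 + ols_se**2)
        assert np.all(np.abs(est.coef_ - ols_coef) < 3 * comb)

    def test_huber_beats_ols_under_gross_outlier(self):
        wins = 0
        n_rep = 200
        for s in range(n_rep):
            r = np.random.default_rng(s)
            x = r.normal(size=60)
            y = x + 0.5 * r.normal(size=60)
            k = int(np.argmax(np.abs(x)))  # a leveraged gross outlier
            y[k] += 20 * 0.5  # 20 residual SDs
            X = np.column_stack([np.ones(60), x])
            rob = RobustLinearRegression().fit(X, y).coef_[1]
            ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
            wins += abs(rob - 1) < abs(ols - 1)
        assert wins / n_rep >= 0.95

    def test_reduces_to_ols_for_huge_tuning_constant(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1, 2] + rng.standard_t(df=3, size=n)
        est = RobustLinearRegression(t_const=1e8).fit(X, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(est.coef_, ols, atol=1e-6)

    def test_matches_statsmodels_rlm(self, rng):
        import statsmodels.api as sm

        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ [0.5, 1.0, -2.0] + rng.standard_t(df=4, size=n)
        est = RobustLinearRegression(max_iter=100, tol=1e-10).fit(X, y)
        ref = sm.RLM(y, X, M=sm.robust.norms.HuberT(1.345)).fit(
            maxiter=100, tol=1e-10, scale_est="mad", conv="coefs", cov="H1"
        )
        assert np.allclose(est.coef_, ref.params, atol=1e-9)
        assert np.allclose(est.se_, ref.bse, rtol=1e-8)

    def test_rank_deficient_design_names_columns(self, cohort):
        X = np.column_stack([np.ones(20), np.arange(20), 2 * np.arange(20)])
        with pytest.raises(ValueError, match="collinear"):
            RobustLinearRegression().fit(X, np.zeros(20), feature_names=["i", "a", "b"])

    def test_design_matrix_encoding_and_missing_drop(self, cohort):
        design = q.DesignSpec(
            "sn_vta_susceptibility", "group", ["age", "sex", "smoking", "thc_positive"]
        )
        y, Xdf = build_design_matrix(cohort, design)
        for col in ("(Intercept)", "group[patient]", "smoking[current]",
                    "smoking[past]", "sex[male]"):
            assert col in Xdf.columns
        assert "smoking[never]" not in Xdf.columns
        fit = q.fit_robust_lm(cohort, design)
        assert set(fit.table.columns) == {"coef", "se", "t", "p", "ci_low", "ci_high"}
        t = fit.table
        assert ((t.ci_low <= t.coef) & (t.coef <= t.ci_high)).all()
        assert t.p.between(0, 1).all()


class TestCohensD:
    def test_null_case(self):
        d, lo, hi = q.cohens_d([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert d == 0 and lo == -hi

    def test_hand_computed_two_point_groups(self):
        d, _, _ = q.cohens_d([0.0, 2.0], [1.0, 3.0])
        assert np.isclose(d, 1 / np.sqrt(2))

    def test_printed_ci_for_study_groups(self):
        lo, hi = cohens_d_ci(-0.66, 80, 79)
        assert round(lo, 2) == -0.98 and round(hi, 2) == -0.34

    def test_antisymmetric_under_group_swap(self, rng):
        a, b = rng.normal(size=30), rng.normal(1, 1, size=40)
        d1, lo1, hi1 = q.cohens_d(a, b)
        d2, lo2, hi2 = q.cohens_d(b, a)
        assert np.isclose(d1, -d2) and np.isclose(lo1, -hi2) and np.isclose(hi1, -lo2)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            q.cohens_d([1.0, 1.0], [2.0, 2.0])


class TestPearson:
    def test_identity_correlation(self):
        x = np.arange(10.0)
        r, p = q.pearson_with_p(x, x)
        assert np.isclose(r, 1.0)

    def test_printed_p_for_study_correlation(self):
        # r = -0.44 at the PET subsample size prints as p = 0.005 (the exact
        # t-transform value is 0.0045, one ULP below at 3 printed decimals)
        p = pearson_p_from_r(-0.44, 40)
        assert abs(p - 0.005) <= 1e-3

    def test_analytic_p_matches_permutation(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        r, p = q.pearson_with_p(x, y)
        n_perm = 20000
        count = 0
        for _ in range(n_perm):
            rp = np.corrcoef(x, rng.permutation(y))[0, 1]
            count += abs(rp) >= abs(r)
        p_perm = (1 + count) / (1 + n_perm)
        assert abs(p_perm - p) < 4 * np.sqrt(p * (1 - p) / n_perm) + 2 / n_perm

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            q.pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFisherComparison:
    def test_equal_correlations_give_zero(self):
        c = q.fisher_independent_comparison(0.4, 50, 0.4, 60)
        assert c.z == 0 and np.isclose(c.p, 1.0)

    def test_printed_study_comparison(self):
        c = q.fisher_independent_comparison(0.25, 73, -0.19, 68)
        assert round(c.z, 1) == 2.6
        assert round(c.p, 3) == 0.009

    def test_antisymmetry(self):
        a = q.fisher_independent_comparison(0.3, 40, -0.1, 50)
        b = q.fisher_independent_comparison(-0.1, 50, 0.3, 40)
        assert np.isclose(a.z, -b.z) and np.isclose(a.p, b.p)

    def test_z_increases_with_n(self):
        zs = [
            abs(q.fisher_independent_comparison(0.25, n, -0.19, n).z)
            for n in (10, 30, 100, 300)
        ]
        assert np.all(np.diff(zs) > 0)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            q.fisher_independent_comparison(1.0, 50, 0.2, 50)


class TestSteigerComparison:
    def test_equal_correlations_give_zero(self):
        c = q.steiger_dependent_comparison(0.4, 0.4, 0.2, 100)
        assert c.z == 0

    def test_published_worked_example(self):
        # r12=.50 vs r13=.70 sharing variable 1, r23=.80, n=103
        c = q.steiger_dependent_comparison(0.50, 0.70, 0.80, 103)
        assert round(c.z, 3) == -4.109
        # independent re-derivation via the full Pearson-Filon psi evaluated
        # at the back-transformed average correlation
        rbar = np.tanh((np.arctanh(0.50) + np.arctanh(0.70)) / 2)
        psi = 0.80 * (1 - rbar**2 - rbar**2) - 0.5 * rbar * rbar * (
            1 - rbar**2 - rbar**2 - 0.80**2
        )
        c_term = psi / (1 - rbar**2) ** 2
        z_oracle = (np.arctanh(0.50) - np.arctanh(0.70)) * np.sqrt(100) / np.sqrt(
            2 - 2 * c_term
        )
        assert np.isclose(c.z, z_oracle, rtol=1e-12)

    def test_type_i_error_calibration(self):
        rho = np.array([[1, 0.4, 0.4], [0.4, 1, 0.3], [0.4, 0.3, 1]])
        chol = np.linalg.cholesky(rho)
        rejections = 0
        n_rep = 2000
        r = np.random.default_rng(99)
        for _ in range(n_rep):
            z = r.standard_normal((100, 3)) @ chol.T
            c = np.corrcoef(z.T)
            rejections += q.steiger_dependent_comparison(c[0, 1], c[0, 2], c[1, 2], 100).p < 0.05
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_non_pd_triple_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            q.steiger_dependent_comparison(0.9, -0.9, 0.9, 50)


class TestModeration:
    def test_centering_invariance_of_interaction_t(self, rng):
        n = 150
        df = pd.DataFrame(
            {
                "x": rng.normal(10, 2, n),
                "m": rng.normal(-5, 1, n),
            }
        )
        df["y"] = 1 + 0.3 * df.x + 0.2 * df.m + 0.5 * df.x * df.m + rng.normal(size=n)
        fit_c, term = q.moderation_fit(df, "y", "x", "m", max_iter=200, tol=1e-12)
        # uncentered variant: same model space, so the interaction t matches
        df2 = df.copy()
        df2["xm"] = df2.x * df2.m
        design = q.DesignSpec("y", "xm", ["x", "m"])
        fit_u = q.fit_robust_lm(df2, design, max_iter=200, tol=1e-12)
        t_c = fit_c.term(term)["t"]
        t_u = fit_u.term("xm")["t"]
        assert abs(t_c - t_u) < 1e-6

    def test_interaction_recovery(self, rng):
        errs = []
        for s in range(30):
            r = np.random.default_rng(s)
            n = 200
            x, m = r.normal(size=n), r.normal(size=n)
            y = x + m + 0.5 * x * m + r.normal(size=n)
            df = pd.DataFrame({"x": x, "m": m, "y": y})
            fit, term = q.moderation_fit(df, "y", "x", "m")
            errs.append(fit.term(term)["coef"] - 0.5)
        assert abs(np.mean(errs)) < 0.1

    def test_null_interaction_rejection_rate(self):
        rej = 0
        n_rep = 500
        for s in range(n_rep):
            r = np.random.default_rng(10000 + s)
            n = 100
            x, m = r.normal(size=n), r.normal(size=n)
            y = x + m + r.normal(size=n)
            df = pd.DataFrame({"x": x, "m": m, "y": y})
            fit, term = q.moderation_fit(df, "y", "x", "m")
            rej += fit.term(term)["p"] < 0.05
        assert 0.02 <= rej / n_rep <= 0.09


class TestBhFdr:
    def test_uniform_small_p_all_rejected(self):
        reject, _ = bh_fdr([0.01] * 5, q=0.05)
        assert reject.all()

    def test_matches_brute_force_step_up(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        reject, p_adj = bh_fdr(p, q=0.05)
        # brute force: largest k with p_(k) <= q k / m
        order = np.argsort(p)
        m = len(p)
        k_max = max((k + 1 for k in range(m) if p[order[k]] <= 0.05 * (k + 1) / m),
                    default=0)
        expected = np.zeros(m, bool)
        expected[order[:k_max]] = True
        assert np.array_equal(reject, expected)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_never_rejects_p_above_q(self):
        r = np.random.default_rng(5)
        for _ in range(50):
            p = r.random(40)
            reject, _ = bh_fdr(p, q=0.05)
            assert not (reject & (p > 0.05)).any()

    def test_fdr_control_under_null(self):
        r = np.random.default_rng(6)
        fdp = []
        for _ in range(2000)[:2000]:
            p = r.random(100)
            reject, _ = bh_fdr(p, q=0.05)
            fdp.append(reject.any())
        # under the global null FDR = FWER <= q
        assert np.mean(fdp) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


@settings(max_examples=25, deadline=None)
@given(
    r1=st.floats(-0.95, 0.95), r2=st.floats(-0.95, 0.95),
    n1=st.integers(5, 500), n2=st.integers(5, 500),
)
def test_fisher_comparison_properties(r1, r2, n1, n2):
    c = q.fisher_independent_comparison(r1, n1, r2, n2)
    assert 0 <= c.p <= 1
    swapped = q.fisher_independent_comparison(r2, n2, r1, n1)
    assert np.isclose(c.z, -swapped.z)
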
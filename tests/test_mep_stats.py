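import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdcsfield import (
    GenerativeParams,
    MEPDataset,
    association,
    build_design,
    contrast_ftest,
    fit_lme,
    fit_mep_models,
    generate_cohort_mep,
    grubbs_outliers,
    likelihood_ratio_test,
    mean_normalized_mep,
    paired_compare,
    required_sample_size,
    simple_regression,
)
from tdcsfield.mep import grubbs_critical_value, normalized_long


def toy_dataset(base=0.5, post=(0.5, 1.0, 1.0, 0.5)):
    rows = []
    for t, amp in zip(("base", "t0", "t10", "t20", "t30"), (base,) + tuple(post)):
        rows.append({"subject": 0, "session": "real", "time": t, "amplitude_mv": amp})
        rows.append({"subject": 0, "session": "sham", "time": t, "amplitude_mv": amp})
    covs = pd.DataFrame({"e_n": [0.39]}, index=pd.RangeIndex(1, name="subject"))
    return MEPDataset(data=pd.DataFrame(rows), covariates=covs)


class TestNormalization:
    def test_identity_when_no_change(self):
        ds = toy_dataset(0.7, (0.7, 0.7, 0.7, 0.7))
        assert mean_normalized_mep(ds)["mean_norm_mep"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        ds = toy_dataset(0.5, (0.5, 1.0, 1.0, 0.5))
        # mean of (1, 2, 2, 1) = 1.5
        assert mean_normalized_mep(ds)["mean_norm_mep"].iloc[0] == pytest.approx(1.5)

    def test_scaling_post_amplitudes_scales_result(self):
        ds = toy_dataset(0.5, (0.4, 0.6, 0.8, 1.0))
        ds2 = toy_dataset(0.5, (0.8, 1.2, 1.6, 2.0))
        a = mean_normalized_mep(ds)["mean_norm_mep"].iloc[0]
        b = mean_normalized_mep(ds2)["mean_norm_mep"].iloc[0]
        assert b == pytest.approx(2 * a)

    def test_missing_time_point_errors(self):
        ds = toy_dataset()
        ds.data = ds.data[ds.data["time"] != "t20"]
        with pytest.raises(ValueError, match="missing time points"):
            mean_normalized_mep(ds)

    def test_dose_response_law_at_mean_field(self):
        """At E_n = m the fitted law evaluates to its intercept."""
        p = GenerativeParams(subject_intercept_sd=0, noise_cv=0, baseline_slope=0, base_sd_mv=0)
        ds = generate_cohort_mep(p, n_subjects=27, seed=0)
        mn = mean_normalized_mep(ds).merge(ds.covariates, left_on="subject", right_index=True)
        real = mn[mn["session"] == "real"]
        reg = simple_regression(real["e_n"].to_numpy(), real["mean_norm_mep"].to_numpy())
        assert reg.predict(np.array([reg.e_n_mean]))[0] == pytest.approx(1.17, abs=1e-12)


class TestGrubbs:
    def test_small_symmetric_sample_clean(self):
        assert grubbs_outliers(np.array([1.0, 2.0, 3.0])).size == 0

    def test_obvious_outlier_flagged(self):
        x = np.array([1.0, 1.1, 0.9, 1.05, 9.0])
        assert grubbs_outliers(x).tolist() == [4]

    def test_critical_value_against_direct_t_quantile(self):
        for n in (5, 10, 27):
            t = stats.t.ppf(1 - 0.05 / (2 * n), n - 2)
            expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
            assert grubbs_critical_value(n) == pytest.approx(expected, rel=1e-12)

    def test_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        flags = sum(
            grubbs_outliers(rng.normal(size=27), alpha=0.05).size > 0 for _ in range(2000)
        )
        rate = flags / 2000
        assert 0.025 < rate < 0.075  # per-dataset false-positive rate ~ alpha

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            grubbs_outliers(np.ones(5))


def one_way_data(m=8, k=6, tau=0.5, sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, tau, size=m)
    y = (u[:, None] + rng.normal(0, sigma, size=(m, k))).ravel()
    g = np.repeat(np.arange(m), k)
    X = np.ones((m * k, 1))
    return y, X, g


class TestLME:
    def test_zero_between_subject_variance_matches_ols(self):
        rng = np.random.default_rng(1)
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 2.0] + rng.normal(size=n)
        g = np.arange(n)  # one observation per group: no intercept variance
        fit = fit_lme(y, X, g)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        s2 = resid @ resid / n
        ll_ols = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
        assert np.allclose(fit.beta, beta_ols, atol=1e-8)
        assert fit.loglik == pytest.approx(ll_ols, abs=1e-6)

    def test_matches_numeric_ml_oracle_balanced(self):
        """Profiled ML equals direct 2-parameter likelihood maximization."""
        y, X, g = one_way_data()
        fit = fit_lme(y, X, g)

        def negll(params):
            tau2, sig2 = np.exp(params)
            m, k = 8, 6
            ll = 0.0
            for i in range(m):
                yi = y[g == i]
                V = sig2 * np.eye(k) + tau2
                mu = np.full(k, fit.beta[0])
                ll += stats.multivariate_normal.logpdf(yi, mu, V)
            return -ll

        from scipy.optimize import minimize

        res = minimize(negll, [np.log(0.3), np.log(1.0)], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)
        tau2, sig2 = np.exp(res.x)
        assert fit.sigma2_intercept == pytest.approx(tau2, rel=1e-3, abs=1e-6)
        assert fit.sigma2_residual == pytest.approx(sig2, rel=1e-3)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        m, k = 12, 5
        g = np.repeat(np.arange(m), k)
        X = np.column_stack([np.ones(m * k), rng.normal(size=m * k)])
        y = X @ [0.5, -1.0] + rng.normal(0, 0.6, m)[g] + rng.normal(0, 1.0, m * k)
        fit = fit_lme(y, X, g)
        sm_fit = sm.MixedLM(y, X, groups=g).fit(reml=False)
        assert np.allclose(fit.beta, sm_fit.fe_params, atol=1e-5)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-5)

    def test_singular_design_raises(self):
        y, X, g = one_way_data()
        X2 = np.column_stack([X, X])
        with pytest.raises(ValueError, match="singular"):
            fit_lme(y, X2, g)

    def test_session_field_interaction_negative_with_defaults(self):
        neg = 0
        for seed in range(20):
            ds = generate_cohort_mep(GenerativeParams(), n_subjects=27, seed=seed)
            models = fit_mep_models(ds, covariate="e_n")
            beta = dict(zip(models["fit_with_covariate"].term_names,
                            models["fit_with_covariate"].beta))
            neg += beta["e_n:session"] < 0
        assert neg >= 19  # negative in >= 95% of replicates


class TestLRT:
    def test_identical_models_give_zero(self):
        y, X, g = one_way_data()
        fit = fit_lme(y, X, g)
        chi2, df, p = likelihood_ratio_test(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_non_nested_raises(self):
        y, X, g = one_way_data()
        f1 = fit_lme(y, X, g, ["a"])
        f2 = fit_lme(y, X, g, ["b"])
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(f1, f2)

    def test_null_distribution_matches_chi2(self):
        """Under the null the LRT follows chi2_df (KS check, seeded)."""
        rng = np.random.default_rng(11)
        m, k, df_test = 20, 4, 2
        stats_out = []
        for _ in range(400):
            g = np.repeat(np.arange(m), k)
            X0 = np.column_stack([np.ones(m * k), rng.normal(size=m * k)])
            Xe = np.column_stack([X0, rng.normal(size=(m * k, df_test))])
            y = X0 @ [1.0, 0.5] + rng.normal(0, 0.5, m)[g] + rng.normal(size=m * k)
            f0 = fit_lme(y, X0, g, ["i", "x"])
            f1 = fit_lme(y, Xe, g, ["i", "x", "z1", "z2"])
            stats_out.append(likelihood_ratio_test(f0, f1)[0])
        _, p = stats.kstest(stats_out, stats.chi2(df_test).cdf)
        assert p > 0.01

    def test_power_with_planted_field_effect(self):
        """The 8-term field block is detected at the calibrated effect size."""
        sig = 0
        chis = []
        for seed in range(15):
            ds = generate_cohort_mep(GenerativeParams(), n_subjects=27, seed=seed + 500)
            res = fit_mep_models(ds, covariate="e_n")
            chis.append(res["lrt"]["chi2"])
            sig += res["lrt"]["p"] < 0.05
            assert res["lrt"]["df"] == 8
        assert sig >= 12
        assert np.median(chis) > stats.chi2(8).ppf(0.95)


class TestContrastF:
    def test_zero_coefficient_gives_zero_f(self):
        rng = np.random.default_rng(3)
        y, X, g = one_way_data(seed=3)
        X2 = np.column_stack([X, np.zeros((len(y), 0))])
        fit = fit_lme(y, X, g)
        L = np.zeros((1, 1))
        with pytest.raises(ValueError, match="rank-deficient"):
            contrast_ftest(fit, L)

    def test_single_row_equals_squared_t_on_ols_reducible_fit(self):
        rng = np.random.default_rng(9)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.3] + rng.normal(size=n)
        g = np.arange(n)  # no grouping: reduces to OLS
        fit = fit_lme(y, X, g)
        F, df1, df2, p = contrast_ftest(fit, np.array([[0.0, 1.0]]))
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        # ML variance (1/n) vs OLS (1/(n-p)): rescale to compare the shape
        t2 = float(ols.tvalues[1] ** 2)
        # the ML covariance uses RSS/n, the OLS t uses RSS/(n-2)
        assert F * ((n - 2) / n) == pytest.approx(t2, rel=1e-6)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(21)
        m, k = 40, 4
        hits = 0
        reps = 800
        for _ in range(reps):
            g = np.repeat(np.arange(m), k)
            X = np.column_stack([np.ones(m * k), rng.normal(size=(m * k, 2))])
            y = 1.0 + rng.normal(0, 0.5, m)[g] + rng.normal(size=m * k)
            fit = fit_lme(y, X, g)
            L = np.zeros((2, 3))
            L[0, 1] = 1.0
            L[1, 2] = 1.0
            hits += contrast_ftest(fit, L)[3] < 0.05
        rate = hits / reps
        band = 2.58 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < band + 0.01


class TestAssociation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = association(x, x)
        assert r == pytest.approx(1.0)

    def test_partial_self_control_annihilates(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        y = x + z
        r, _ = association(x, y, controls=x, method="partial")
        assert abs(r) < 1e-10

    def test_partial_matches_closed_form(self, rng):
        x, y, z = rng.normal(size=(3, 200))
        y = y + 0.5 * x + 0.8 * z
        x = x + 0.3 * z
        r_part, _ = association(x, y, controls=z, method="partial")
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r_part == pytest.approx(closed, abs=1e-10)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            association(np.ones(5), np.arange(5.0))


class TestPairedCompare:
    def test_equal_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_compare(a, a.copy() + 0.0)
        assert res["t"] == 0.0 and res["t_p"] == 1.0
        assert "wilcoxon_error" in res

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 27))
        assert paired_compare(a, b)["df"] == 26

    def test_exact_wilcoxon_equals_enumeration_n8(self):
        """Exact p equals brute-force enumeration over all 2^8 sign patterns."""
        rng = np.random.default_rng(5)
        d = rng.normal(size=8)
        while len(np.unique(np.abs(d))) < 8 or np.any(d == 0):
            d = rng.normal(size=8)
        res = paired_compare(d + 1.0, np.ones(8))
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        ws = []
        for mask in range(2**8):
            w = sum(ranks[i] for i in range(8) if mask >> i & 1)
            ws.append(w)
        ws = np.array(ws)
        p_exact = np.mean(np.minimum(ws, total - ws) <= min(w_obs, total - w_obs))
        assert res["wilcoxon_p"] == pytest.approx(p_exact, abs=1e-12)

    def test_all_zero_differences_flagged(self):
        res = paired_compare(np.ones(6), np.ones(6))
        assert res["wilcoxon_error"] == "all differences are zero"

    def test_type_one_error_both_tests(self):
        rng = np.random.default_rng(8)
        n, reps = 30, 2000
        t_hits = w_hits = 0
        for _ in range(reps):
            a, b = rng.normal(size=(2, n))
            res = paired_compare(a, b)
            t_hits += res["t_p"] < 0.05
            w_hits += res["wilcoxon_p"] < 0.05
        band = 2.58 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(t_hits / reps - 0.05) < band
        assert abs(w_hits / reps - 0.05) < band


class TestSimpleRegression:
    def test_noiseless_recovery_of_generating_law(self):
        rng = np.random.default_rng(2)
        e_n = rng.uniform(0.2, 0.6, size=27)
        m = e_n.mean()
        y = 1.17 - 0.72 * (e_n - m) / m
        reg = simple_regression(e_n, y)
        assert reg.intercept == pytest.approx(1.17, abs=1e-12)
        assert reg.slope == pytest.approx(-0.72, abs=1e-12)
        assert reg.e_n_mean == pytest.approx(m)

    def test_intercept_is_mean_response(self):
        rng = np.random.default_rng(3)
        e_n = rng.uniform(0.2, 0.6, size=30)
        y = rng.normal(size=30)
        reg = simple_regression(e_n, y)
        # x is mean-centred by construction, so the intercept is mean(y)
        assert reg.intercept == pytest.approx(y.mean(), abs=1e-10)

    def test_ci_coverage_under_generator_noise(self):
        """t-based 95% CI covers the true slope ~95% of the time at n=27."""
        params = GenerativeParams(noise_law="gaussian")
        from tdcsfield import recovery_experiment

        rec = recovery_experiment(params, replicates=400, seed=31, fit_mixed=False)
        assert 0.92 <= rec["ci_coverage"] <= 0.98

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            simple_regression(np.full(5, 0.4), np.arange(5.0))


class TestSampleSize:
    def test_reference_value(self):
        assert required_sample_size(0.35, power=0.80, alpha=0.05) == 20

    def test_limit_high_r2(self):
        assert required_sample_size(0.9999) == 4

    def test_power_090_matches_numeric_inversion(self):
        """Fisher-z closed form equals numeric inversion of the power curve."""
        r = np.sqrt(0.35)
        za = stats.norm.ppf(0.975)

        def power(n):
            if n <= 3:
                return 0.0
            delta = np.arctanh(r) * np.sqrt(n - 3)
            return stats.norm.sf(za - delta) + stats.norm.cdf(-za - delta)

        n = 4
        while power(n) < 0.90:
            n += 1
        assert required_sample_size(0.35, power=0.90) == n

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            required_sample_size(1.2)
        with pytest.raises(ValueError):
            required_sample_size(0.35, power=1.2)


def test_build_design_has_expected_terms():
    ds = generate_cohort_mep(GenerativeParams(), n_subjects=6, seed=0)
    frame = normalized_long(ds).merge(
        ds.covariates["e_n"], left_on="subject", right_index=True
    )
    X, names = build_design(frame, covariate="e_n")
    base = [n for n in names if not n.startswith("e_n")]
    ef = [n for n in names if n.startswith("e_n")]
    assert len(ef) == 8  # main, 3x time, session, 3x time:session
    assert X.shape == (len(frame), len(names))
    assert np.linalg.matrix_rank(X) == X.shape[1]
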
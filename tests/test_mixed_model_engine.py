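import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dyadpred import (Design, FitResult, ModelSpec, aic, build_design,
                      fit_lmm, icc, marginal_r2, predict,
                      residual_diagnostics)
from dyadpred.mixed_model_engine import RankDeficiencyError, loglik_at
from dyadpred.terms import ModelTerm as T


def grouped_frame(n_groups=20, group_size=4, beta=(0.5, -0.3), tau00=0.25,
                  sigma2=0.5, seed=0):
    rng = np.random.default_rng(seed)
    n = n_groups * group_size
    g = np.repeat([f"T{j:03d}" for j in range(n_groups)], group_size)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    u = rng.normal(0, np.sqrt(tau00), n_groups)
    y = (beta[0] * x1 + beta[1] * x2 + np.repeat(u, group_size)
         + rng.normal(0, np.sqrt(sigma2), n))
    return pd.DataFrame({"therapist_id": g, "x1": x1, "x2": x2, "y": y})


SPEC2 = ModelSpec("y", (T.linear("x1"), T.linear("x2")))


class TestBuildDesign:
    def test_linear_identity(self):
        df = pd.DataFrame({"x": [-1.0, 0.0, 1.0], "y": [0.0, 0.0, 0.0],
                           "therapist_id": ["a", "b", "c"]})
        d = build_design(df, ModelSpec("y", (T.linear("x"),)))
        np.testing.assert_allclose(d.X[:, 1], [-1, 0, 1])

    def test_quadratic_squares(self):
        df = pd.DataFrame({"x": [-1.0, 0.0, 1.0], "y": [0.0] * 3,
                           "therapist_id": list("abc")})
        d = build_design(df, ModelSpec("y", (T.quadratic("x"),)))
        np.testing.assert_allclose(d.X[:, 1], [1, 0, 1])

    def test_interaction_products(self):
        df = pd.DataFrame({"g": [-0.5, 0.5], "x": [2.0, 2.0], "y": [0.0] * 2,
                           "therapist_id": list("ab")})
        d = build_design(df, ModelSpec("y", (T.interaction("g", "x"),)))
        np.testing.assert_allclose(d.X[:, 1], [-1, 1])

    def test_missing_cells_rejected(self):
        df = grouped_frame()
        df.loc[0, "x1"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            build_design(df, SPEC2)

    def test_column_order_canonical(self):
        df = grouped_frame()
        spec = ModelSpec("y", (T.interaction("x1", "x2"), T.quadratic("x1"),
                               T.linear("x2"), T.linear("x1")))
        d = build_design(df, spec)
        assert d.columns == ("(Intercept)", "x1", "x2", "x1^2", "x1:x2")


class TestFitLmm:
    def test_singleton_groups_reduce_to_ols(self):
        # one client per therapist: the mixed model IS OLS for any lambda
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 40
            df = pd.DataFrame({
                "therapist_id": [f"T{i}" for i in range(n)],
                "x1": rng.standard_normal(n),
                "x2": rng.standard_normal(n)})
            df["y"] = 0.5 * df.x1 - 0.3 * df.x2 + rng.standard_normal(n)
            fit = fit_lmm(build_design(df, SPEC2))
            X = np.column_stack([np.ones(n), df.x1, df.x2])
            beta_ols = np.linalg.lstsq(X, df.y.to_numpy(), rcond=None)[0]
            np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-4)
            assert fit.tau00 == 0.0

    def test_balanced_anova_closed_form(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            J, m = 15, 4
            y = (rng.normal(0, 0.8, J)[:, None]
                 + rng.normal(0, 0.6, (J, m)))
            df = pd.DataFrame({
                "therapist_id": np.repeat([f"T{j}" for j in range(J)], m),
                "y": y.ravel()})
            fit = fit_lmm(build_design(df, ModelSpec("y")))
            W = float(((y - y.mean(1, keepdims=True)) ** 2).sum())
            B = m * float(((y.mean(1) - y.mean()) ** 2).sum())
            s2 = W / (J * m - J)
            tau = max(B / (J * m) - s2 / m, 0.0)
            assert fit.sigma2 == pytest.approx(s2, abs=1e-4)
            assert fit.tau00 == pytest.approx(tau, abs=1e-4)

    def test_loglik_matches_direct_mvn(self):
        # n <= 12: engine loglik vs direct multivariate-normal density
        for seed in range(10):
            df = grouped_frame(n_groups=4, group_size=3, seed=seed)
            design = build_design(df, SPEC2)
            fit = fit_lmm(design)
            Z = np.equal.outer(design.groups, np.arange(design.n_groups))
            cov = fit.sigma2 * np.eye(12) + fit.tau00 * (Z @ Z.T)
            direct = stats.multivariate_normal.logpdf(
                design.y, mean=design.X @ fit.beta, cov=cov)
            assert fit.loglik == pytest.approx(direct, abs=1e-8)
            # and the reusable evaluator agrees
            assert loglik_at(design, fit.beta, fit.tau00, fit.sigma2) == \
                pytest.approx(direct, abs=1e-8)

    def test_fixed_parameter_loglik_grid(self):
        df = grouped_frame(n_groups=4, group_size=3, seed=3)
        design = build_design(df, SPEC2)
        Z = np.equal.outer(design.groups, np.arange(design.n_groups))
        beta = np.array([0.1, 0.4, -0.2])
        for tau00, sigma2 in ((0.3, 0.7), (1e-8, 1.0), (2.0, 0.2)):
            cov = sigma2 * np.eye(12) + tau00 * (Z @ Z.T)
            direct = stats.multivariate_normal.logpdf(
                design.y, mean=design.X @ beta, cov=cov)
            assert loglik_at(design, beta, tau00, sigma2) == \
                pytest.approx(direct, abs=1e-8)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf
        df = grouped_frame(n_groups=30, group_size=4, tau00=1.0, seed=0)
        fit = fit_lmm(build_design(df, SPEC2))
        sm_fit = smf.mixedlm("y ~ x1 + x2", df, groups=df["therapist_id"]) \
            .fit(reml=False, method="lbfgs")
        np.testing.assert_allclose(fit.beta, sm_fit.fe_params.to_numpy(),
                                   atol=1e-4)
        assert fit.sigma2 == pytest.approx(sm_fit.scale, rel=1e-3)
        tau_sm = float(sm_fit.cov_re.iloc[0, 0])
        assert fit.tau00 == pytest.approx(tau_sm, abs=2e-3)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-5)

    def test_permutation_invariance(self):
        df = grouped_frame(seed=9)
        fit1 = fit_lmm(build_design(df, SPEC2))
        perm = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = fit_lmm(build_design(perm, SPEC2))
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-8)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)
        assert fit1.tau00 == pytest.approx(fit2.tau00, abs=1e-8)

    def test_rank_deficiency_names_column(self):
        df = grouped_frame()
        df["x2"] = 2.0 * df["x1"]
        with pytest.raises(RankDeficiencyError, match="x2"):
            fit_lmm(build_design(df, SPEC2))

    def test_nesting_deviance_monotone(self):
        df = grouped_frame(seed=13)
        small = fit_lmm(build_design(df, ModelSpec("y", (T.linear("x1"),))))
        big = fit_lmm(build_design(df, SPEC2))
        assert -2 * small.loglik >= -2 * big.loglik - 1e-6

    def test_noise_column_aic_change_bounded(self):
        rng = np.random.default_rng(99)
        df = grouped_frame(seed=21)
        df["junk"] = rng.standard_normal(len(df))
        base = fit_lmm(build_design(df, SPEC2))
        bigger = fit_lmm(build_design(
            df, ModelSpec("y", SPEC2.terms + (T.linear("junk"),))))
        assert bigger.aic <= base.aic + 2.0 + 1e-6

    def test_ci_brackets_estimate(self):
        fit = fit_lmm(build_design(grouped_frame(seed=2), SPEC2))
        assert (fit.ci_low < fit.beta).all() and (fit.beta < fit.ci_high).all()
        assert fit.df == fit.n_obs - 3 - 1


class TestAic:
    def test_direct_formula(self):
        fit = FitResult(loglik=-10.0, columns=("(Intercept)", "x"))
        assert aic(fit) == pytest.approx(28.0)

    def test_reml_rejected(self):
        fit = FitResult(loglik=-10.0, columns=("(Intercept)",),
                        estimation="REML")
        with pytest.raises(ValueError, match="ML"):
            aic(fit)

    def test_gaussian_closed_form_interceptonly(self):
        # singleton groups, tau00 -> 0: loglik = Gaussian ML closed form
        rng = np.random.default_rng(3)
        n = 100
        y = rng.standard_normal(n)
        df = pd.DataFrame({"y": y,
                           "therapist_id": [f"T{i}" for i in range(n)]})
        fit = fit_lmm(build_design(df, ModelSpec("y")))
        s2 = np.mean((y - y.mean()) ** 2)
        expected = -n / 2 * (np.log(2 * np.pi * s2) + 1)
        assert fit.loglik == pytest.approx(expected, abs=1e-8)


class TestMarginalR2:
    def test_intercept_only_zero(self):
        fit = fit_lmm(build_design(grouped_frame(seed=4), ModelSpec("y")))
        assert fit.r2_marginal == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula(self):
        fit = FitResult(sigma2=0.2, tau00=0.2, var_fixed=0.6)
        assert marginal_r2(fit) == pytest.approx(0.6)

    def test_limit_to_one(self):
        df = grouped_frame(tau00=0.0, sigma2=1e-12, seed=6)
        fit = fit_lmm(build_design(df, SPEC2))
        assert fit.r2_marginal > 0.999

    def test_algebraic_identity(self):
        df = grouped_frame(seed=8)
        design = build_design(df, SPEC2)
        fit = fit_lmm(design)
        var_f = np.var(design.X @ fit.beta)
        assert fit.r2_marginal == pytest.approx(
            var_f / (var_f + fit.tau00 + fit.sigma2), abs=1e-12)
        assert marginal_r2(fit, design) == pytest.approx(fit.r2_marginal)


class TestIcc:
    def test_model1_components(self):
        assert round(icc(FitResult(sigma2=0.35, tau00=0.07)), 2) == 0.17

    def test_model3_components(self):
        assert round(icc(FitResult(sigma2=0.29, tau00=0.17)), 2) == 0.37

    def test_zero_tau(self):
        assert icc(FitResult(sigma2=0.5, tau00=0.0)) == 0.0

    def test_identity_from_fit(self):
        fit = fit_lmm(build_design(grouped_frame(seed=10), SPEC2))
        assert fit.icc == pytest.approx(fit.tau00 / (fit.tau00 + fit.sigma2))


class TestPredict:
    def test_zero_row_returns_intercept(self):
        df = grouped_frame(seed=11)
        fit = fit_lmm(build_design(df, SPEC2))
        row = pd.DataFrame({"x1": [0.0], "x2": [0.0]})
        assert predict(fit, row)[0] == pytest.approx(fit.beta[0])

    def test_modes_identical_when_tau_zero(self):
        rng = np.random.default_rng(12)
        n = 40
        df = pd.DataFrame({"therapist_id": [f"T{i}" for i in range(n)],
                           "x1": rng.standard_normal(n),
                           "x2": rng.standard_normal(n)})
        df["y"] = 0.5 * df.x1 + rng.standard_normal(n)
        fit = fit_lmm(build_design(df, SPEC2))
        assert fit.tau00 == 0.0
        np.testing.assert_allclose(
            predict(fit, df, "fixed_only"),
            predict(fit, df, "with_group_effects"), atol=1e-12)

    def test_known_vs_unknown_therapist_blup(self):
        df = grouped_frame(seed=13, tau00=1.0)
        design = build_design(df, SPEC2)
        fit = fit_lmm(design)
        row = df.iloc[[0]].copy()
        known = predict(fit, row, "with_group_effects")[0]
        row_unknown = row.assign(therapist_id="T_NEW")
        unknown = predict(fit, row_unknown, "with_group_effects")[0]
        tid = df["therapist_id"].iloc[0]
        assert known - unknown == pytest.approx(fit.group_effects[tid])
        # BLUP closed form: u_g = tau*n_g*mean_resid / (sigma2 + tau*n_g)
        mask = df["therapist_id"] == tid
        resid = (df.loc[mask, "y"].to_numpy()
                 - predict(fit, df.loc[mask], "fixed_only"))
        n_g = mask.sum()
        u_direct = fit.tau00 * resid.sum() / (fit.sigma2 + fit.tau00 * n_g)
        assert fit.group_effects[tid] == pytest.approx(u_direct, abs=1e-10)

    def test_unknown_mode_rejected(self):
        fit = fit_lmm(build_design(grouped_frame(), SPEC2))
        with pytest.raises(ValueError, match="mode"):
            predict(fit, grouped_frame(), "oracle")


class TestDiagnostics:
    def test_constant_residuals_rejected(self):
        df = grouped_frame(seed=14)
        design = build_design(df, SPEC2)
        fit = fit_lmm(design)
        design2 = Design(y=design.X @ fit.beta, X=design.X,
                         groups=design.groups,
                         group_labels=design.group_labels,
                         columns=design.columns, spec=design.spec)
        fit2 = fit_lmm(design2)
        with pytest.raises(ValueError, match="constant|zero"):
            residual_diagnostics(fit2, design2)

    def test_small_n_refused(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({"therapist_id": list("aabbcc"),
                           "x1": rng.standard_normal(6),
                           "x2": rng.standard_normal(6)})
        df["y"] = rng.standard_normal(6)
        design = build_design(df, ModelSpec("y"))
        fit = fit_lmm(design)
        with pytest.raises(ValueError, match="at least 8"):
            residual_diagnostics(fit, design)

    def test_clean_residuals_pass(self):
        df = grouped_frame(n_groups=50, seed=16)
        design = build_design(df, SPEC2)
        fit = fit_lmm(design)
        rep = residual_diagnostics(fit, design)
        assert rep.normality_ok and rep.homoscedasticity_ok
        assert 0.0 <= rep.normality_p <= 1.0

    def test_detects_heteroscedasticity(self):
        rng = np.random.default_rng(17)
        n = 200
        df = pd.DataFrame({"therapist_id": np.repeat(
            [f"T{i}" for i in range(100)], 2),
            "x1": rng.standard_normal(n), "x2": rng.standard_normal(n)})
        mu = 3.0 + 2.0 * df.x1
        df["y"] = mu + rng.standard_normal(n) * 0.5 * np.abs(mu)
        design = build_design(df, SPEC2)
        fit = fit_lmm(design)
        rep = residual_diagnostics(fit, design)
        assert not rep.homoscedasticity_ok


class TestBetaRecovery:
    def test_bias_and_coverage(self):
        # duplicated (lighter) version of acceptance criterion 3
        hits = np.zeros(2)
        errs = []
        reps = 30
        for rep in range(reps):
            df = grouped_frame(n_groups=100, group_size=2, seed=1000 + rep)
            fit = fit_lmm(build_design(df, SPEC2))
            errs.append(fit.beta[1:] - np.array([0.5, -0.3]))
            hits += ((fit.ci_low[1:] <= [0.5, -0.3])
                     & ([0.5, -0.3] <= fit.ci_high[1:]))
        assert np.all(np.abs(np.mean(errs, axis=0)) < 0.05)
        assert (hits / reps).min() > 0.85
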
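"""OLS and quantile-regression machinery against independent oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

import fundusmorph as fm


def lad_oracle(X, y):
    """Least-absolute-deviations fit as a linear program (HiGHS)."""
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.ones(2 * n)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    assert res.success
    return res.x[:p]


class TestQuantileGrid:
    def test_default_grid_shape(self):
        taus = fm.quantile_grid()
        assert len(taus) == 34
        assert taus[0] == pytest.approx(0.005)
        assert taus[-1] == pytest.approx(0.995)
        assert np.allclose(np.diff(taus), 0.03, atol=1e-12)

    def test_configurable(self):
        taus = fm.quantile_grid(n=5, lo=0.1, hi=0.9)
        assert len(taus) == 5 and taus[0] == 0.1 and taus[-1] == 0.9

    def test_invalid_endpoints_raise(self):
        with pytest.raises(ValueError):
            fm.quantile_grid(lo=0.0)


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame({"a": rng.uniform(10, 30, 500), "b": rng.normal(-4, 9, 500)})
        out, _ = fm.standardize(df, ["a", "b"])
        assert abs(out["a"].mean()) < 1e-10 and abs(out["b"].mean()) < 1e-10
        assert out["a"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_idempotent_and_affine_invariant(self, rng):
        df = pd.DataFrame({"a": rng.normal(0, 1, 300)})
        once, _ = fm.standardize(df, ["a"])
        twice, _ = fm.standardize(once, ["a"])
        assert np.allclose(once["a"], twice["a"], atol=1e-10)
        affine, _ = fm.standardize(pd.DataFrame({"a": 3.5 * df["a"] - 7.0}), ["a"])
        assert np.allclose(affine["a"], once["a"], atol=1e-10)

    def test_inverse_round_trip(self, rng):
        df = pd.DataFrame({"a": rng.uniform(5, 9, 100)})
        out, scaler = fm.standardize(df, ["a"])
        back = scaler.inverse(out)
        assert np.allclose(back["a"], df["a"])

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fm.standardize(pd.DataFrame({"a": np.ones(50)}), ["a"])


class TestVIF:
    def test_orthogonal_predictors_are_unity(self):
        # Hadamard-style +/-1 columns: zero-mean and mutually orthogonal
        idx = np.arange(256)
        X = np.column_stack([(-1.0) ** ((idx >> b) & 1) for b in range(4)])
        df = pd.DataFrame(X, columns=list("abcd"))
        assert np.allclose(fm.vif(df), 1.0, atol=1e-8)

    def test_near_collinear_flagged(self, rng):
        x = rng.normal(size=500)
        df = pd.DataFrame({"x1": x, "x2": x + rng.normal(0, 1e-4, 500), "x3": rng.normal(size=500)})
        v = fm.vif(df)
        assert v["x1"] > 10 and v["x2"] > 10 and v["x3"] < 2

    def test_perfect_collinearity_gives_inf_not_crash(self, rng):
        x = rng.normal(size=100)
        v = fm.vif(pd.DataFrame({"x1": x, "x2": 2 * x}))
        assert np.isinf(v["x1"]) and np.isinf(v["x2"])

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        X = rng.normal(size=(1000, 5))
        X[:, 1] += 0.6 * X[:, 0]
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(5)])
        ours = fm.vif(df)
        Xc = np.column_stack([X, np.ones(len(X))])
        for j in range(5):
            assert ours.iloc[j] == pytest.approx(variance_inflation_factor(Xc, j), abs=1e-8)


def _linear_cohort(n, seed, betas, noise_sd):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({name: rng.normal(size=n) for name in betas})
    df["ser"] = sum(b * df[k] for k, b in betas.items()) + rng.normal(0, noise_sd, n)
    return df


class TestOLS:
    BETAS = {"f1": 0.6, "f2": -0.3, "age": -0.1, "sex": 0.0, "cr": 0.2}

    def test_noise_free_data_recovered_exactly(self):
        df = _linear_cohort(500, 0, self.BETAS, 0.0)
        model = fm.SEROLSModel.from_dataframe(df, ["f1", "f2"])
        res = model.fit()
        for c in res.coefficients:
            want = self.BETAS.get(c.term, 0.0)
            assert c.beta_std == pytest.approx(want, abs=1e-8)
        assert np.allclose(res.sm_results.resid, 0.0, atol=1e-8)

    def test_row_permutation_invariance(self):
        df = _linear_cohort(400, 1, self.BETAS, 1.0)
        r1 = fm.SEROLSModel.from_dataframe(df, ["f1", "f2"]).fit()
        r2 = fm.SEROLSModel.from_dataframe(df.sample(frac=1, random_state=9), ["f1", "f2"]).fit()
        assert np.allclose(r1.params, r2.params, atol=1e-10)

    def test_group_split_on_myopia_cutoff(self):
        df = _linear_cohort(600, 2, self.BETAS, 1.0)
        myo = fm.SEROLSModel.from_dataframe(df, ["f1", "f2"], group="myope")
        non = fm.SEROLSModel.from_dataframe(df, ["f1", "f2"], group="nonmyope")
        assert len(myo.endog) + len(non.endog) == len(df)
        assert myo.endog.max() <= -0.5 and non.endog.min() > -0.5

    def test_ci_coverage_under_gaussian_noise(self):
        hits = total = 0
        for rep in range(60):
            df = _linear_cohort(2000, 100 + rep, self.BETAS, 1.0)
            res = fm.SEROLSModel.from_dataframe(df, ["f1", "f2"]).fit()
            for c in res.coefficients:
                if c.term == "intercept":
                    continue
                want = self.BETAS.get(c.term, 0.0)
                hits += c.ci_low <= want <= c.ci_high
                total += 1
        assert hits / total >= 0.90

    def test_singular_design_names_aliased_columns(self):
        df = _linear_cohort(200, 3, self.BETAS, 1.0)
        df["f2"] = 2.0 * df["f1"]
        with pytest.raises(ValueError, match="aliased"):
            fm.SEROLSModel.from_dataframe(df, ["f1", "f2"])

    def test_diagnostics_shapes(self):
        df = _linear_cohort(300, 4, self.BETAS, 1.0)
        res = fm.SEROLSModel.from_dataframe(df, ["f1", "f2"]).fit()
        theo, sample = res.qq_points()
        fitted, resid = res.resid_fitted()
        assert len(theo) == len(sample) == len(fitted) == len(resid) == 300
        assert np.all(np.diff(sample) >= 0)  # sorted residual quantiles
        v = res.vif()
        assert set(v.index) == {"f1", "f2", "age", "sex", "cr"}


class TestQuantileRegression:
    def test_median_fit_matches_lad_oracle(self):
        df, _ = fm.simulate_cohort(fm.CohortEffectSpec(
            n=300, seed=5, feature_effects={"f": (0.5, 0.1)}, covariate_effects={}))
        model = fm.SERQuantileModel.from_dataframe(df, ["f"], covariates=())
        fit = model.fit(taus=[0.5]).fits[0]
        X = np.column_stack([np.ones(len(df)), df["f"]])
        b = lad_oracle(X, df["ser"].to_numpy())
        assert fit.intercept == pytest.approx(b[0], abs=1e-6)
        assert fit.coefficients[0].beta_std == pytest.approx(b[1], abs=1e-6)

    def test_check_loss_not_worse_than_truth(self):
        spec = fm.CohortEffectSpec(n=2000, seed=6, feature_effects={"f": (0.5, 0.1)},
                                   covariate_effects={})
        df, truth = fm.simulate_cohort(spec)
        model = fm.SERQuantileModel.from_dataframe(df, ["f"], covariates=())
        y = df["ser"].to_numpy()
        x = df["f"].to_numpy()
        for f in model.fit(taus=[0.25, 0.75]).fits:
            def loss(b0, b1, tau=f.tau):
                r = y - b0 - b1 * x
                return np.sum(r * (tau - (r < 0)))
            fitted = loss(f.intercept, f.coefficients[0].beta_std)
            from scipy.special import ndtri
            true_b0 = truth.intercept + truth.sigma * ndtri(f.tau)
            true_b1 = truth.slope("f", f.tau)
            assert fitted <= loss(true_b0, true_b1) + 1e-9

    def test_flat_curves_under_homoscedastic_null(self):
        spec = fm.CohortEffectSpec(n=5000, seed=7,
                                   feature_effects={"f": (0.5, 0.0)},
                                   covariate_effects={"age": (-0.1, 0.0)})
        df, _ = fm.simulate_cohort(spec)
        res = fm.SERQuantileModel.from_dataframe(df, ["f"], covariates=("age",)).fit()
        sub = res.frame().query("term == 'f'")
        halfwidth = ((sub["ci_high"] - sub["ci_low"]) / 2).median()
        assert (sub["beta_std"] - sub["beta_std"].mean()).abs().max() < 3 * halfwidth

    def test_sparse_tail_quantiles_are_refused_not_fitted(self):
        df, _ = fm.simulate_cohort(fm.CohortEffectSpec(n=300, seed=8))
        res = fm.SERQuantileModel.from_dataframe(
            df, ["vessel_fd", "od_fovea_angle"]).fit(taus=[0.005, 0.5])
        assert 0.005 in res.errors and "refusing" in res.errors[0.005]
        assert [f.tau for f in res.fits] == [0.5]

    def test_tau_outside_unit_interval_raises(self):
        df, _ = fm.simulate_cohort(fm.CohortEffectSpec(n=200, seed=9))
        model = fm.SERQuantileModel.from_dataframe(df, ["vessel_fd", "od_fovea_angle"])
        with pytest.raises(ValueError):
            model.fit(taus=[1.5])

    def test_bootstrap_ci_contains_point_estimate(self):
        df, _ = fm.simulate_cohort(fm.CohortEffectSpec(
            n=400, seed=10, feature_effects={"f": (0.5, 0.1)}, covariate_effects={}))
        model = fm.SERQuantileModel.from_dataframe(df, ["f"], covariates=())
        res = model.fit(taus=[0.5], ci="bootstrap", n_boot=50, seed=0)
        c = res.fits[0].coefficients[0]
        assert c.ci_low <= c.beta_std <= c.ci_high
        assert c.ci_high - c.ci_low > 0


class TestReporting:
    @staticmethod
    def _results(betas=(0.8, 0.2), n=3000, seed=11):
        spec = fm.CohortEffectSpec(
            n=n, seed=seed,
            feature_effects={"f_big": (betas[0], 0.0), "f_small": (betas[1], 0.0)},
            covariate_effects={})
        df, _ = fm.simulate_cohort(spec)
        return fm.fit_quantile_curve(df, taus=fm.quantile_grid(n=9, lo=0.1, hi=0.9),
                                     features=["f_big", "f_small"], covariates=())

    def test_ranking_matches_construction_at_every_tau(self):
        res = self._results()
        ranking = res.ranking_table(["f_big", "f_small"])
        top = ranking[ranking["rank"] == 1]
        assert (top["term"] == "f_big").all()

    def test_report_emits_tables_and_figure(self, tmp_path):
        res = self._results()
        curves, ranking, fig = fm.coefficient_curve_report(res, outdir=tmp_path)
        assert {"tau", "term", "beta_std", "ci_low", "ci_high", "p_value"} <= set(curves.columns)
        assert (tmp_path / "coefficient_curves.csv").exists()
        assert (tmp_path / "coefficient_curves.png").exists()
        assert len(fig.axes) >= 2

    def test_single_fit_cannot_build_curves(self):
        df, _ = fm.simulate_cohort(fm.CohortEffectSpec(n=500, seed=12))
        res = fm.SERQuantileModel.from_dataframe(
            df, ["vessel_fd", "od_fovea_angle"]).fit(taus=[0.5])
        with pytest.raises(ValueError, match="2 quantiles"):
            fm.coefficient_curve_report(res)

    def test_no_significant_points_is_fine(self):
        spec = fm.CohortEffectSpec(n=200, seed=13, sigma=30.0,
                                   feature_effects={"f": (0.01, 0.0)}, covariate_effects={})
        df, _ = fm.simulate_cohort(spec)
        res = fm.SERQuantileModel.from_dataframe(df, ["f"], covariates=()).fit(
            taus=[0.3, 0.5, 0.7])
        fig = res.plot_coefficient_curves()
        assert fig is not None

    def test_summary_mentions_terms(self):
        res = self._results()
        text = res.summary()
        assert "f_big" in text and "quantiles" in text

    def test_intercept_curve_monotone_in_tau(self):
        res = self._results()
        ic = res.intercept_curve()
        assert (np.diff(ic["predicted_ser"]) > 0).mean() >= 0.8
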
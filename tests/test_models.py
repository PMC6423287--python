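"""Statistical suite: harmonic terms, fits, posterior CIs, ICC, compensation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lapwing import models, synthetic
from lapwing.io import FEMALE, MALE
from lapwing.models import (
    FitResult,
    ModelSpec,
    compensation,
    fit_model,
    harmonic_design,
    posterior_ci,
    repeatability,
    sample_one_sex_per_hour,
    z_transform,
)


class TestHarmonicDesign:
    def test_quarter_and_half_period_values(self):
        h = harmonic_design([6.0])
        assert h.loc[0, "rad24"] == pytest.approx(np.pi / 2)
        assert h.loc[0, "sin24"] == pytest.approx(1.0)
        assert h.loc[0, "cos24"] == pytest.approx(0.0, abs=1e-12)
        assert h.loc[0, "rad12"] == pytest.approx(np.pi)
        assert h.loc[0, "sin12"] == pytest.approx(0.0, abs=1e-12)
        assert h.loc[0, "cos12"] == pytest.approx(-1.0)

    def test_periodicity_at_wraparound(self):
        a = harmonic_design([0.0]).iloc[0]
        b = harmonic_design([24.0 - 1e-10]).iloc[0]
        assert abs(a["sin24"] - b["sin24"]) < 1e-9
        assert abs(a["cos24"] - b["cos24"]) < 1e-9

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            harmonic_design([24.0])

    @given(st.floats(min_value=0.0, max_value=23.999))
    @settings(max_examples=50, deadline=None)
    def test_unit_circle_invariant(self, t):
        h = harmonic_design([t]).iloc[0]
        for p in (12, 24):
            assert h[f"sin{p}"] ** 2 + h[f"cos{p}"] ** 2 == pytest.approx(1.0)


class TestZTransform:
    def test_small_example(self):
        assert z_transform([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_idempotent(self):
        x = z_transform(np.random.default_rng(0).normal(5, 3, 100))
        assert np.allclose(z_transform(x), x, atol=1e-12)

    def test_large_sample_moments(self):
        x = z_transform(np.random.default_rng(1).normal(2, 7, 10_000))
        assert abs(x.mean()) < 0.02
        assert abs(x.std(ddof=1) - 1) < 0.02

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            z_transform([2.0, 2.0, 2.0])


class TestFitModel:
    def test_noiseless_ols_is_exact(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2.0 + 3.0 * x})
        fit = fit_model(ModelSpec("m", "y ~ x"), df)
        assert fit.as_series()["Intercept"] == pytest.approx(2.0, abs=1e-10)
        assert fit.as_series()["x"] == pytest.approx(3.0, abs=1e-10)
        assert fit.method == "ols"

    def test_weighted_fit_matches_hand_computed_wls(self):
        # 5-row WLS with weights sqrt(t): beta = (X'WX)^-1 X'Wy
        df = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0, 3.0, 4.0], "y": [1.0, 2.2, 2.9, 4.3, 4.9],
             "t": [1.0, 4.0, 9.0, 16.0, 25.0]}
        )
        fit = fit_model(ModelSpec("m", "y ~ x", weights="t"), df)
        X = np.column_stack([np.ones(5), df["x"]])
        W = np.diag(np.sqrt(df["t"]))
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ df["y"])
        assert np.allclose(fit.estimates, beta, atol=1e-10)

    def test_random_intercept_variance_recovery(self):
        rng = np.random.default_rng(4)
        groups = np.repeat(np.arange(60), 5)
        y = rng.normal(0, 1, 60)[groups] + rng.normal(0, 1, 300)
        df = pd.DataFrame({"y": y, "g": groups})
        fit = fit_model(ModelSpec("m", "y ~ 1", groups="g", re_formula="1"), df)
        assert fit.method == "mixed-reml"
        vb = float(np.asarray(fit.variance_components["group_cov"]).ravel()[0])
        ve = fit.variance_components["resid"]
        assert abs(vb - 1.0) < 0.3
        assert abs(ve - 1.0) < 0.3

    def test_rank_deficiency_names_aliased_terms(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6], "y": np.arange(6.0)})
        df["x2"] = 2 * df["x"]
        with pytest.raises(ValueError, match="aliased"):
            fit_model(ModelSpec("m", "y ~ x + x2"), df)

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="too few"):
            fit_model(ModelSpec("m", "y ~ x"), df)


class TestPosteriorCI:
    def test_matches_analytic_normal_ci_for_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 200)
        df = pd.DataFrame({"x": x, "y": 1.0 + 0.5 * x + rng.normal(0, 1, 200)})
        fit = fit_model(ModelSpec("m", "y ~ x"), df)
        post = posterior_ci(fit, n_draws=5000, seed=0)
        se = np.sqrt(np.diag(fit.cov))
        for i, term in enumerate(fit.names):
            lo = fit.estimates[i] - 1.96 * se[i]
            hi = fit.estimates[i] + 1.96 * se[i]
            tol = 3 * se[i] / np.sqrt(5000) * 1.96 + 0.02 * se[i]
            row = post.table.set_index("term").loc[term]
            assert abs(row["ci_low"] - lo) < max(tol, 0.05 * se[i] * 3)
            assert abs(row["ci_high"] - hi) < max(tol, 0.05 * se[i] * 3)

    def test_zero_covariance_degenerates_to_estimate(self):
        fit = FitResult(["a"], np.array([1.5]), np.zeros((1, 1)), "ols", 10, True)
        post = posterior_ci(fit, n_draws=100, seed=1)
        row = post.table.iloc[0]
        assert row["ci_low"] == row["ci_high"] == pytest.approx(1.5)

    def test_reproducible_under_seed(self):
        fit = FitResult(
            ["a", "b"], np.array([1.0, 2.0]), np.eye(2), "ols", 10, True
        )
        t1 = posterior_ci(fit, n_draws=500, seed=7).table
        t2 = posterior_ci(fit, n_draws=500, seed=7).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_non_psd_covariance_rejected(self):
        fit = FitResult(
            ["a", "b"], np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]),
            "ols", 10, True,
        )
        with pytest.raises(ValueError, match="semi-definite"):
            posterior_ci(fit)


class TestSampleOneSexPerHour:
    def _hourly(self, n=400):
        return pd.DataFrame(
            {
                "nest_id": ["N1"] * n,
                "attendance_female": np.linspace(0, 1, n),
                "attendance_male": np.linspace(1, 0, n),
            }
        )

    def test_single_sex_per_row_and_matching_value(self):
        out = sample_one_sex_per_hour(self._hourly(), seed=3)
        f = out["sex"] == FEMALE
        assert np.allclose(
            out.loc[f, "attendance_sex"], out.loc[f, "attendance_female"]
        )
        assert np.allclose(
            out.loc[~f, "attendance_sex"], out.loc[~f, "attendance_male"]
        )

    def test_sex_proportion_is_binomial_half(self):
        out = sample_one_sex_per_hour(self._hourly(2000), seed=5)
        p = (out["sex"] == MALE).mean()
        assert abs(p - 0.5) < 3 * 0.5 / np.sqrt(2000)

    def test_reproducible(self):
        a = sample_one_sex_per_hour(self._hourly(), seed=9)["sex"]
        b = sample_one_sex_per_hour(self._hourly(), seed=9)["sex"]
        assert (a == b).all()


class TestRepeatability:
    def test_profiled_reml_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        groups = np.repeat([f"N{i}" for i in range(30)], 4)
        y = rng.normal(0, np.sqrt(0.7), 30)[
            pd.factorize(groups)[0]
        ] + rng.normal(0, np.sqrt(0.3), 120)
        df = pd.DataFrame({"y": y, "g": groups})
        mu, vb, ve, _, _ = models._oneway_reml(df["y"].to_numpy(), df["g"].to_numpy())
        res = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(reml=True)
        assert mu == pytest.approx(res.fe_params.iloc[0], abs=1e-4)
        assert vb == pytest.approx(float(np.asarray(res.cov_re).ravel()[0]), abs=1e-3)
        assert ve == pytest.approx(float(res.scale), abs=1e-3)

    def test_zero_between_variance_recovers_near_zero(self):
        d = synthetic.simulate_daily_attendance(
            60, 3, var_between=0.0, var_resid=0.01, seed=2
        )
        rep = repeatability(d, FEMALE, n_bootstrap=100, seed=1)
        assert rep.R <= 0.05

    def test_requires_replicated_nests(self):
        d = synthetic.simulate_daily_attendance(3, 1, seed=0)
        with pytest.raises(ValueError, match=">=2"):
            repeatability(d, FEMALE)

    def test_ci_orders_and_brackets_estimate_reasonably(self):
        d = synthetic.simulate_daily_attendance(
            40, 4, var_between=0.007, var_resid=0.003, seed=6
        )
        rep = repeatability(d, FEMALE, n_bootstrap=300, seed=2)
        assert 0 <= rep.ci_low <= rep.ci_high <= 1


class TestCompensation:
    def _nests(self, male, female, days=3):
        return pd.DataFrame(
            {
                "nest_id": [f"N{i}" for i in range(len(male))],
                "male_attendance": male,
                "female_attendance": female,
                "n_days_included": days,
                "included": True,
            }
        )

    def test_exact_linear_relation_recovered_to_1e9(self):
        male = np.linspace(0.0, 0.4, 20)
        df = self._nests(male, 0.9 - 0.62 * male)
        c = compensation(df, n_draws=100, seed=0)
        assert c.estimate == pytest.approx(0.62, abs=1e-9)

    def test_independent_female_attendance_gives_zero(self):
        rng = np.random.default_rng(3)
        male = np.linspace(0.0, 0.4, 40)
        df = self._nests(male, 0.75 + rng.normal(0, 0.02, 40))
        c = compensation(df, n_draws=2000, seed=1)
        assert abs(c.estimate) < 0.1
        assert c.ci_low <= 0.0 <= c.ci_high

    def test_constant_male_attendance_rejected(self):
        df = self._nests(np.full(12, 0.2), np.full(12, 0.7))
        with pytest.raises(ValueError, match="constant"):
            compensation(df)

    def test_needs_at_least_ten_nests(self):
        male = np.linspace(0, 0.4, 5)
        with pytest.raises(ValueError, match=">=10"):
            compensation(self._nests(male, 0.9 - 0.5 * male))


def test_suite_propagates_per_model_errors_without_aborting():
    out = models.run_model_suite({"nests": pd.DataFrame()}, n_draws=50, seed=0)
    assert all("error" in v for v in out.values())


def test_suite_null_daytime_rhythm_covers_zero():
    df = synthetic.simulate_hourly_rhythm(n_nests=20, n_days=3, amplitude=0.0, seed=21)
    out = models.run_model_suite({"hourly": df}, n_draws=1000, seed=2)
    post = out["hourly_attendance"]["posterior"].table.set_index("term")
    for term in ("sin24", "cos24", "sin12", "cos12"):
        assert post.loc[term, "ci_low"] <= 0.0 <= post.loc[term, "ci_high"]
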
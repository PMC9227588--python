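"""Spline basis, OLS machinery, LR tests, and adjusted curves."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from folcog import splines as spl
from folcog.synthetic import SyntheticConfig, generate_cohort


def _np_knots():
    rng = np.random.default_rng(5)
    x = np.exp(rng.normal(4, 0.4, 400))
    return x, spl.compute_knots(x)


class TestKnots:
    def test_percentile_rule_matches_order_statistic_oracle(self):
        x = np.arange(1.0, 101.0)
        spec = spl.compute_knots(x)
        # independent computation: linear interpolation of sorted values
        xs = np.sort(x)
        expected = []
        for q in (10, 50, 90):
            h = (len(xs) - 1) * q / 100
            lo = int(np.floor(h))
            expected.append(xs[lo] + (h - lo) * (xs[min(lo + 1, len(xs) - 1)] - xs[lo]))
        np.testing.assert_allclose(spec.knots, expected)

    def test_constant_exposure_rejected(self):
        with pytest.raises(spl.DegenerateKnotError):
            spl.compute_knots(np.full(50, 3.0))

    def test_knots_within_range_and_increasing(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10) * 5 + 20
        spec = spl.compute_knots(x)
        t = np.asarray(spec.knots)
        assert np.all(np.diff(t) > 0)
        assert t[0] >= x.min() and t[2] <= x.max()


class TestRcsBasis:
    def test_zero_below_first_knot(self):
        _, spec = _np_knots()
        x = np.linspace(spec.knots[0] - 10, spec.knots[0], 20)
        basis = spl.rcs_basis(x, spec)
        np.testing.assert_allclose(basis[:, 1], 0.0)

    def test_matches_closed_form_oracle(self):
        x, spec = _np_knots()
        t1, t2, t3 = spec.knots
        # independent evaluation of the restricted truncated-power form
        pos = lambda u: np.where(u > 0, u, 0.0) ** 3
        expected = (
            pos(x - t1)
            - pos(x - t2) * (t3 - t1) / (t3 - t2)
            + pos(x - t3) * (t2 - t1) / (t3 - t2)
        ) / (t3 - t1) ** 2
        np.testing.assert_allclose(spl.rcs_basis(x, spec)[:, 1], expected)

    @given(shift=st.floats(1.0, 100.0))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_linear_beyond_boundary_knot(self, shift):
        _, spec = _np_knots()
        t3 = spec.knots[2]
        x = t3 + shift + np.array([0.0, 1.0, 2.0])
        r = spl.rcs_basis(x, spec)[:, 1]
        second_diff = r[2] - 2 * r[1] + r[0]
        assert abs(second_diff) < 1e-6 * max(1.0, abs(r[1]))


class TestBuildDesign:
    def test_reference_coding_of_marital(self, small_cohort):
        df, _ = small_cohort
        spec = spl.compute_knots(df["serum_total_folate"].dropna())
        X, _, _ = spl.build_design(df, "serum_total_folate", "af", spline=spec)
        marital_cols = [c for c in X.columns if c.startswith("marital_")]
        n_levels = df["marital"].nunique()
        assert len(marital_cols) == n_levels - 1

    def test_age_square_construction(self, small_cohort):
        df, _ = small_cohort
        spec = spl.compute_knots(df["serum_total_folate"].dropna())
        X, _, _ = spl.build_design(df, "serum_total_folate", "af", spline=spec)
        np.testing.assert_allclose(X["age_sq"], X["age"] ** 2)

    def test_zero_variance_column_dropped_with_warning(self, small_cohort):
        df, _ = small_cohort
        df = df.copy()
        df["sex"] = "female"
        spec = spl.compute_knots(df["serum_total_folate"].dropna())
        with pytest.warns(UserWarning, match="zero-variance"):
            X, _, _ = spl.build_design(df, "serum_total_folate", "af", spline=spec)
        assert not any(c.startswith("sex") for c in X.columns)


class TestFitOls:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        y = pd.Series(rng.normal(size=20))
        fit = spl.fit_ols(X, y)
        Xv = X.to_numpy()
        beta = np.linalg.solve(Xv.T @ Xv, Xv.T @ y.to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-8)
        rss = float(((y.to_numpy() - Xv @ beta) ** 2).sum())
        assert fit.rss == pytest.approx(rss, rel=1e-10)

    def test_loglik_invariant(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            np.column_stack([np.ones(50), rng.normal(size=50)]), columns=["i", "x"]
        )
        y = pd.Series(rng.normal(size=50))
        fit = spl.fit_ols(X, y)
        expected = -(50 / 2) * (np.log(2 * np.pi * fit.rss / 50) + 1)
        assert fit.loglik == pytest.approx(expected, rel=1e-12)

    def test_matches_statsmodels_loglik(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            np.column_stack([np.ones(80), rng.normal(size=(80, 2))]),
            columns=["i", "x1", "x2"],
        )
        y = pd.Series(rng.normal(size=80))
        fit = spl.fit_ols(X, y)
        sm_fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        assert fit.loglik == pytest.approx(sm_fit.llf, rel=1e-10)

    def test_perfect_fit_loglik_finite(self):
        x = np.linspace(0, 1, 30)
        X = pd.DataFrame({"i": np.ones(30), "x": x})
        y = pd.Series(2.0 + 3.0 * x)
        fit = spl.fit_ols(X, y)
        assert np.isfinite(fit.loglik)

    def test_duplicated_column_raises(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        X = pd.DataFrame({"i": np.ones(30), "x": x, "x2": x})
        with pytest.raises(ValueError, match="rank-deficient"):
            spl.fit_ols(X, pd.Series(rng.normal(size=30)))


class TestLrTests:
    def _two_fits(self, nonlinear=False, n=300, seed=0):
        rng = np.random.default_rng(seed)
        x = np.exp(rng.normal(4, 0.4, n))
        y = 0.05 * x + rng.normal(0, 1, n)
        if nonlinear:
            y = y - 0.1 * np.maximum(x - np.median(x), 0)
        spec = spl.compute_knots(x)
        basis = spl.rcs_basis(x, spec)
        X_l = pd.DataFrame({"i": np.ones(n), "x": x})
        X_s = X_l.assign(x_rcs=basis[:, 1])
        ys = pd.Series(y)
        return spl.fit_ols(X_l, ys), spl.fit_ols(X_s, ys)

    def test_identical_rss_gives_lr_zero_p_one(self):
        fit_l, fit_s = self._two_fits()
        fake_s = spl.SplineFit(
            params=fit_s.params,
            cov_params=fit_s.cov_params,
            rss=fit_l.rss,
            loglik=fit_l.loglik,
            n=fit_l.n,
            k_params=fit_l.k_params + 1,
        )
        t = spl.lr_nonlinearity(fit_l, fake_s)
        assert t.statistic == pytest.approx(0.0, abs=1e-10)
        assert t.pvalue == pytest.approx(1.0)

    def test_lr_equals_arithmetic_oracle(self):
        fit_l, fit_s = self._two_fits(nonlinear=True)
        t = spl.lr_nonlinearity(fit_l, fit_s)
        n = fit_l.n
        assert t.statistic == pytest.approx(n * np.log(fit_l.rss / fit_s.rss), rel=1e-9)
        assert t.statistic == pytest.approx(2 * (fit_s.loglik - fit_l.loglik), rel=1e-9)
        assert t.df == 1

    def test_detects_strong_kink(self):
        fit_l, fit_s = self._two_fits(nonlinear=True, n=500)
        assert spl.lr_nonlinearity(fit_l, fit_s).pvalue < 0.01

    def test_mismatched_n_rejected(self):
        fit_l, _ = self._two_fits(n=300)
        _, fit_s = self._two_fits(n=200)
        with pytest.raises(ValueError, match="same rows"):
            spl.lr_nonlinearity(fit_l, fit_s)

    def test_lr_invariant_to_affine_exposure_rescaling(self, small_cohort):
        df, _ = small_cohort
        res1 = spl.fit_spline_model(df, "serum_total_folate", "af")
        df2 = df.copy()
        df2["serum_total_folate"] = 3.5 * df2["serum_total_folate"] + 11.0
        res2 = spl.fit_spline_model(df2, "serum_total_folate", "af")
        assert res1["nonlinearity"].statistic == pytest.approx(
            res2["nonlinearity"].statistic, abs=1e-8, rel=1e-8
        )


class TestPredictCurve:
    def test_ci_matches_delta_method_oracle(self, small_cohort):
        df, _ = small_cohort
        res = spl.fit_spline_model(df, "serum_total_folate", "af")
        X, fit, spec = res["X"], res["fit_spline"], res["spec"]
        g = float(np.median(X["serum_total_folate"]))
        curve = spl.predict_curve(fit, spec, X, "serum_total_folate", grid=[g])
        xbar = X.to_numpy(dtype=float).mean(axis=0)
        cols = list(X.columns)
        basis = spl.rcs_basis(np.array([g]), spec)
        xbar[cols.index("serum_total_folate")] = basis[0, 0]
        xbar[cols.index("serum_total_folate_rcs")] = basis[0, 1]
        se = np.sqrt(xbar @ fit.cov_params.to_numpy() @ xbar)
        expected_fit = xbar @ fit.params.to_numpy()
        assert curve.fit[0] == pytest.approx(expected_fit, rel=1e-10)
        assert (curve.upper[0] - curve.fit[0]) == pytest.approx(1.959964 * se, rel=1e-5)

    def test_bounds_ordering(self, small_cohort):
        df, _ = small_cohort
        res = spl.fit_spline_model(df, "serum_total_folate", "af")
        curve = spl.predict_curve(
            res["fit_spline"], res["spec"], res["X"], "serum_total_folate", n_grid=25
        )
        assert np.all(curve.lower <= curve.fit) and np.all(curve.fit <= curve.upper)

    def test_curve_linear_beyond_boundary_knot(self, small_cohort):
        df, _ = small_cohort
        res = spl.fit_spline_model(df, "serum_total_folate", "af")
        t3 = res["spec"].knots[2]
        xmax = res["X"]["serum_total_folate"].max()
        grid = np.linspace(t3 + 0.05 * (xmax - t3), xmax, 8)
        curve = spl.predict_curve(
            res["fit_spline"], res["spec"], res["X"], "serum_total_folate", grid=grid
        )
        second = np.diff(curve.fit, 2)
        assert np.all(np.abs(second) < 1e-8 * max(1.0, np.abs(curve.fit).max()))

    def test_extrapolation_rejected(self, small_cohort):
        df, _ = small_cohort
        res = spl.fit_spline_model(df, "serum_total_folate", "af")
        xmax = res["X"]["serum_total_folate"].max()
        with pytest.raises(ValueError, match="grid"):
            spl.predict_curve(
                res["fit_spline"], res["spec"], res["X"], "serum_total_folate",
                grid=[xmax * 2],
            )

    def test_se_wider_in_sparse_tail(self, small_cohort):
        df, _ = small_cohort
        res = spl.fit_spline_model(df, "serum_total_folate", "af")
        x = res["X"]["serum_total_folate"].to_numpy()
        g_mid, g_tail = np.percentile(x, [10, 99])
        curve = spl.predict_curve(
            res["fit_spline"], res["spec"], res["X"], "serum_total_folate",
            grid=[g_mid, g_tail],
        )
        half = (curve.upper - curve.lower) / 2
        assert half[1] > half[0]


class TestStratifiedAnalyses:
    def test_single_stratum_when_status_constant(self, small_cohort):
        df, _ = small_cohort
        df = df.copy()
        df["low_b12"] = 0.0
        out = spl.subgroup_fits(df, "serum_total_folate", "af")
        assert list(out.keys()) == ["normal"]

    def test_tiny_stratum_skipped_with_warning(self, small_cohort):
        df, _ = small_cohort
        df = df.copy()
        df["low_b12"] = 0.0
        df.iloc[:5, df.columns.get_loc("low_b12")] = 1.0
        with pytest.warns(UserWarning, match="skipped"):
            out = spl.subgroup_fits(df, "serum_total_folate", "af")
        assert "low" not in out

    def test_constant_modifier_rejected(self, small_cohort):
        df, _ = small_cohort
        df = df.copy()
        df["low_b12"] = 1.0
        with pytest.raises(ValueError, match="variation"):
            spl.interaction_lr(df, "serum_total_folate", "af")

    def test_interaction_df_is_two(self, default_cohort):
        adf = default_cohort["cohort"].data
        t = spl.interaction_lr(adf, "serum_total_folate", "af")
        assert t.df == 2
        assert 0.0 <= t.pvalue <= 1.0

    def test_interaction_power_when_slope_doubles(self):
        # modifier doubles the exposure slope: LR interaction should detect it
        rng = np.random.default_rng(8)
        n = 2000
        x = np.exp(rng.normal(4, 0.4, n))
        m = (rng.random(n) < 0.4).astype(float)
        y = 0.05 * x * (1 + m) + rng.normal(0, 1.5, n)
        df = pd.DataFrame({"x": x, "y": y, "mod": m})
        t = spl.interaction_lr(df, "x", "y", status_col="mod", adjust=False)
        assert t.pvalue < 0.05
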
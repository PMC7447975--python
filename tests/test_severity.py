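"""Severity GAMM: screening, oversampling, fitting, thresholds, LTS."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import cyclesafe.gam as gam
import cyclesafe.severity as sev
from cyclesafe.errors import InvalidArgumentError


class TestScreenCovariates:
    @staticmethod
    def base_frame(rng, n=800):
        y = (rng.random(n) < 0.3).astype(int)
        return pd.DataFrame({"fatal": y}), y

    def test_missingness_rule(self, rng):
        df, y = self.base_frame(rng)
        v = rng.normal(size=len(df))
        v[: int(0.15 * len(df))] = np.nan
        df["patchy"] = v
        res = sev.screen_covariates(df, ["patchy"])
        assert "patchy" not in res.selected
        reason = res.exclusions.set_index("covariate").loc["patchy",
                                                           "reason"]
        assert reason == "missingness"

    def test_independent_covariate_dropped_by_bivariate_p(self, rng):
        df, y = self.base_frame(rng)
        # exactly-null covariate: each outcome class gets the quantile grid
        # of the same distribution, so the two-sample statistic is ~0
        from scipy.stats import norm

        noise = np.empty(len(df))
        for cls in (0, 1):
            m = (y == cls).sum()
            noise[y == cls] = norm.ppf((np.arange(m) + 0.5) / m)
        df["noise"] = noise
        df["signal"] = y + rng.normal(0, 0.5, len(df))
        res = sev.screen_covariates(df, ["noise", "signal"])
        assert "signal" in res.selected
        assert "noise" not in res.selected
        reason = res.exclusions.set_index("covariate").loc["noise",
                                                           "reason"]
        assert reason == "bivariate p"

    def test_constant_covariate_degenerate(self, rng):
        df, _ = self.base_frame(rng)
        df["flat"] = 1.0
        res = sev.screen_covariates(df, ["flat"])
        reason = res.exclusions.set_index("covariate").loc["flat", "reason"]
        assert reason == "degenerate"

    def test_collinear_pair_drops_one(self, rng):
        df, y = self.base_frame(rng)
        df["a"] = y + rng.normal(0, 0.3, len(df))
        df["b"] = df["a"] + rng.normal(0, 0.01, len(df))
        res = sev.screen_covariates(df, ["a", "b"])
        assert len({"a", "b"} & set(res.selected)) == 1
        assert (res.exclusions["reason"] == "collinearity").any()

    def test_constant_outcome_rejected(self, rng):
        df = pd.DataFrame({"fatal": np.zeros(50), "x": rng.normal(size=50)})
        with pytest.raises(InvalidArgumentError):
            sev.screen_covariates(df, ["x"])


class TestOversample:
    @staticmethod
    def table(n_neg, n_pos):
        return pd.DataFrame({
            "fatal": [0] * n_neg + [1] * n_pos,
            "row": range(n_neg + n_pos)})

    def test_exact_target_on_divisible_counts(self):
        out = sev.oversample(self.table(700, 30), 0.30, seed=1)
        assert len(out) == 1000
        assert out["fatal"].sum() == 300
        assert out["fatal"].mean() == pytest.approx(0.30)

    def test_already_at_target_unchanged_with_warning(self):
        t = self.table(70, 30)
        with pytest.warns(UserWarning):
            out = sev.oversample(t, 0.30, seed=1)
        pd.testing.assert_frame_equal(out, t)

    def test_seed_determinism(self):
        a = sev.oversample(self.table(500, 25), 0.30, seed=7)
        b = sev.oversample(self.table(500, 25), 0.30, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_negatives_untouched(self):
        out = sev.oversample(self.table(200, 10), 0.30, seed=3)
        assert (out["fatal"] == 0).sum() == 200


class TestFitGamm:
    def test_intercept_only_equals_logit_prevalence(self, rng):
        y = (rng.random(600) < 0.25).astype(int)
        df = pd.DataFrame({"fatal": y})
        spec = sev.ModelSpec(linear_terms={}, smooth_terms=[],
                             spatial_smooth=None, random_intercepts=[])
        fit = sev.fit_gamm(df, spec)
        assert fit.coefficients["estimate"].iloc[0] == pytest.approx(
            float(logit(y.mean())), abs=1e-6)

    def test_binary_covariate_matches_2x2_oracle(self, rng):
        """Unpenalized logistic fit equals the closed-form 2x2-table
        log-odds-ratio."""
        x = (rng.random(3000) < 0.4).astype(int)
        y = rng.binomial(1, expit(-1.5 + 0.9 * x))
        df = pd.DataFrame({"fatal": y, "xflag": x})
        spec = sev.ModelSpec(linear_terms={"xflag": None}, smooth_terms=[],
                             spatial_smooth=None, random_intercepts=[])
        fit = sev.fit_gamm(df, spec)
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        oracle = np.log(a * d / (b * c))
        est = fit.coefficients.set_index("term").loc["xflag", "estimate"]
        assert est == pytest.approx(oracle, abs=1e-6)

    def test_matches_mgcv_reml_oracle(self, rng, tmp_path):
        """Cross-check the linear coefficient of a smooth+linear binomial
        fit against mgcv's REML estimate on the same data."""
        n = 3000
        x = (rng.random(n) < 0.35).astype(int)
        z = rng.uniform(0, 10, n)
        y = rng.binomial(1, expit(-2.0 + 0.9 * x + 0.4 * np.sin(z)))
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        spec = sev.ModelSpec(linear_terms={"x": None},
                             smooth_terms=[sev.SmoothSpec("z")],
                             spatial_smooth=None, random_intercepts=[])
        fit = sev.fit_gamm(df.rename(columns={"y": "fatal"}), spec)
        co = fit.coefficients.set_index("term")
        script = textwrap.dedent(f"""
            suppressMessages(library(mgcv))
            d <- read.csv("{csv}")
            m <- gam(y ~ x + s(z, bs='tp', k=10), family=binomial,
                     method='REML', data=d)
            cat(coef(m)['x'], summary(m)$se['x'], sep='\\n')
        """)
        out = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, check=True)
        mgcv_coef, mgcv_se = (float(v) for v in out.stdout.split())
        assert co.loc["x", "estimate"] == pytest.approx(mgcv_coef, abs=0.05)
        assert co.loc["x", "se"] == pytest.approx(mgcv_se, rel=0.10)

    def test_smooth_collapses_to_line_at_large_lambda(self, rng):
        """With the smoothing parameter forced huge, the penalized spline
        falls into its null space: the fitted curve is a straight line and
        the fit matches a parametric linear-logistic fit."""
        import statsmodels.api as smapi

        n = 2500
        z = rng.uniform(0, 10, n)
        y = rng.binomial(1, expit(-1.0 + 0.25 * z))
        df = pd.DataFrame({"fatal": y, "z": z})
        spec = sev.ModelSpec(linear_terms={}, smooth_terms=[
            sev.SmoothSpec("z")], spatial_smooth=None, random_intercepts=[])
        fit = sev.fit_gamm(df, spec, lambdas=[1e9], optimize_lambda=False)
        sm = fit.smooths["z"]
        # residual from the least-squares line is tiny relative to range
        coef = np.polyfit(sm["x"], sm["fit"], 1)
        resid = sm["fit"] - np.polyval(coef, sm["x"])
        assert np.max(np.abs(resid)) < 0.02 * np.ptp(sm["fit"])
        glm = smapi.GLM(y, smapi.add_constant(z),
                        family=smapi.families.Binomial()).fit()
        assert fit.raw.deviance == pytest.approx(glm.deviance, abs=1.0)

    def test_oversampling_shifts_only_intercept(self, rng):
        """Case-control-style resampling leaves slope estimates consistent;
        the intercept shifts by the log sampling-odds ratio."""
        n = 20_000
        x = (rng.random(n) < 0.5).astype(int)
        y = rng.binomial(1, expit(-3.0 + 1.0 * x))
        df = pd.DataFrame({"fatal": y, "xflag": x})
        spec = sev.ModelSpec(linear_terms={"xflag": None}, smooth_terms=[],
                             spatial_smooth=None, random_intercepts=[])
        raw = sev.fit_gamm(df, spec)
        bal = sev.fit_gamm(sev.oversample(df, 0.30, seed=2), spec)
        raw_co = raw.coefficients.set_index("term")
        bal_co = bal.coefficients.set_index("term")
        assert abs(bal_co.loc["xflag", "estimate"]
                   - raw_co.loc["xflag", "estimate"]) \
            < 2 * raw_co.loc["xflag", "se"]
        assert abs(bal_co.loc["intercept", "estimate"]
                   - raw_co.loc["intercept", "estimate"]) > 0.5

    def test_complete_separation_flagged_not_infinite(self, rng):
        x = (rng.random(400) < 0.1).astype(int)
        y = x.copy()  # perfect separation
        df = pd.DataFrame({"fatal": y, "xflag": x})
        spec = sev.ModelSpec(linear_terms={"xflag": None}, smooth_terms=[],
                             spatial_smooth=None, random_intercepts=[])
        fit = sev.fit_gamm(df, spec)
        co = fit.coefficients.set_index("term")
        assert np.isfinite(co.loc["xflag", "estimate"])
        assert co.loc["xflag", "flag"] == "separation"

    def test_fit_invariant_to_row_order_and_zone_relabel(
            self, default_collisions, simple_gamm_spec):
        table, _ = default_collisions
        data = table.sample(n=2000, random_state=0).reset_index(drop=True)
        spec = sev.ModelSpec(
            linear_terms=dict(simple_gamm_spec.linear_terms),
            smooth_terms=simple_gamm_spec.smooth_terms,
            spatial_smooth=None, random_intercepts=["zone_id"])
        base = sev.fit_gamm(data, spec)
        shuffled = sev.fit_gamm(
            data.sample(frac=1, random_state=1).reset_index(drop=True),
            spec)
        relabeled = sev.fit_gamm(
            data.assign(zone_id="X" + data["zone_id"].str[1:]), spec)
        for other in (shuffled, relabeled):
            pd.testing.assert_frame_equal(
                base.coefficients, other.coefficients,
                atol=1e-4, rtol=1e-3)


class TestSmoothThresholds:
    def test_null_smooth_mostly_empty(self, rng):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            z = r.uniform(0, 10, 3000)
            y = r.binomial(1, 0.2, 3000)
            df = pd.DataFrame({"fatal": y, "z": z})
            spec = sev.ModelSpec(linear_terms={}, smooth_terms=[
                sev.SmoothSpec("z")], spatial_smooth=None,
                random_intercepts=[])
            fit = sev.fit_gamm(df, spec)
            hits += bool(sev.smooth_thresholds(fit, "z"))
        assert hits <= 2

    def test_band_above_zero_gives_full_interval(self):
        sm = pd.DataFrame({"x": np.linspace(0, 1, 5),
                           "fit": 1.0, "se": 0.1,
                           "lo": 0.8, "hi": 1.2})
        fit = sev.SeverityFit(
            coefficients=pd.DataFrame(), smooths={"z": sm}, random_sd={},
            n_obs=0, converged=True, edf=0, deviance=0, spec=None, raw=None)
        assert sev.smooth_thresholds(fit, "z") == []
        assert sev.significant_intervals(fit, "z") == [(0.0, 1.0)]

    def test_hinge_threshold_recovered_near_kink(self):
        """Effect confined to a small upper tail: the significance onset
        lands within one grid step of the planted kink."""
        r = np.random.default_rng(3)
        n = 12_000
        x = np.minimum(r.exponential(1.2, n), 8.0)
        y = r.binomial(1, expit(logit(0.05) + 0.8 * np.maximum(x - 3, 0)))
        df = pd.DataFrame({"fatal": y, "xv": x})
        bal = sev.oversample(df, 0.30, seed=3)
        spec = sev.ModelSpec(linear_terms={}, smooth_terms=[
            sev.SmoothSpec("xv")], spatial_smooth=None,
            random_intercepts=[])
        fit = sev.fit_gamm(bal, spec, grid_size=25)
        th = sev.smooth_thresholds(fit, "xv")
        sm = fit.smooths["xv"]
        spacing = float(sm["x"].iloc[1] - sm["x"].iloc[0])
        assert any(abs(t - 3.0) <= spacing for t in th)


class TestLtsRating:
    def test_bike_path_rates_one(self):
        seg = {"lanes": 3, "lane_width": 3.0, "speed_limit": 60,
               "has_bike_path": True, "has_transit_route": True}
        assert sev.lts_rating(seg) == 1

    def test_wide_fast_road_rates_four(self):
        seg = {"lanes": 4, "lane_width": 3.5, "speed_limit": 60,
               "has_bike_path": False, "has_transit_route": True}
        assert sev.lts_rating(seg) == 4

    def test_quiet_street_moderate(self):
        seg = {"lanes": 2, "lane_width": 3.0, "speed_limit": 30,
               "has_bike_path": False, "has_transit_route": False}
        assert sev.lts_rating(seg) == 2

    def test_table_is_total_and_deterministic(self, rng):
        for _ in range(50):
            seg = {"lanes": int(rng.integers(1, 6)),
                   "lane_width": float(rng.uniform(2.5, 4)),
                   "speed_limit": float(rng.choice([30, 40, 50, 60, 80])),
                   "has_bike_path": bool(rng.random() < 0.5),
                   "has_transit_route": bool(rng.random() < 0.5)}
            a = sev.lts_rating(seg)
            assert a in (1, 2, 3, 4)
            assert sev.lts_rating(seg) == a


class TestStratifiedFit:
    def test_single_class_stratum_skipped(self, rng):
        n = 400
        df = pd.DataFrame({
            "fatal": np.r_[rng.binomial(1, 0.3, n), np.zeros(50, int)],
            "sex": ["M"] * n + ["F"] * 50,
            "xflag": rng.integers(0, 2, n + 50)})
        spec = sev.ModelSpec(linear_terms={"xflag": None}, smooth_terms=[],
                             spatial_smooth=None, random_intercepts=[])
        with pytest.warns(UserWarning, match="single outcome class"):
            fits = sev.stratified_fit(df, spec, strata="sex")
        assert fits["F"] is None
        assert fits["M"] is not None and fits["pooled"] is not None

    def test_sex_specific_effect_found_in_right_stratum(self, rng):
        n = 8000
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        x = (rng.random(n) < 0.4).astype(int)
        eta = -2.0 + np.where(sex == "F", 1.5, 0.0) * x
        y = rng.binomial(1, expit(eta))
        df = pd.DataFrame({"fatal": y, "sex": sex, "xflag": x})
        spec = sev.ModelSpec(linear_terms={"xflag": None}, smooth_terms=[],
                             spatial_smooth=None, random_intercepts=[])
        fits = sev.stratified_fit(df, spec, strata="sex")
        f = fits["F"].coefficients.set_index("term")
        m = fits["M"].coefficients.set_index("term")
        assert f.loc["xflag", "p"] < 0.01
        assert abs(m.loc["xflag", "estimate"]) < 3 * m.loc["xflag", "se"]
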
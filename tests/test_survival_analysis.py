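"""Person-time construction, Cox fitting, trend/spline/PH/interaction tests.

Oracle routes: a brute-force partial-likelihood grid search on a tiny
fixture, reference values from R survival::coxph / cox.zph frozen for a
deterministic fixture, a lifelines cross-check on counting-process data,
and planted-truth simulations for power and calibration.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_participants, simulate_dataset
from pbdi import (
    ConvergenceError,
    build_persontime,
    fit_cox,
    fit_spline,
    interaction_tests,
    ph_test,
    sensitivity_exclude_early,
    trend_test,
)
from pbdi.survival_analysis import (
    CoxFitResult,
    _covariate_frame,
    _phreg,
    person_years,
    rcs_basis,
)


def exposure_frame(ids, total, quartile, energy=2000.0):
    return pd.DataFrame(
        {"total": total, "quartile": quartile, "energy": energy},
        index=pd.Index(ids, name="id"),
    )


class TestBuildPersontime:
    def three_person_inputs(self):
        rng = np.random.default_rng(0)
        p = make_participants(3, rng)
        fu = pd.DataFrame({
            "id": [1, 2, 3],
            "exit_time": [3.0, 10.0, 18.0],
            "event": ["none", "CHD", "dropout"],
        })
        fa = exposure_frame([1, 2, 3], [45.0, 52.0, 60.0], [1, 2, 4])
        fb = exposure_frame([1, 2, 3], [46.0, 55.0, 58.0], [1, 3, 4])
        return p, fu, fa, fb

    def test_censoring_before_split_gives_single_wave1_segment(self):
        p, fu, fa, fb = self.three_person_inputs()
        ds = build_persontime(p, fu, fa, fb, "CHD", split_time=4.0)
        rows = ds.loc[ds["id"] == 1]
        assert len(rows) == 1
        assert rows.iloc[0]["stop"] == 3.0
        assert rows.iloc[0]["event"] == 0
        assert rows.iloc[0]["total"] == 45.0

    def test_event_after_split_gets_two_segments_with_cumulative_exposure(self):
        p, fu, fa, fb = self.three_person_inputs()
        ds = build_persontime(p, fu, fa, fb, "CHD", split_time=4.0)
        rows = ds.loc[ds["id"] == 2].sort_values("start")
        assert [tuple(r) for r in rows[["start", "stop", "event"]].to_numpy()] == [
            (0.0, 4.0, 0), (4.0, 10.0, 1)
        ]
        assert rows.iloc[0]["quartile"] == 2   # wave-1 exposure
        assert rows.iloc[1]["quartile"] == 3   # cumulative-average exposure

    def test_person_years_conserved_under_splitting(self):
        p, fu, fa, fb = self.three_person_inputs()
        single = build_persontime(p, fu, fa, None, "CHD")
        split = build_persontime(p, fu, fa, fb, "CHD", split_time=4.0)
        assert person_years(single) == pytest.approx(3.0 + 10.0 + 18.0)
        assert person_years(split) == pytest.approx(person_years(single))

    def test_competing_subtype_censors(self):
        p, fu, fa, fb = self.three_person_inputs()
        ds_stroke = build_persontime(p, fu, fa, fb, "stroke", split_time=4.0)
        assert ds_stroke["event"].sum() == 0
        ds_cvd = build_persontime(p, fu, fa, fb, "CVD", split_time=4.0)
        assert ds_cvd["event"].sum() == 1

    def test_unknown_outcome_rejected(self):
        p, fu, fa, fb = self.three_person_inputs()
        with pytest.raises(ValueError, match="outcome"):
            build_persontime(p, fu, fa, fb, "cancer")


class TestCoxEngine:
    def test_matches_grid_search_partial_likelihood(self):
        # 6 participants, one binary covariate, distinct event times
        df = pd.DataFrame({
            "start": 0.0,
            "stop": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 0, 1],
            "x": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0],
        })
        x = df["x"].to_numpy()
        stop = df["stop"].to_numpy()
        ev = df["event"].to_numpy().astype(bool)

        def pll(beta):
            ll = 0.0
            for t, xi in zip(stop[ev], x[ev]):
                risk = stop >= t
                ll += beta * xi - np.log(np.exp(beta * x[risk]).sum())
            return ll

        grid = np.arange(-3.0, 3.0, 1e-3)
        best = grid[np.argmax([pll(b) for b in grid])]
        params, _, _, ok = _phreg(df, df[["x"]])
        assert ok
        assert params["x"] == pytest.approx(best, abs=2e-3)

    def r_oracle_fixture(self):
        """Deterministic fixture with delayed entry; reference values below
        were computed with R survival::coxph(ties='efron') and
        cox.zph(transform='identity')."""
        rng = np.random.default_rng(7)
        n = 80
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.4).astype(float)
        start = np.where(rng.random(n) < 0.3, rng.uniform(0.5, 2.0, n), 0.0)
        lam = 0.15 * np.exp(0.5 * x1 + 0.8 * x2)
        t = start + rng.exponential(1 / lam, n)
        cens = start + rng.exponential(1 / 0.1, n)
        stop = np.minimum(np.minimum(t, cens), 12.0)
        event = ((t <= cens) & (t < 12.0)).astype(int)
        return pd.DataFrame(dict(start=start, stop=stop, event=event, x1=x1, x2=x2))

    def test_matches_r_survival_coxph(self):
        df = self.r_oracle_fixture()
        params, cov, llf, ok = _phreg(df, df[["x1", "x2"]])
        assert ok
        assert params.to_numpy() == pytest.approx([0.49605942, 0.59960295], abs=1e-6)
        assert np.sqrt(np.diag(cov)) == pytest.approx([0.16858455, 0.27821828], abs=1e-6)
        assert llf == pytest.approx(-185.59996978, abs=1e-6)

    def test_ph_test_matches_r_cox_zph(self):
        df = self.r_oracle_fixture()
        params, cov, llf, ok = _phreg(df, df[["x1", "x2"]])
        fit = CoxFitResult({}, llf, int(df["event"].sum()), person_years(df),
                           params, cov, "custom", ok,
                           design=df[["x1", "x2"]], dataset=df)
        res = ph_test(fit, "identity")
        assert res.per_covariate.loc["x1", "stat"] == pytest.approx(2.02996859, abs=1e-6)
        assert res.per_covariate.loc["x2", "stat"] == pytest.approx(0.19075756, abs=1e-6)
        assert res.global_stat == pytest.approx(2.41927569, abs=1e-6)
        assert res.global_p == pytest.approx(0.29830529, abs=1e-6)

    def test_cross_check_against_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(17)
        ds, _ = simulate_dataset(rng, n=400, base_hazard=0.02,
                                 beta_by_quartile=(0.1, 0.2, 0.4))
        fit = fit_cox(ds, model="age_sex")
        df = ds[["start", "stop", "event", "age", "sex_male"]].copy()
        for k in (2, 3, 4):
            df[f"quartile_{k}"] = (ds["quartile"] == k).astype(float)
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="stop", event_col="event", entry_col="start")
        for k in (2, 3, 4):
            assert fit.hr_by_quartile[k][0] == pytest.approx(
                np.exp(cph.params_[f"quartile_{k}"]), rel=1e-4
            )

    def test_zero_events_flagged(self):
        rng = np.random.default_rng(1)
        ds, _ = simulate_dataset(rng, n=50, base_hazard=1e-9)
        ds["event"] = 0
        with pytest.raises(ConvergenceError):
            fit_cox(ds, model="age_sex")

    def test_null_ci_coverage(self):
        rng = np.random.default_rng(42)
        cover = {2: 0, 3: 0, 4: 0}
        n_rep = 60
        for _ in range(n_rep):
            ds, _ = simulate_dataset(rng, n=1200, base_hazard=0.012)
            fit = fit_cox(ds, model="age_sex")
            for k in (2, 3, 4):
                _, lo, hi = fit.hr_by_quartile[k]
                cover[k] += lo <= 1.0 <= hi
        for k in (2, 3, 4):
            assert cover[k] / n_rep >= 0.88

    def test_planted_q4_effect_recovered(self):
        rng = np.random.default_rng(77)
        hrs = []
        for _ in range(30):
            ds, _ = simulate_dataset(rng, n=2000, base_hazard=0.012,
                                     beta_by_quartile=(0.1, 0.3, np.log(2.0)))
            hrs.append(fit_cox(ds, model="age_sex").hr_by_quartile[4][0])
        assert 1.8 <= np.median(hrs) <= 2.2

    def test_estimator_error_shrinks_with_n(self):
        rng = np.random.default_rng(88)
        err = {}
        for n in (2000, 8000):
            est = []
            for _ in range(12):
                ds, _ = simulate_dataset(rng, n=n, base_hazard=0.01,
                                         beta_by_quartile=(0.1, 0.3, 0.5))
                est.append(np.log(fit_cox(ds, model="age_sex").hr_by_quartile[4][0]))
            err[n] = np.sqrt(np.mean((np.array(est) - 0.5) ** 2))
        assert err[8000] < err[2000]


class TestTrend:
    def test_monotone_effect_detected(self):
        rng = np.random.default_rng(5)
        hits = sum(
            trend_test(*simulate_dataset(rng, n=1200, base_hazard=0.018,
                                         beta_by_quartile=(0.2, 0.4, 0.6)),
                       model="age_sex") < 0.05
            for _ in range(25)
        )
        assert hits / 25 >= 0.8

    def test_non_monotone_effect_has_little_trend_power(self):
        rng = np.random.default_rng(6)
        hits = sum(
            trend_test(*simulate_dataset(rng, n=1200, base_hazard=0.018,
                                         beta_by_quartile=(0.5, 0.5, 0.0)),
                       model="age_sex") < 0.05
            for _ in range(25)
        )
        assert hits / 25 <= 0.4

    def test_single_quartile_rejected(self):
        rng = np.random.default_rng(2)
        ds, med = simulate_dataset(rng, n=100, base_hazard=0.02)
        ds["quartile"] = 1
        with pytest.raises(ValueError):
            trend_test(ds, {1: 50.0}, model="age_sex")


class TestSpline:
    def test_basis_is_linear_beyond_boundary_knots(self):
        knots = (40.0, 51.0, 62.0)
        x = np.array([20.0, 30.0, 70.0, 80.0])
        y = rcs_basis(x, knots)
        # second differences vanish on each linear tail
        assert (y[1] - y[0]) == pytest.approx(0.0, abs=1e-12)  # below k1: all zero
        slope_hi = (y[3] - y[2]) / 10.0
        y_mid = rcs_basis(np.array([75.0]), knots)[0]
        assert y_mid == pytest.approx(y[2] + slope_hi * 5.0, rel=1e-9)

    def test_nesting_spline_loglik_at_least_linear(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            ds, _ = simulate_dataset(rng, n=600, base_hazard=0.02, quadratic=0.2)
            sp = fit_spline(ds, model="age_sex")
            assert sp.loglik_spline >= sp.loglik_linear - 1e-8
            assert 0.0 <= sp.p_nonlinear <= 1.0

    def test_curve_is_zero_at_reference(self):
        rng = np.random.default_rng(4)
        ds, _ = simulate_dataset(rng, n=600, base_hazard=0.02)
        sp = fit_spline(ds, model="age_sex")
        ref_val = np.interp(sp.reference, sp.grid, sp.log_hr)
        assert ref_val == pytest.approx(0.0, abs=1e-6)

    def test_quadratic_hazard_detected(self):
        rng = np.random.default_rng(15)
        hits = sum(
            fit_spline(simulate_dataset(rng, n=1500, base_hazard=0.02,
                                        quadratic=0.3)[0],
                       model="age_sex").p_nonlinear < 0.05
            for _ in range(25)
        )
        assert hits / 25 >= 0.8

    def test_collapsed_knots_fall_back_to_linear_with_warning(self):
        rng = np.random.default_rng(16)
        ds, _ = simulate_dataset(rng, n=300, base_hazard=0.02)
        ds["total"] = np.where(np.arange(len(ds)) % 100 == 0, 50.0,
                               np.where(np.arange(len(ds)) % 100 == 1, 52.0, 51.0))
        with pytest.warns(UserWarning, match="collapsed"):
            sp = fit_spline(ds, model="age_sex")
        assert np.isnan(sp.p_nonlinear)
        assert sp.knots is None


class TestPHDiagnostics:
    def test_time_varying_effect_detected(self):
        # planted violation: quartile log-HRs double from year 9 onward
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(25):
            ds, _ = simulate_dataset(rng, n=1500, base_hazard=0.012,
                                     beta_by_quartile=(0.6, 0.9, 1.2),
                                     double_after=9.0)
            hits += ph_test(fit_cox(ds, model="age_sex")).global_p < 0.05
        assert hits / 25 >= 0.8

    def test_zero_events_rejected(self):
        rng = np.random.default_rng(10)
        ds, _ = simulate_dataset(rng, n=60, base_hazard=0.02)
        fit = fit_cox(ds, model="age_sex")
        fit.dataset = fit.dataset.assign(event=0)
        with pytest.raises(ValueError):
            ph_test(fit)


class TestInteractions:
    def test_bonferroni_threshold_is_0_007(self):
        rng = np.random.default_rng(11)
        ds, med = simulate_dataset(rng, n=300, base_hazard=0.02)
        res = interaction_tests(ds, med, model="age_sex")
        assert len(res) == 7
        assert res.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 7)
        assert round(res.attrs["bonferroni_threshold"], 3) == 0.007

    def test_familywise_null_error_controlled(self):
        rng = np.random.default_rng(12)
        any_flag = 0
        for _ in range(40):
            ds, med = simulate_dataset(rng, n=500, base_hazard=0.02)
            res = interaction_tests(ds, med, model="age_sex")
            any_flag += res["significant"].any()
        assert any_flag / 40 <= 0.15

    def test_planted_sex_interaction_flagged(self):
        rng = np.random.default_rng(13)
        sex_flagged = 0
        other_flags = 0
        n_rep = 25
        for _ in range(n_rep):
            ds, med = simulate_dataset(rng, n=1500, base_hazard=0.02,
                                       sex_interaction=0.08)
            res = interaction_tests(ds, med, model="age_sex")
            sex_flagged += bool(res.loc["sex", "significant"])
            other_flags += int(res.drop("sex")["significant"].sum())
        assert sex_flagged / n_rep >= 0.7
        assert other_flags / n_rep <= 0.5

    def test_single_level_modifier_rejected(self):
        rng = np.random.default_rng(14)
        ds, med = simulate_dataset(rng, n=200, base_hazard=0.02)
        ds["sex_male"] = 1.0
        with pytest.raises(ValueError, match="single level"):
            interaction_tests(ds, med, modifiers=("sex",), model="age_sex")


class TestSensitivity:
    def test_zero_window_is_noop(self):
        rng = np.random.default_rng(20)
        ds, _ = simulate_dataset(rng, n=500, base_hazard=0.02)
        main = fit_cox(ds, model="age_sex")
        sens = sensitivity_exclude_early(ds, 0.0, model="age_sex")
        assert sens.params.to_numpy() == pytest.approx(main.params.to_numpy())
        assert sens.n_events == main.n_events

    def test_early_events_dropped_from_count(self):
        rng = np.random.default_rng(21)
        ds, _ = simulate_dataset(rng, n=500, base_hazard=0.02)
        n_early = int(((ds["event"] == 1) & (ds["stop"] < 2.0)).sum())
        assert n_early > 0
        sens = sensitivity_exclude_early(ds, 2.0, model="age_sex")
        assert sens.n_events == int(ds["event"].sum()) - n_early

    def test_window_beyond_followup_rejected(self):
        rng = np.random.default_rng(22)
        ds, _ = simulate_dataset(rng, n=100, base_hazard=0.02)
        with pytest.raises(ValueError):
            sensitivity_exclude_early(ds, 100.0)

    def test_null_sensitivity_agrees_with_main_fit(self):
        rng = np.random.default_rng(23)
        diffs = []
        for _ in range(10):
            ds, _ = simulate_dataset(rng, n=1000, base_hazard=0.015)
            main = fit_cox(ds, model="age_sex")
            sens = sensitivity_exclude_early(ds, 2.0, model="age_sex")
            diffs.append(np.log(sens.hr_by_quartile[4][0] / main.hr_by_quartile[4][0]))
        assert abs(np.mean(diffs)) < 0.15
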
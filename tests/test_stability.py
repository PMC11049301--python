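"""Stability: trend fit, checkpoint tests, bands, shelf life."""

import math

import numpy as np
import pytest
from scipy import stats

from commutakit import (SimulationConfig, StabilitySeries, StabilityTrend,
                        baseline_comparison_test, checkpoint_test,
                        estimate_shelf_life, fit_trend, gen_stability,
                        prediction_band_point, stability_uncertainty)

DAYS = (0, 30, 60, 90, 120, 150, 180)


def make_series(day_values, material="M"):
    """Series from {day: [values]} mapping."""
    recs = [(d, f"v{i}", v) for d, vals in day_values.items()
            for i, v in enumerate(vals)]
    return StabilitySeries(material, recs)


def linear_series(slope, intercept=100.0, days=DAYS, n_vials=5, noise=None):
    vals = {}
    for d in days:
        base = intercept + slope * d
        if noise is None:
            # deterministic within-day spread so s_res stays finite
            vals[d] = [base + off for off in
                       np.linspace(-0.2, 0.2, n_vials)]
        else:
            vals[d] = list(base + noise[d])
    return make_series(vals)


class TestTrendFit:
    def test_exact_line_is_recovered_with_zero_residual(self):
        series = make_series({d: [100 - 0.05 * d] * 3 for d in DAYS})
        fit = fit_trend(series, 180)
        assert fit.b1 == pytest.approx(-0.05)
        assert fit.s_res == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_has_zero_slope_and_zero_t(self):
        series = make_series({d: [100.0, 100.0, 100.0] for d in DAYS})
        assert fit_trend(series, 180).b1 == pytest.approx(0.0)
        check = checkpoint_test(series, 180)
        assert check.t_cal == 0.0
        assert check.acceptable

    def test_single_day_window_is_an_error(self):
        series = make_series({0: [100, 101], 30: [99, 100]})
        with pytest.raises(ValueError, match="single distinct day"):
            fit_trend(series, 30)  # day 0 excluded by default

    def test_slope_recovery_monte_carlo(self):
        # true drift -0.02 mg/dL/day, sigma = 1.2, 6 checkpoints x 5 vials
        est = []
        for i in range(500):
            cfg = SimulationConfig(seed=40_000 + i, drift_slope=-0.02,
                                   sigma_bb=0.0, sigma_r=1.2,
                                   checkpoint_days=(0, 30, 60, 90, 120, 180))
            fit = fit_trend(gen_stability(cfg, 120.0), 180)
            est.append(fit.b1)
        assert np.mean(est) == pytest.approx(-0.02, rel=0.15)


class TestCheckpointTest:
    def test_default_design_reproduces_critical_value_sequence(
            self, default_design_series):
        expect = {60: (8, 2.31), 90: (13, 2.16), 120: (18, 2.10),
                  150: (23, 2.07), 180: (28, 2.05)}
        for day, (df, t_crit) in expect.items():
            c = checkpoint_test(default_design_series, day)
            assert c.df == df
            assert round(c.t_critical, 2) == t_crit

    def test_critical_sequence_nonincreasing(self, default_design_series):
        crits = [checkpoint_test(default_design_series, d).t_critical
                 for d in (60, 90, 120, 150, 180)]
        assert all(a >= b for a, b in zip(crits, crits[1:]))

    def test_perfect_drift_line_is_flagged_with_infinite_t(self):
        series = make_series({d: [100 - 0.05 * d] * 5 for d in DAYS})
        c = checkpoint_test(series, 180)
        assert math.isinf(c.t_cal)
        assert not c.acceptable

    def test_baseline_welch_mode_accepts_identical_days(self):
        series = make_series({0: [100, 101, 99, 100, 101],
                              60: [100, 99, 101, 101, 100]})
        c = baseline_comparison_test(series, 60)
        assert c.acceptable

    def test_size_under_null_drift(self):
        # rejection rate of the day-180 slope test with zero drift
        reject = 0
        n_rep = 2000
        for i in range(n_rep):
            cfg = SimulationConfig(seed=50_000 + i, drift_slope=0.0,
                                   sigma_bb=0.0, sigma_r=1.5)
            c = checkpoint_test(gen_stability(cfg, 120.0), 180)
            reject += not c.acceptable
        assert reject / n_rep == pytest.approx(0.05, abs=0.02)


class TestUncertaintyAndBand:
    def test_u_sta_is_linear_in_horizon(self):
        series = linear_series(-0.01)
        fit = fit_trend(series, 180)
        assert stability_uncertainty(fit, 0) == 0.0
        u180 = stability_uncertainty(fit, 180)
        assert u180 == pytest.approx(fit.se_b1 * 180)
        assert stability_uncertainty(fit, 360) == pytest.approx(2 * u180)
        with pytest.raises(ValueError):
            stability_uncertainty(fit, -1)

    def test_forced_arithmetic_example(self):
        fit = fit_trend(linear_series(-0.01), 180)
        fake = fit.__class__(b0=fit.b0, b1=fit.b1, se_b1=0.01,
                             s_res=fit.s_res, n=fit.n, df=fit.df,
                             mean_day=fit.mean_day, sxx_day=fit.sxx_day)
        assert stability_uncertainty(fake, 180) == pytest.approx(1.8)

    def test_band_contains_line_and_is_narrowest_at_mean_day(self):
        fit = fit_trend(linear_series(-0.02), 180)
        widths = []
        for day in (0, 60, fit.mean_day, 180, 240):
            lo, hi = prediction_band_point(fit, day)
            assert lo <= fit.b0 + fit.b1 * day <= hi
            widths.append((abs(day - fit.mean_day), hi - lo))
        widths.sort()
        assert all(w1 <= w2 + 1e-12 for (_, w1), (_, w2)
                   in zip(widths, widths[1:]))

    def test_band_coverage_of_new_observation(self):
        # a new measurement at day 90 falls inside the 95% band ~95%
        hits = 0
        n_rep = 2000
        sigma = 1.5
        rng = np.random.default_rng(99)
        for i in range(n_rep):
            cfg = SimulationConfig(seed=60_000 + i, drift_slope=-0.02,
                                   sigma_bb=0.0, sigma_r=sigma)
            fit = fit_trend(gen_stability(cfg, 120.0), 180)
            lo, hi = prediction_band_point(fit, 90.0, 0.95)
            new = 120.0 - 0.02 * 90.0 + rng.normal(0.0, sigma)
            hits += lo <= new <= hi
        assert hits / n_rep == pytest.approx(0.95, abs=0.02)


class TestShelfLife:
    def test_no_crossing_with_flat_trend_and_wide_limits(self):
        fit = fit_trend(linear_series(0.0), 180)
        est = estimate_shelf_life(fit, 50.0, 150.0, horizon=365.0)
        assert est.shelf_life_days is None
        assert est.u_sta_at(0.0) == 0.0

    def test_crossing_matches_quadratic_closed_form(self):
        fit = fit_trend(linear_series(-0.05), 180)
        est = estimate_shelf_life(fit, fit.b0 * 0.9, fit.b0 * 1.1,
                                  level=0.95, horizon=2000.0)
        # oracle: square the band equation and solve the quadratic
        tq = stats.t.ppf(0.975, fit.df)
        c2 = tq ** 2 * fit.s_res ** 2
        L = fit.b0 * 0.9
        # (b0 + b1 t - L)^2 = c2 (1 + 1/n + (t - m)^2 / sxx)
        a = fit.b1 ** 2 - c2 / fit.sxx_day
        b = (2 * fit.b1 * (fit.b0 - L)
             + 2 * c2 * fit.mean_day / fit.sxx_day)
        c = ((fit.b0 - L) ** 2
             - c2 * (1 + 1 / fit.n + fit.mean_day ** 2 / fit.sxx_day))
        roots = np.roots([a, b, c])
        valid = [r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 0]
        assert est.crossing_day_lower == pytest.approx(min(valid), abs=0.1)

    def test_shrinking_limits_never_delays_the_crossing(self):
        fit = fit_trend(linear_series(-0.05), 180)
        prev = None
        for pct in (0.15, 0.10, 0.05):
            est = estimate_shelf_life(fit, fit.b0 * (1 - pct),
                                      fit.b0 * (1 + pct), horizon=3000.0)
            day = est.shelf_life_days or math.inf
            if prev is not None:
                assert day <= prev + 0.11
            prev = day

    def test_limits_must_bracket_baseline(self):
        fit = fit_trend(linear_series(-0.05), 180)
        with pytest.raises(ValueError, match="bracket"):
            estimate_shelf_life(fit, fit.b0 + 1, fit.b0 + 10)

    def test_invariant_to_vial_relabeling_and_record_order(self):
        cfg = SimulationConfig(seed=11, drift_slope=-0.03)
        series = gen_stability(cfg, 120.0)
        fit = fit_trend(series, 180)
        shuffled = StabilitySeries(
            series.material_id,
            [(d, f"x{hash(v) % 97}", x)
             for d, v, x in reversed(series.records)])
        fit2 = fit_trend(shuffled, 180)
        est1 = estimate_shelf_life(fit, fit.b0 * 0.9, fit.b0 * 1.1)
        est2 = estimate_shelf_life(fit2, fit.b0 * 0.9, fit.b0 * 1.1)
        assert est1.shelf_life_days == pytest.approx(est2.shelf_life_days)


class TestStabilityTrendModel:
    def test_fit_collects_checkpoints_and_shelf_life(self):
        cfg = SimulationConfig(seed=21, drift_slope=-0.05)
        series = gen_stability(cfg, 120.0)
        res = StabilityTrend(series, limits_pct=10.0).fit()
        assert [c.day for c in res.checkpoints] == [60, 90, 120, 150, 180]
        assert res.shelf_life is not None
        summary = res.summary()
        assert list(summary.columns) == ["day", "t_cal", "t_critical",
                                         "interpretation"]

    def test_from_dataframe_matches_direct(self):
        cfg = SimulationConfig(seed=22)
        series = gen_stability(cfg, 120.0)
        res1 = StabilityTrend(series).fit()
        res2 = StabilityTrend.from_dataframe(series.to_frame()).fit()
        assert res1.final_fit.b1 == pytest.approx(res2.final_fit.b1)
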
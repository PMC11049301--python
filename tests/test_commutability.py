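"""Commutability: Deming fit, prediction band, verdicts, Tukey HSD."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from commutakit import (MaterialPoint, MatrixEffect, MeterModel,
                        PairedSampleSet, SimulationConfig,
                        characterize_materials, classify_commutability,
                        deming_fit, gen_material, gen_native_pairs,
                        paired_difference, prediction_band)
from commutakit.datasets import (EXAMPLE_REFERENCE_METHOD,
                                 example_material_points)


def pairs_from_xy(x, y):
    return PairedSampleSet([(f"s{i}", xi, yi)
                            for i, (xi, yi) in enumerate(zip(x, y))])


class TestDemingFit:
    def test_perfect_identity_for_any_lambda(self):
        pairs = pairs_from_xy([50, 100, 150, 200], [50, 100, 150, 200])
        for lam in (0.1, 1.0, 10.0):
            fit = deming_fit(pairs, lam)
            assert fit.slope == pytest.approx(1.0)
            assert fit.intercept == pytest.approx(0.0, abs=1e-9)
            assert fit.s_res == pytest.approx(0.0, abs=1e-9)

    def test_limiting_behaviours_of_the_error_ratio(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(60, 300, 25)
        y = 0.9 * x + 5 + rng.normal(0, 4, 25)
        pairs = pairs_from_xy(x, y)
        dx, dy = x - x.mean(), y - y.mean()
        s_xx, s_yy, s_xy = (dx**2).sum(), (dy**2).sum(), (dx*dy).sum()
        # all error assigned to y -> OLS of y on x
        assert deming_fit(pairs, 1e8).slope == pytest.approx(
            s_xy / s_xx, rel=1e-4)
        # all error assigned to x -> inverse regression
        assert deming_fit(pairs, 1e-8).slope == pytest.approx(
            s_yy / s_xy, rel=1e-4)

    def test_orthogonal_slope_matches_brute_force_minimizer(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(50, 250, 20)
        y = 1.1 * x - 8 + rng.normal(0, 6, 20)
        pairs = pairs_from_xy(x, y)
        fit = deming_fit(pairs, 1.0)

        def orthogonal_ssr(params):
            a, b = params
            return float(((y - a - b * x) ** 2).sum() / (1 + b * b))

        res = optimize.minimize(orthogonal_ssr, x0=[0.0, 1.0],
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.slope == pytest.approx(res.x[1], abs=1e-6)
        assert fit.intercept == pytest.approx(res.x[0], abs=1e-4)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(60, 300, 15)
        y = 0.95 * x + rng.normal(0, 3, 15)
        f1 = deming_fit(pairs_from_xy(x, y))
        f2 = deming_fit(pairs_from_xy(3.5 * x, 3.5 * y))
        assert f2.slope == pytest.approx(f1.slope)
        assert f2.intercept == pytest.approx(3.5 * f1.intercept)
        assert f2.s_res == pytest.approx(3.5 * f1.s_res)

    def test_swapping_axes_inverts_the_line(self):
        rng = np.random.default_rng(29)
        x = rng.uniform(60, 300, 15)
        y = 0.9 * x + 4 + rng.normal(0, 2, 15)
        f = deming_fit(pairs_from_xy(x, y), lambda_=2.0)
        g = deming_fit(pairs_from_xy(y, x), lambda_=0.5)
        assert g.slope == pytest.approx(1 / f.slope, rel=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="3 pairs"):
            deming_fit(pairs_from_xy([100, 110], [100, 110]))
        with pytest.raises(ValueError, match="vertical"):
            deming_fit(pairs_from_xy([100, 100, 100], [90, 100, 110]))


class TestPredictionBand:
    @pytest.fixture
    def noisy_fit(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(60, 300, 30)
        y = x + rng.normal(0, 5, 30)
        return deming_fit(pairs_from_xy(x, y))

    def test_band_contains_fitted_line(self, noisy_fit):
        for x0 in (60, 120, 200, 300):
            lo, hi = prediction_band(noisy_fit, x0)
            assert lo <= noisy_fit.predict(x0) <= hi

    def test_band_narrowest_at_mean_x(self, noisy_fit):
        w = lambda x0: np.subtract(*prediction_band(noisy_fit, x0)[::-1])
        assert w(noisy_fit.mean_x) <= w(noisy_fit.mean_x + 50)
        assert w(noisy_fit.mean_x) <= w(noisy_fit.mean_x - 50)


class TestClassification:
    @pytest.fixture
    def fit(self):
        cfg = SimulationConfig(seed=41)
        meter = MeterModel("m", slope=1.0, cv_prop=0.02)
        return deming_fit(gen_native_pairs(cfg, meter))

    def test_point_on_line_is_commutable(self, fit):
        x0 = 150.0
        m = MaterialPoint("M", x_mean=x0, x_sd=1.0,
                          y_mean=fit.predict(x0), y_sd=1.0)
        assert classify_commutability(fit, m).commutable

    def test_band_boundary_is_inclusive(self, fit):
        x0 = 150.0
        _, upper = prediction_band(fit, x0)
        on = MaterialPoint("M", x_mean=x0, x_sd=0, y_mean=upper, y_sd=0)
        above = MaterialPoint("M", x_mean=x0, x_sd=0,
                              y_mean=upper + 0.001, y_sd=0)
        assert classify_commutability(fit, on).commutable
        assert not classify_commutability(fit, above).commutable

    def test_large_matrix_offset_is_non_commutable(self, fit):
        cfg = SimulationConfig(seed=43)
        meter = MeterModel("m", slope=1.0, cv_prop=0.02)
        mat = gen_material(cfg, meter, MatrixEffect("additive", 30.0),
                           150.0, n_rep=10)
        verdict = classify_commutability(fit, mat)
        lo, hi = prediction_band(fit, mat.x_mean)
        assert hi - lo < 2 * 30  # offset exceeds the band half-width
        assert not verdict.commutable
        assert verdict.band_lower == pytest.approx(lo)

    def test_verdict_invariant_to_sample_order(self):
        cfg = SimulationConfig(seed=47)
        meter = MeterModel("m", slope=0.95, cv_prop=0.02)
        pairs = gen_native_pairs(cfg, meter)
        shuffled = PairedSampleSet(list(reversed(pairs.samples)))
        mat = gen_material(cfg, meter, MatrixEffect("additive", 0.0),
                           140.0, n_rep=5)
        v1 = classify_commutability(deming_fit(pairs), mat)
        v2 = classify_commutability(deming_fit(shuffled), mat)
        assert v1.commutable == v2.commutable
        assert v1.band_lower == pytest.approx(v2.band_lower)


class TestPairedDifference:
    def test_example_characterisation_differences(self):
        # printed means: reference 106 vs meters 71 and 92
        m71 = MaterialPoint("B2", x_mean=106, x_sd=1.4, y_mean=71, y_sd=2.7)
        m92 = MaterialPoint("B2", x_mean=106, x_sd=1.4, y_mean=92, y_sd=1.2)
        assert paired_difference(m71)[0] == pytest.approx(-35)
        assert paired_difference(m92)[0] == pytest.approx(-14)
        assert not paired_difference(m71)[2]

    def test_identical_means_are_compatible(self):
        m = MaterialPoint("M", x_mean=120, x_sd=1, y_mean=120, y_sd=1)
        diff, pct, ok = paired_difference(m)
        assert (diff, pct, ok) == (0.0, 0.0, True)

    def test_denominator_selection(self):
        m = MaterialPoint("M", x_mean=100, x_sd=1, y_mean=80, y_sd=1)
        assert paired_difference(m, "reference")[1] == pytest.approx(20.0)
        assert paired_difference(m, "meter")[1] == pytest.approx(25.0)
        with pytest.raises(ValueError):
            paired_difference(m, "bogus")


def studentized_range_sf_oracle(q, k, df):
    """Tail of the studentized range by direct numerical integration."""
    def inner(s):
        def f(z):
            return (stats.norm.pdf(z)
                    * (stats.norm.cdf(z) - stats.norm.cdf(z - q * s))
                    ** (k - 1))
        val, _ = integrate.quad(f, -8, 8, limit=200)
        return k * val

    # density of s = sqrt(chi2_df / df)
    log_norm = (df / 2) * math.log(df / 2) - math.lgamma(df / 2)

    def outer(s):
        log_dens = (log_norm + (df - 1) * math.log(s) - df * s * s / 2
                    + math.log(2))
        return math.exp(log_dens) * inner(s)

    cdf, _ = integrate.quad(outer, 1e-6, 8, limit=200)
    return 1.0 - cdf


class TestCharacterization:
    def toy_frame(self):
        import pandas as pd
        rng = np.random.default_rng(53)
        rows = []
        for meth, bias in [("ref", 0.0), ("m1", 2.0), ("m2", -4.0)]:
            for mat, level in [("A", 100.0), ("B", 150.0)]:
                for r in range(4):
                    rows.append({"material_id": mat, "method": meth,
                                 "value": level + bias
                                 + rng.normal(0, 1.5)})
        return pd.DataFrame(rows)

    def test_identical_methods_give_tukey_p_near_one(self):
        reps = {"ref": {"A": [100, 101, 99], "B": [150, 151, 149]},
                "dup": {"A": [100, 101, 99], "B": [150, 151, 149]}}
        _, tukey = characterize_materials(reps, "ref")
        assert tukey[("dup", "ref")] >= 0.99

    def test_cell_means_and_sds_match_hand_arithmetic(self):
        reps = {"ref": {"A": [99, 101, 100], "B": [148, 152, 150]},
                "m1": {"A": [102, 104, 103], "B": [155, 157, 156]}}
        table, _ = characterize_materials(reps, "ref")
        row = table.set_index(["method", "material_id"])
        assert row.loc[("m1", "A"), "mean"] == pytest.approx(103.0)
        assert row.loc[("m1", "A"), "sd"] == pytest.approx(1.0)
        assert row.loc[("ref", "B"), "mean"] == pytest.approx(150.0)

    def test_tukey_p_matches_numerical_integration_oracle(self):
        df = self.toy_frame()
        _, tukey = characterize_materials(df, "ref")
        import statsmodels.formula.api as smf
        model = smf.ols("value ~ C(method) + C(material_id)",
                        data=df).fit()
        mse, dfr = model.mse_resid, int(model.df_resid)
        means = df.groupby("method")["value"].mean()
        n_per = df.groupby("method")["value"].count()
        for meth in ("m1", "m2"):
            q = abs(means[meth] - means["ref"]) / math.sqrt(
                mse / n_per[meth])
            expected = studentized_range_sf_oracle(q, 3, dfr)
            assert tukey[(meth, "ref")] == pytest.approx(expected,
                                                         abs=1e-4)

    def test_single_replicate_cell_raises(self):
        reps = {"ref": {"A": [100.0]}, "m1": {"A": [101, 102]}}
        with pytest.raises(ValueError, match="single replicate"):
            characterize_materials(reps, "ref")


class TestExampleDataset:
    def test_ten_method_material_pairs_ship(self):
        points = example_material_points()
        assert len(points) == 5
        assert all(len(v) == 2 for v in points.values())
        assert EXAMPLE_REFERENCE_METHOD not in points
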
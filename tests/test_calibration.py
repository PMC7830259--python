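"""Calibration-curve fitting, pooling F test, LOD/LOQ and assay summaries."""

import numpy as np
import pandas as pd
import pytest

from cmskinetics import (
    CSA_MASS_FRACTION,
    CalibrationModel,
    accuracy_precision,
    default_calibration_truth,
    fit_calibration,
    indirect_cms,
    lod_loq,
    partition_cs,
    pool_curves_f_test,
)

CSA_LEVELS = [1.806, 2.408, 3.612, 4.816, 6.02, 6.622]


def csa_points(noise_sd=0.0, seed=0, levels=CSA_LEVELS, slope=130.1, intercept=-195.3):
    rng = np.random.default_rng(seed)
    x = np.asarray(levels)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, x.size)
    return list(zip(x, y))


class TestFitCalibration:
    def test_exact_linear_recovery(self):
        curve = fit_calibration(csa_points(), order=1, analyte="CSA")
        assert curve.coefficients[0] == pytest.approx(-195.3, rel=1e-9)
        assert curve.coefficients[1] == pytest.approx(130.1, rel=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_quadratic_recovery(self):
        truth = default_calibration_truth("CMS")
        levels = [2.0, 6.0, 8.0, 12.0, 16.0, 20.0, 22.0]
        pts = [(x, truth.predict(x)) for x in levels]
        curve = fit_calibration(pts, order=2, analyte="CMS")
        np.testing.assert_allclose(
            curve.coefficients, [131.6, 20.97, 1.425], rtol=1e-9
        )

    def test_misspecified_order_shows_curvature(self):
        truth = default_calibration_truth("CMS")
        levels = np.array([2.0, 6.0, 8.0, 12.0, 16.0, 20.0, 22.0])
        pts = [(x, truth.predict(x)) for x in levels]
        curve = fit_calibration(pts, order=1)
        assert curve.r_squared < 1.0 - 1e-6
        resid = np.array([y - curve.predict(x) for x, y in pts])
        # convex truth under a straight line: ends above, middle below
        assert resid[0] > 0 and resid[-1] > 0 and np.any(resid[2:5] < 0)

    def test_standard_errors_match_statsmodels(self):
        """Independent cross-check of the coefficient covariance."""
        sm = pytest.importorskip("statsmodels.api")
        pts = csa_points(noise_sd=20.0, seed=11)
        x, y = map(np.asarray, zip(*pts))
        curve = fit_calibration(pts, order=1)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(curve.coefficients, ols.params, rtol=1e-10)
        np.testing.assert_allclose(curve.standard_errors, ols.bse, rtol=1e-10)
        assert curve.r_squared == pytest.approx(ols.rsquared, rel=1e-10)

    def test_standard_errors_calibrated_against_monte_carlo(self):
        """Reported SEs track the sampling SD over 500 simulated curves."""
        coefs, ses = [], []
        for seed in range(500):
            curve = fit_calibration(csa_points(noise_sd=20.0, seed=seed), order=1)
            coefs.append(curve.coefficients)
            ses.append(curve.standard_errors)
        mc_sd = np.std(coefs, axis=0, ddof=1)
        np.testing.assert_allclose(np.mean(ses, axis=0), mc_sd, rtol=0.2)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank-deficient|distinct"):
            CalibrationModel([5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0], order=1)

    def test_invert_round_trip_linear(self):
        curve = fit_calibration(csa_points(), order=1)
        assert curve.invert(130.1 * 5.0 - 195.3) == pytest.approx(5.0, rel=1e-9)

    def test_invert_round_trip_quadratic(self):
        truth = default_calibration_truth("CMS")
        for x in (2.0, 8.0, 16.0, 22.0):
            assert truth.invert(truth.predict(x)) == pytest.approx(x, rel=1e-9)

    def test_invert_out_of_range_rejected(self):
        curve = fit_calibration(csa_points(), order=1)
        with pytest.raises(ValueError, match="outside|ambiguous"):
            curve.invert(curve.predict(0.5))


class TestPoolCurvesFTest:
    def test_identical_replicates_give_zero_F(self):
        reps = [csa_points(noise_sd=5.0, seed=9)] * 3
        res = pool_curves_f_test(reps, order=1)
        assert res.F == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-8)
        assert not res.curves_differ

    def test_nesting_inequality(self):
        reps = [csa_points(noise_sd=20.0, seed=s) for s in (1, 2, 3)]
        res = pool_curves_f_test(reps, order=1)
        assert res.sse_pooled >= res.sse_separate - 1e-9

    def test_null_behavior(self):
        """Replicates of one true curve pool successfully (p > 0.05) in at
        least 90% of 200 simulations."""
        keep = 0
        for sim in range(200):
            reps = [
                csa_points(noise_sd=20.0, seed=1000 + 3 * sim + r) for r in range(3)
            ]
            if pool_curves_f_test(reps, order=1).p_value > 0.05:
                keep += 1
        assert keep >= 180

    def test_power_against_shifted_slopes(self):
        """Slopes 5 published-SE apart are detected (p < 0.05) in at least
        90% of simulations."""
        reject = 0
        for sim in range(100):
            reps = [
                csa_points(
                    noise_sd=20.0,
                    seed=5000 + 3 * sim + r,
                    slope=130.1 + (r - 1) * 5 * 2.6,
                )
                for r in range(3)
            ]
            if pool_curves_f_test(reps, order=1).p_value < 0.05:
                reject += 1
        assert reject >= 90

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            pool_curves_f_test([csa_points()], order=1)


class TestLodLoq:
    def test_ratio_reproduces_published_csa_loq(self):
        # sigma chosen so LOD is the published 0.29 ug/mL; LOQ follows as 0.88
        sigma = 0.29 * 130.1 / 3.3
        lod, loq = lod_loq(sigma, 130.1)
        assert round(lod, 2) == 0.29
        assert round(loq, 2) == 0.88

    def test_zero_sigma(self):
        assert lod_loq(0.0, 130.1) == (0.0, 0.0)

    def test_direct_arithmetic(self):
        lod, loq = lod_loq(1.0, 10.0)
        assert lod == pytest.approx(0.33)
        assert loq == pytest.approx(1.0)

    def test_ratio_invariant(self):
        for sigma, slope in [(0.5, 3.0), (12.0, 130.1), (7.0, 21.0)]:
            lod, loq = lod_loq(sigma, slope)
            assert loq / lod == pytest.approx(10.0 / 3.3, rel=1e-12)

    def test_bad_slope(self):
        with pytest.raises(ValueError):
            lod_loq(1.0, 0.0)


class TestPartitionAndIndirect:
    @pytest.mark.parametrize(
        "total, csa, csb",
        [(22.0, 6.622, 15.378), (16.0, 4.816, 11.184), (0.0, 0.0, 0.0)],
    )
    def test_reference_split(self, total, csa, csb):
        a, b = partition_cs(total)
        assert a == pytest.approx(csa, abs=1e-9)
        assert b == pytest.approx(csb, abs=1e-9)
        assert a + b == total  # exact mass conservation

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            partition_cs(10.0, csa_fraction=1.0)

    def test_default_fraction_is_reference_standard(self):
        assert CSA_MASS_FRACTION == 0.301

    def test_indirect_cms_difference(self):
        assert indirect_cms(10.0, 4.0) == (6.0, False)
        assert indirect_cms(10.0, 10.0) == (0.0, False)

    def test_indirect_cms_caveat_flag(self):
        cms, caveat = indirect_cms(10.0, 4.0, hydrolysis_complete=False)
        assert cms == 6.0 and caveat

    def test_negative_cms_rejected(self):
        with pytest.raises(ValueError, match="inconsistency"):
            indirect_cms(10.0, 11.0)


class TestAccuracyPrecision:
    @staticmethod
    def table(noise_cv, seed, levels=(2.0, 6.0, 8.0), runs=3, reps=3):
        rng = np.random.default_rng(seed)
        rows = [
            {"level": lev, "run": run, "value": lev * (1 + rng.normal(0, noise_cv))}
            for lev in levels
            for run in range(runs)
            for _ in range(reps)
        ]
        return pd.DataFrame(rows), {lev: lev for lev in levels}

    def test_perfect_measurements(self):
        df, nominal = self.table(0.0, 0)
        vs = accuracy_precision(df, nominal)
        assert (vs.table["pct_error"] == 0).all()
        assert (vs.table["repeatability_rsd"] == 0).all()
        assert (vs.table["intermediate_rsd"] == 0).all()

    def test_two_percent_noise_band(self):
        """With 2% measurement CV the within-run %RSD lands in the
        0.5-5% band typical of the validated assay."""
        df, nominal = self.table(0.02, 7)
        vs = accuracy_precision(df, nominal)
        assert vs.table["repeatability_rsd"].between(0.5, 5.0).all()
        assert (vs.table["pct_error"] < 5.0).all()
        assert vs.sigma > 0

    def test_single_replicate_reports_missing_not_zero(self):
        df = pd.DataFrame(
            [{"level": 2.0, "run": 0, "value": 2.1},
             {"level": 2.0, "run": 1, "value": 1.9}]
        )
        vs = accuracy_precision(df, {2.0: 2.0})
        assert np.isnan(vs.table["repeatability_rsd"]).all()
        assert np.isfinite(vs.table["intermediate_rsd"]).all()

    def test_zero_nominal_rejected(self):
        df, _ = self.table(0.01, 1)
        with pytest.raises(ValueError, match="nominal"):
            accuracy_precision(df, {2.0: 0.0, 6.0: 6.0, 8.0: 8.0})
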
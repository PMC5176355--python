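"""Growth-rate extraction, abundance-fitness branches, rescue and rank stats."""

import warnings

import numpy as np
import pytest

from gdtox.growth import (
    FitnessPoint,
    GrowthCurve,
    RescueMeasurement,
    fit_depletion_branch,
    fit_growth_curve,
    fit_overexpression_branch,
    ortholog_significance,
    rank_correlation,
    relative_growth,
    rescue_factor,
)
from gdtox.synthdata import gen_fitness_curve, gen_growth_curves


class TestGompertzFit:
    def test_noiseless_recovery(self):
        curve, _ = gen_growth_curves(mu=0.6, lag=1.0, amplitude=2.0, noise_cv=0.0, seed=0)
        p = fit_growth_curve(curve)
        assert p.mu_max == pytest.approx(0.6, rel=1e-4)
        assert p.lag == pytest.approx(1.0, rel=1e-3)
        assert p.amplitude == pytest.approx(2.0, rel=1e-4)

    def test_constant_od_reports_zero_growth(self):
        t = np.arange(0, 721, 15.0)
        with pytest.warns(UserWarning):
            p = fit_growth_curve(GrowthCurve(t, np.full_like(t, 0.05), "flat"))
        assert p.mu_max == 0.0
        assert p.flat

    def test_recovery_under_noise(self):
        mus = []
        for seed in range(100):
            curve, _ = gen_growth_curves(mu=0.6, noise_cv=0.01, seed=seed)
            mus.append(fit_growth_curve(curve).mu_max)
        assert np.median(mus) == pytest.approx(0.6, rel=0.02)

    @pytest.mark.parametrize("mu", [0.1, 0.5, 1.0, 1.5])
    def test_recovery_across_growth_rates(self, mu):
        vals = []
        for seed in range(20):
            curve, _ = gen_growth_curves(mu=mu, lag=0.5, noise_cv=0.01, seed=seed)
            vals.append(fit_growth_curve(curve).mu_max)
        assert np.median(vals) == pytest.approx(mu, rel=0.02)

    def test_blank_subtraction_changes_baseline_only(self):
        curve, _ = gen_growth_curves(mu=0.6, od0=0.10, noise_cv=0.0, seed=0)
        shifted = GrowthCurve(curve.time, curve.od600 + 0.04, curve.label)
        p = fit_growth_curve(shifted, blank=0.04)
        assert p.mu_max == pytest.approx(0.6, rel=1e-3)


class TestRelativeGrowth:
    def test_basic_ratios(self):
        assert relative_growth(0.5, 0.5) == 1.0
        assert relative_growth(0.0, 0.5) == 0.0
        # 73% maximal reduction regime: mu = 0.27 of reference
        assert relative_growth(0.27, 1.0) == pytest.approx(0.27)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_growth(0.5, 0.0)


class TestFitnessBranches:
    def test_depletion_noiseless_recovery(self):
        a = np.logspace(-2, 0, 8)
        pts = [FitnessPoint(x, 1.0 * x / (x + 0.05)) for x in a]
        fit = fit_depletion_branch(pts)
        assert fit.f_max == pytest.approx(1.0, rel=1e-6)
        assert fit.k_f == pytest.approx(0.05, rel=1e-6)
        assert float(fit.predict(fit.k_f)) == pytest.approx(fit.f_max / 2.0, rel=1e-9)

    def test_depletion_recovery_under_noise(self):
        fmax, kf = [], []
        for seed in range(50):
            pts, gt = gen_fitness_curve("depletion", n_points=8, sd=0.03, seed=seed)
            fit = fit_depletion_branch(pts)
            fmax.append(fit.f_max)
            kf.append(fit.k_f)
        assert np.median(fmax) == pytest.approx(1.0, rel=0.10)
        assert np.median(kf) == pytest.approx(0.05, rel=0.10)

    def test_overexpression_noiseless_recovery(self):
        pts, gt = gen_fitness_curve("overexpression", n_points=9, sd=0.0, seed=0)
        fit = fit_overexpression_branch(pts)
        assert fit.bottom == pytest.approx(gt.params["bottom"], abs=1e-4)
        assert fit.top == pytest.approx(gt.params["top"], abs=1e-4)
        assert fit.log10_mid == pytest.approx(gt.params["log10_mid"], abs=1e-4)

    def test_overexpression_midpoint_prediction(self):
        pts, _ = gen_fitness_curve("overexpression", n_points=9, sd=0.0, seed=0)
        fit = fit_overexpression_branch(pts)
        mid = float(fit.predict(10.0**fit.log10_mid))
        assert mid == pytest.approx((fit.top + fit.bottom) / 2.0, rel=1e-9)

    def test_monotone_series_has_perfect_negative_rank_correlation(self):
        pts, _ = gen_fitness_curve("overexpression", n_points=6, sd=0.0, seed=0)
        rho, _ = rank_correlation(pts)
        assert rho == pytest.approx(-1.0)


class TestOrthologSignificance:
    def _fit(self):
        pts, _ = gen_fitness_curve("overexpression", n_points=9, sd=0.0, seed=0)
        return fit_overexpression_branch(pts)

    def test_replicates_at_prediction_are_not_significant(self):
        # observed replicates sitting on the curve should rarely reject; the
        # comparison sample is stochastic, so aggregate over draws
        fit = self._fit()
        pred = float(fit.predict(100.0))
        reps = [pred * 0.999, pred, pred * 1.001]
        pvals = [ortholog_significance(fit, 100.0, reps, rng=s) for s in range(200)]
        assert np.median(pvals) > 0.25
        assert np.mean(np.asarray(pvals) < 0.05) < 0.15

    def test_far_replicates_are_highly_significant(self):
        fit = self._fit()
        pred = float(fit.predict(100.0))
        sd = 0.03 * pred
        reps = [pred + 20 * sd, pred + 20.5 * sd, pred + 19.5 * sd]
        p = ortholog_significance(fit, 100.0, reps, rng=1)
        assert p < 0.001

    def test_type_i_error_calibration(self):
        fit = self._fit()
        pred = float(fit.predict(100.0))
        rng = np.random.default_rng(2024)
        rejections = 0
        trials = 2000
        for _ in range(trials):
            reps = rng.normal(pred, 0.03 * pred, size=3)
            if ortholog_significance(fit, 100.0, reps, rng=rng) < 0.05:
                rejections += 1
        assert abs(rejections / trials - 0.05) <= 0.02

    def test_extrapolation_warns(self):
        fit = self._fit()
        with pytest.warns(UserWarning):
            ortholog_significance(fit, 1e6, [0.3, 0.31, 0.29], rng=0)


class TestRescueFactor:
    def test_all_equal_rates_give_zero(self):
        assert rescue_factor(RescueMeasurement(0.5, 0.5, 0.5, 0.5)) == 0.0

    def test_worked_arithmetic(self):
        assert rescue_factor(RescueMeasurement(0.50, 0.40, 0.95, 1.00)) == pytest.approx(0.15)

    def test_pure_toxicity_correction(self):
        # X is itself toxic but does not interact with the hub
        assert rescue_factor(RescueMeasurement(0.40, 0.40, 0.90, 1.00)) == pytest.approx(0.10)

    def test_invariant_under_constant_shift(self):
        m = RescueMeasurement(0.5, 0.4, 0.95, 1.0)
        shifted = RescueMeasurement(0.7, 0.6, 1.15, 1.2)
        assert rescue_factor(m) == pytest.approx(rescue_factor(shifted))


class TestRankCorrelation:
    def test_five_point_monotone_exact_two_sided_p(self):
        # strictly decreasing 5-point series: |rho| = 1 occurs for exactly 2
        # of the 120 rank orderings, so the exact two-sided p is 2/120
        x = [1.0, 2.0, 4.0, 8.0, 16.0]
        y = [1.0, 0.9, 0.7, 0.5, 0.3]
        rho, p = rank_correlation((x, y))
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2.0 / 120.0, rel=1e-9)
        assert round(p, 4) == 0.0167

    def test_six_point_monotone_exact_p(self):
        x = list(range(1, 7))
        y = [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]
        rho, p2 = rank_correlation((x, y), alternative="two-sided")
        _, p1 = rank_correlation((x, y), alternative="less")
        assert rho == pytest.approx(-1.0)
        assert p2 == pytest.approx(2.0 / 720.0, rel=1e-9)
        assert p1 == pytest.approx(1.0 / 720.0, rel=1e-9)

    def test_constant_values_return_zero_with_warning(self):
        with pytest.warns(UserWarning):
            rho, p = rank_correlation(([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0]))
        assert rho == 0.0

    def test_permutation_null_p_is_uniform(self):
        # under random orderings the exact p-value must be (super)uniform
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(2000):
            y = rng.permutation(6).astype(float)
            _, p = rank_correlation((np.arange(6.0), y))
            pvals.append(p)
        pvals = np.asarray(pvals)
        for alpha in (0.05, 0.2, 0.5):
            assert np.mean(pvals <= alpha) <= alpha + 0.03
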
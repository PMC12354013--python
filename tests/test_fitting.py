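"""Fitting round-trips, residual diagnostics, the model-selection ladder."""

import numpy as np
import pytest

from acylnmr import (
    BiExpParams,
    KineticModelSelector,
    MonoExpParams,
    ProgressCurve,
    ProgressCurveFitter,
    SiteRateProfile,
    add_noise,
    aggregate_curve,
    amplitude_fraction,
    compare_fits,
    eval_mono_exp,
    fit_progress_curve,
    initialize_parameters,
    residual_diagnostics,
    select_model,
)
from acylnmr.fitting import runs_test_pvalue
from acylnmr import constants as C


class TestInitializer:
    def test_mono_init_near_truth_on_clean_curve(self, schedule):
        t = schedule.times()
        curve = ProgressCurve(times=t, intensities=eval_mono_exp(MonoExpParams(1.0, 0.03), t))
        init = initialize_parameters(curve, "mono")
        assert init.i_max == pytest.approx(1.0, rel=0.05)
        assert init.k == pytest.approx(0.03, rel=0.5)

    def test_constant_zero_curve_uses_fallback(self, schedule):
        t = schedule.times()
        curve = ProgressCurve(times=t, intensities=np.zeros(len(t)))
        init = initialize_parameters(curve, "mono")
        assert init.k == pytest.approx(1.0 / np.median(t))

    def test_bi_init_amplitude_near_curve_max(self, biexp_curve):
        init = initialize_parameters(biexp_curve, "bi")
        assert init.a1 + init.a2 == pytest.approx(np.max(biexp_curve.intensities), rel=0.10)

    def test_too_few_points_rejected(self):
        curve = ProgressCurve(times=np.array([1.0, 2.0, 3.0]), intensities=np.zeros(3))
        with pytest.raises(ValueError, match="mono"):
            initialize_parameters(curve, "mono")


class TestFitRoundTrips:
    def test_mono_recovery_from_equal_rate_aggregate(self, equal_rate_profile, schedule):
        curve = aggregate_curve(equal_rate_profile, schedule)
        fit = fit_progress_curve(curve, "mono")
        assert fit.converged
        assert fit.params.k == pytest.approx(C.ACETYL_MONO_K["p300"], rel=1e-6)
        assert fit.params.i_max == pytest.approx(5.0, rel=1e-6)

    def test_bi_recovery_from_two_class_aggregate(self, biexp_curve):
        fit = fit_progress_curve(biexp_curve, "bi")
        k1, k2 = C.ACETYL_BI_K["p300d"]
        assert fit.params.k1 == pytest.approx(k1, rel=1e-6)
        assert fit.params.k2 == pytest.approx(k2, rel=1e-6)
        assert amplitude_fraction(fit.params) == pytest.approx((0.6, 0.4), rel=1e-6)

    def test_lagged_recovery(self, lagged_curve):
        curve, truth = lagged_curve
        fit = fit_progress_curve(curve, "lagged")
        assert fit.params.k == pytest.approx(truth.k, rel=1e-4)
        assert fit.params.t0 == pytest.approx(truth.t0, rel=1e-4)

    def test_rescaling_invariance(self, biexp_curve):
        fit1 = fit_progress_curve(biexp_curve, "bi")
        scaled = biexp_curve.with_intensities(biexp_curve.intensities * 137.0)
        fit2 = fit_progress_curve(scaled, "bi")
        assert fit2.params.k1 == pytest.approx(fit1.params.k1, rel=1e-8)
        assert fit2.params.k2 == pytest.approx(fit1.params.k2, rel=1e-8)
        assert fit2.params.a1 == pytest.approx(137.0 * fit1.params.a1, rel=1e-8)

    def test_nan_intensities_rejected(self, schedule):
        t = schedule.times()
        y = np.ones(len(t))
        y[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit_progress_curve(ProgressCurve(times=t, intensities=y), "mono")

    def test_generating_model_r2_dominates(self, biexp_curve):
        bi = fit_progress_curve(biexp_curve, "bi")
        mono = fit_progress_curve(biexp_curve, "mono")
        assert bi.r_squared >= mono.r_squared
        assert bi.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_noisy_mono_recovery_median_error(self, equal_rate_profile, schedule):
        # sigma = 2% of asymptote, 100 seeded replicates
        clean = aggregate_curve(equal_rate_profile, schedule)
        errs = []
        for seed in range(100):
            noisy = add_noise(clean, 0.02, seed=seed)
            fit = fit_progress_curve(noisy, "mono")
            errs.append(abs(fit.params.k - C.ACETYL_MONO_K["p300"]) / C.ACETYL_MONO_K["p300"])
        assert np.median(errs) <= 0.05


class TestEstimatorInterface:
    def test_fit_predict_round_trip(self, biexp_curve):
        est = ProgressCurveFitter(model="bi").fit(biexp_curve.times, biexp_curve.intensities)
        np.testing.assert_allclose(est.predict(biexp_curve.times), biexp_curve.intensities, atol=1e-8)
        assert est.r_squared_ == pytest.approx(1.0, abs=1e-10)

    def test_get_set_params(self):
        est = ProgressCurveFitter()
        assert est.get_params()["model"] == "mono"
        est.set_params(model="lagged")
        assert est.model == "lagged"

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError):
            ProgressCurveFitter().predict([1.0, 2.0])

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = KineticModelSelector(runs_alpha=0.01)
        assert clone(est).get_params()["runs_alpha"] == 0.01


class TestDiagnostics:
    def test_runs_test_against_statsmodels(self):
        from statsmodels.sandbox.stats.runs import runstest_1samp

        rng = np.random.default_rng(0)
        for _ in range(5):
            signs = rng.choice([-1.0, 1.0], size=60)
            p_ours, _ = runs_test_pvalue(signs)
            z_sm, _ = runstest_1samp(signs, cutoff=0, correction=False)
            # ours is the lower-tail (too-few-runs) probability of the same z
            from scipy.stats import norm

            assert p_ours == pytest.approx(norm.cdf(z_sm), abs=1e-8)

    def test_mono_fit_to_biexp_curve_is_systematic(self, biexp_curve):
        # underestimates then overestimates: the residual signature of two rate classes
        fit = fit_progress_curve(biexp_curve, "mono")
        diag = residual_diagnostics(fit, biexp_curve)
        assert diag.systematic

    def test_alternating_residuals_not_systematic(self, schedule):
        t = schedule.times()
        curve = ProgressCurve(times=t, intensities=np.ones(len(t)))
        fit = fit_progress_curve(curve, "mono")
        fit.residuals = np.resize([0.01, -0.01], len(t))
        diag = residual_diagnostics(fit, curve)
        assert diag.runs_test_p > 0.5
        assert not diag.systematic

    def test_perfect_fit_not_systematic(self, equal_rate_profile, schedule):
        curve = aggregate_curve(equal_rate_profile, schedule)
        fit = fit_progress_curve(curve, "mono")
        diag = residual_diagnostics(fit, curve)
        assert not diag.systematic

    def test_length_mismatch_rejected(self, biexp_curve, schedule):
        fit = fit_progress_curve(biexp_curve, "mono")
        short = ProgressCurve(times=biexp_curve.times[:5], intensities=biexp_curve.intensities[:5])
        with pytest.raises(ValueError):
            residual_diagnostics(fit, short)


class TestModelSelection:
    def test_two_class_acetylation_selects_bi(self, biexp_curve):
        sel = select_model(biexp_curve)
        assert sel.chosen == "bi"
        assert sel.rationale

    def test_lag_phase_propionylation_selects_lagged(self, lagged_curve):
        curve, _ = lagged_curve
        sel = select_model(curve)
        assert sel.chosen == "lagged"

    def test_clean_single_rate_selects_mono(self, equal_rate_profile, schedule):
        curve = aggregate_curve(equal_rate_profile, schedule)
        noisy = add_noise(curve, 0.02, seed=42)
        sel = select_model(noisy)
        assert sel.chosen == "mono"

    def test_lagged_bi_probe_never_auto_selected_without_big_gain(self, lagged_curve):
        curve, _ = lagged_curve
        sel = select_model(curve, probe_lagged_bi=True)
        assert sel.chosen == "lagged"
        assert "lagged_bi" in sel.fits


class TestCompareFits:
    def test_bi_preferred_on_biexp_data(self, biexp_curve):
        mono = fit_progress_curve(biexp_curve, "mono")
        bi = fit_progress_curve(biexp_curve, "bi")
        out = compare_fits(mono, bi)
        assert out["preferred"] == "bi"
        assert out["delta_r_squared"] < 0

    def test_lagged_preferred_on_lagged_data(self, lagged_curve):
        curve, _ = lagged_curve
        bi = fit_progress_curve(curve, "bi")
        lag = fit_progress_curve(curve, "lagged")
        assert compare_fits(bi, lag)["preferred"] == "lagged"

    def test_exact_tie_prefers_fewer_parameters(self, biexp_curve):
        mono = fit_progress_curve(biexp_curve, "mono")
        other = fit_progress_curve(biexp_curve, "bi")
        other.aic_c = mono.aic_c  # forced tie
        assert compare_fits(mono, other)["preferred"] == "mono"

    def test_aicc_penalizes_redundant_parameters(self, equal_rate_profile, schedule):
        # mono and bi fit an equal-rate aggregate equally well; AICc must favor mono
        curve = add_noise(aggregate_curve(equal_rate_profile, schedule), 0.01, seed=3)
        mono = fit_progress_curve(curve, "mono")
        bi = fit_progress_curve(curve, "bi")
        assert mono.aic_c < bi.aic_c

    def test_length_mismatch_rejected(self, biexp_curve, lagged_curve):
        curve, _ = lagged_curve
        a = fit_progress_curve(biexp_curve, "mono")
        b = fit_progress_curve(
            ProgressCurve(times=curve.times[:10], intensities=curve.intensities[:10]), "mono"
        )
        with pytest.raises(ValueError):
            compare_fits(a, b)
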
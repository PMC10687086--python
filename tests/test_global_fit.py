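"""Global progress-curve fitting: objective, recovery, nuisance handling."""

import numpy as np
import pytest

import lucikin as lk
from lucikin.errors import ConfigError, DomainError
from lucikin.global_fit import FitOptions, FitProblem
from lucikin.signal_model import apply_scaling


def _study(params, noise, replicates=1, read_interval=2.0, seed_tag="wt|CTZ",
           jitter=0.0, max_duration=1000.0, **kw):
    variant, luciferin = seed_tag.split("|")
    return lk.generate_study(
        [lk.StudyEntry(variant, luciferin, params, scaling_f=1e6)],
        design=lk.SeriesDesign(replicates=replicates),
        noise=noise, E0=0.01, read_interval_s=read_interval,
        jitter_fraction=jitter, max_duration_s=max_duration, **kw,
    )


class TestChiSquared:
    def test_zero_at_generating_parameters(self, noiseless_wt_ctz_study, wt_ctz):
        ds = lk.datasets_from_traces(noiseless_wt_ctz_study.traces)
        chi2 = lk.chi_squared(wt_ctz, {"scaling_f": 1e6}, ds)
        # noiseless data generated by the same forward model
        assert chi2 < 1e-4

    def test_sigma_scaling_identity(self, noiseless_wt_ctz_study, wt_ctz):
        ds = lk.datasets_from_traces(noiseless_wt_ctz_study.traces)
        wrong = lk.KineticParams(wt_ctz.k_cat * 1.2, wt_ctz.K_m, wt_ctz.K_p)
        chi2 = lk.chi_squared(wrong, {"scaling_f": 1e6}, ds)
        for d in ds:
            d.sigma = d.sigma * 3.0
        chi2_scaled = lk.chi_squared(wrong, {"scaling_f": 1e6}, ds)
        assert chi2_scaled == pytest.approx(chi2 / 9.0, rel=1e-12)

    def test_hand_computed_three_point_value(self, wt_ctz):
        # model evaluated once, then compared against a hand-built dataset
        d = lk.CurveData(
            S0=0.5, E0=0.01, times=np.array([1.0, 2.0, 3.0]),
            cumulative=np.zeros(3), sigma=np.array([1.0, 2.0, 4.0]), group="g",
        )
        model = FitProblem([d]).model_for({"k_cat": wt_ctz.k_cat, "K_m": wt_ctz.K_m,
                                           "K_p": wt_ctz.K_p, "f[g]": 1e6})[0]
        d.cumulative = model - np.array([1.0, -2.0, 4.0])
        chi2 = lk.chi_squared(wt_ctz, {"scaling_f": {"g": 1e6}}, [d])
        assert chi2 == pytest.approx(1.0 / 1.0 + 4.0 / 4.0 + 16.0 / 16.0, rel=1e-10)

    def test_missing_sigma_refused(self):
        with pytest.raises(ConfigError):
            lk.CurveData(S0=0.5, E0=0.01, times=np.array([1.0]),
                         cumulative=np.array([0.0]), sigma=None)


class TestFitGlobal:
    def test_fixed_point_at_truth_on_noiseless_data(self, noiseless_wt_ctz_study, wt_ctz):
        ds = lk.datasets_from_traces(noiseless_wt_ctz_study.traces)
        res = lk.fit_global(ds, init=wt_ctz, multistart_n=1, seed=0)
        assert res.chi2 < 1e-4
        assert res.params.k_cat == pytest.approx(wt_ctz.k_cat, rel=1e-6)
        assert res.params.K_m == pytest.approx(wt_ctz.K_m, rel=1e-6)

    def test_noiseless_recovery_from_perturbed_start_wt_fmz(self, wt_fmz):
        bundle = _study(wt_fmz, lk.NoiseModel(0, 0, seed=1), read_interval=0.5,
                        seed_tag="wt|FMZ")
        ds = lk.datasets_from_traces(bundle.traces)
        init = lk.KineticParams(wt_fmz.k_cat * 3, wt_fmz.K_m / 3, wt_fmz.K_p * 3)
        res = lk.fit_global(ds, init=init, multistart_n=1, seed=0)
        for name in ("k_cat", "K_m", "K_p"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(wt_fmz, name), rel=1e-3
            ), name

    def test_dataset_order_does_not_change_estimates(self, noiseless_wt_ctz_study, wt_ctz):
        ds = lk.datasets_from_traces(noiseless_wt_ctz_study.traces)
        init = lk.KineticParams(wt_ctz.k_cat * 2, wt_ctz.K_m / 2, wt_ctz.K_p)
        a = lk.fit_global(ds, init=init, multistart_n=1, seed=0)
        b = lk.fit_global(ds[::-1], init=init, multistart_n=1, seed=0)
        assert b.params.k_cat == pytest.approx(a.params.k_cat, rel=1e-10)
        assert b.params.K_m == pytest.approx(a.params.K_m, rel=1e-10)

    def test_conc_corrections_stay_in_box_and_absorb_jitter(self, wt_ctz):
        bundle = _study(wt_ctz, lk.NoiseModel(0, 0, seed=3), jitter=0.04)
        ds = lk.datasets_from_traces(bundle.traces)
        # scaling fixed at truth: otherwise a shared amplitude factor can
        # trade off against the per-curve corrections
        res = lk.fit_global(ds, init=wt_ctz, multistart_n=1, seed=0,
                            options=FitOptions(fit_conc_corrections=True,
                                               fixed_scaling={"wt|CTZ": 1e6}))
        assert all(0.95 <= c <= 1.05 for c in res.conc_corrections)
        truth = bundle.truth["entries"]["wt|CTZ"]["curves"]
        fitted = {c["S0_nominal"]: r for c, r in zip(truth, res.conc_corrections)}
        for c in truth:
            ratio = c["S0_true"] / c["S0_nominal"]
            assert fitted[c["S0_nominal"]] == pytest.approx(ratio, abs=0.01)

    def test_scaling_matches_calibration_on_complete_curves(self, noiseless_wt_ctz_study):
        ds = lk.datasets_from_traces(noiseless_wt_ctz_study.traces)
        res = lk.fit_global(ds, init=lk.KineticParams(2.48, 0.57, 0.256),
                            multistart_n=1, seed=0)
        # every curve in this study completes; calibrate from the lowest-S0 one
        low = min(ds, key=lambda d: d.S0)
        curve = lk.ConversionCurve(times=low.times, cumulative=low.cumulative,
                                   sigma=low.sigma)
        f_cal = lk.calibrate_scaling(curve, S0=low.S0, override_completion=True)
        f_fit = list(res.scaling_f.values())[0]
        assert f_fit == pytest.approx(f_cal, rel=0.01)

    def test_truncated_curves_inflate_scaling_uncertainty(self, wt_ctz):
        noise = lk.NoiseModel(0.02, 5.0, seed=7)
        complete = _study(wt_ctz, noise)
        truncated = _study(wt_ctz, noise, max_duration=40.0)  # <50% conversion
        se = {}
        for tag, bundle in (("complete", complete), ("truncated", truncated)):
            ds = lk.datasets_from_traces(bundle.traces)
            res = lk.fit_global(ds, init=wt_ctz, multistart_n=1, seed=0)
            key = [k for k in res.se if k.startswith("f[")][0]
            se[tag] = res.se[key] / list(res.scaling_f.values())[0]
        assert se["truncated"] > 5 * se["complete"]


class TestCheckDepletion:
    def _calibrated(self, wt_ctz, max_duration):
        cond = lk.AssayConditions(E0=0.05, S0=0.5, read_interval_s=1.0,
                                  max_duration_s=max_duration)
        curve = lk.integrate_progress(wt_ctz, cond)
        cc = lk.cumulative_luminescence(lk.intensity_from_progress(curve, 1e6))
        return apply_scaling(cc, 1e6)

    def test_complete_conversion_passes(self, wt_ctz):
        frac, ok = lk.check_depletion(self._calibrated(wt_ctz, 600.0), 0.5)
        assert ok and frac == pytest.approx(1.0, abs=0.01)

    def test_truncated_conversion_fails(self, wt_ctz):
        frac, ok = lk.check_depletion(self._calibrated(wt_ctz, 10.0), 0.5)
        assert not ok and frac < 0.7

    def test_noisy_complete_conversion_near_unity(self):
        p = lk.KineticParams(2.48, 0.57)
        cond = lk.AssayConditions(E0=0.05, S0=0.5, read_interval_s=1.0, max_duration_s=400)
        fracs = []
        for seed in range(100):
            tr = lk.generate_trace(p, cond, lk.KineticScheme("mm_basic"), 1e6,
                                   lk.NoiseModel(0.02, 5.0, seed=seed))
            cc = lk.cumulative_luminescence(lk.subtract_baseline(tr))
            cal = apply_scaling(cc, 1e6)
            fracs.append(lk.check_depletion(cal, 0.5)[0])
        assert np.median(np.abs(np.array(fracs) - 1.0)) < 0.01

    def test_uncalibrated_curve_rejected(self, wt_ctz):
        cc = lk.ConversionCurve(times=np.array([1.0]), cumulative=np.array([1.0]))
        with pytest.raises(DomainError):
            lk.check_depletion(cc, 0.5)
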
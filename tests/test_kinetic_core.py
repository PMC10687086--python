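"""Rate law, integrators and macroscopic↔microscopic rate bridging."""

import math

import numpy as np
import pytest

import lucikin as lk
from lucikin.errors import DomainError, InfeasibleRateError

from helpers import euler_progress


class TestRateQssa:
    def test_no_substrate_or_no_enzyme_gives_zero(self, wt_ctz):
        assert lk.rate_qssa(wt_ctz, S=0.0, P=0.0, E0=0.01) == 0.0
        assert lk.rate_qssa(wt_ctz, S=1.0, P=0.0, E0=0.0) == 0.0

    def test_closed_form_value_without_inhibition(self):
        p = lk.KineticParams(2.48, 0.57)
        v = lk.rate_qssa(p, S=1.0, P=0.0, E0=0.01)
        assert v == pytest.approx(2.48 * 0.01 * 1.0 / (0.57 + 1.0), rel=1e-12)
        assert v == pytest.approx(0.0158, abs=2e-4)

    def test_product_at_Kp_doubles_Km_term(self, wt_ctz):
        v = lk.rate_qssa(wt_ctz, S=1.0, P=0.256, E0=0.01)
        assert v == pytest.approx(2.48 * 0.01 / (2 * 0.57 + 1.0), rel=1e-12)
        assert v == pytest.approx(0.0116, abs=2e-4)

    def test_negative_concentration_rejected(self, wt_ctz):
        with pytest.raises(DomainError):
            lk.rate_qssa(wt_ctz, S=-1.0, P=0.0, E0=0.01)
        with pytest.raises(DomainError):
            lk.rate_qssa(wt_ctz, S=1.0, P=-0.1, E0=0.01)

    def test_reduces_to_michaelis_menten_without_inhibition(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k_cat, K_m = rng.uniform(0.1, 50), rng.uniform(0.05, 5)
            S, E0 = rng.uniform(0, 10), rng.uniform(0, 0.1)
            P = rng.uniform(0, 10)
            p = lk.KineticParams(k_cat, K_m)
            assert lk.rate_qssa(p, S, P, E0) == pytest.approx(
                k_cat * E0 * S / (K_m + S), rel=1e-14
            )

    def test_strictly_decreasing_in_product_when_Kp_finite(self, wt_ctz):
        S, E0 = 1.0, 0.01
        v = [lk.rate_qssa(wt_ctz, S, P, E0) for P in np.linspace(0, 2, 20)]
        assert np.all(np.diff(v) < 0)

    def test_substrate_inhibition_optimum_at_sqrt_Km_Ks(self):
        p = lk.KineticParams(2.0, 0.5, K_s=20.0)
        S = np.linspace(0.01, 30.0, 20000)
        v = np.array([lk.rate_qssa(p, s, 0.0, 0.01) for s in S])
        S_star = S[np.argmax(v)]
        assert S_star == pytest.approx(math.sqrt(0.5 * 20.0), abs=2 * (S[1] - S[0]))


class TestKineticParams:
    @pytest.mark.parametrize("kw", [
        {"k_cat": -1, "K_m": 1}, {"k_cat": 1, "K_m": 0},
        {"k_cat": math.inf, "K_m": 1}, {"k_cat": 1, "K_m": 1, "K_p": 0},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(DomainError):
            lk.KineticParams(**kw)

    def test_infinite_sentinels_allowed_for_Kp_Ks(self):
        p = lk.KineticParams(1.0, 1.0, math.inf, math.inf)
        assert not np.isfinite(p.K_p) and not np.isfinite(p.K_s)


class TestIntegrateProgress:
    def test_no_enzyme_means_no_product(self, wt_ctz):
        cond = lk.AssayConditions(E0=0.0, S0=1.0, read_interval_s=1.0, max_duration_s=100)
        curve = lk.integrate_progress(wt_ctz, cond)
        assert np.all(curve.product == 0.0)

    def test_complete_conversion_limit(self):
        p = lk.KineticParams(2.48, 0.57)  # no product inhibition
        cond = lk.AssayConditions(E0=0.01, S0=0.5, read_interval_s=1.0, max_duration_s=600)
        curve = lk.integrate_progress(p, cond, lk.KineticScheme("mm_basic"))
        assert curve.product[-1] == pytest.approx(0.5, rel=5e-3)

    def test_product_nondecreasing_and_bounded(self, wt_ctz):
        cond = lk.AssayConditions(E0=0.01, S0=2.28, read_interval_s=2.0, max_duration_s=1000)
        curve = lk.integrate_progress(wt_ctz, cond)
        assert np.all(np.diff(curve.product) >= -1e-12)
        assert np.all((curve.product >= 0) & (curve.product <= 2.28 + 1e-9))

    def test_agrees_with_euler_oracle_wt_fmz(self, wt_fmz):
        cond = lk.AssayConditions(E0=0.01, S0=0.5, read_interval_s=0.5, max_duration_s=60)
        curve = lk.integrate_progress(wt_fmz, cond)
        oracle = euler_progress(wt_fmz, 0.5, 0.01, curve.times)
        assert np.max(np.abs(curve.product - oracle)) / 0.5 < 1e-3
        # time to 50% conversion from both paths
        t50 = np.interp(0.25, curve.product, curve.times)
        t50_oracle = np.interp(0.25, oracle, curve.times)
        assert t50 == pytest.approx(t50_oracle, rel=1e-3)

    def test_agrees_with_euler_oracle_random_parameter_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = lk.KineticParams(
                k_cat=rng.uniform(0.5, 10),
                K_m=rng.uniform(0.1, 2),
                K_p=rng.uniform(0.2, 5),
            )
            S0 = rng.uniform(0.2, 2)
            cond = lk.AssayConditions(E0=0.01, S0=S0, read_interval_s=1.0, max_duration_s=120)
            curve = lk.integrate_progress(p, cond)
            oracle = euler_progress(p, S0, 0.01, curve.times)
            assert np.max(np.abs(curve.product - oracle)) / S0 < 1e-3

    def test_positive_tolerances_required(self, wt_ctz):
        cond = lk.AssayConditions(E0=0.01, S0=1.0, read_interval_s=1.0, max_duration_s=10)
        with pytest.raises(DomainError):
            lk.integrate_progress(wt_ctz, cond, rel_tol=-1.0)


class TestMicroRates:
    def test_arithmetic_from_stated_relation(self):
        p = lk.KineticParams(2.48, 0.57, 0.256)
        mr = lk.derive_micro_rates(p, k1=100.0)
        assert mr.k_off == pytest.approx(57.0 - 2.48, rel=1e-14)

    def test_boundary_k1_rejected_with_minimal_reported(self):
        p = lk.KineticParams(2.48, 0.57)
        with pytest.raises(InfeasibleRateError) as exc:
            lk.derive_micro_rates(p, k1=2.48 / 0.57)
        assert exc.value.minimal_k1 == pytest.approx(2.48 / 0.57)

    def test_round_trip_reproduces_macroscopic_constants(self):
        p = lk.KineticParams(3.1, 0.41, 0.9, 17.0)
        mr = lk.derive_micro_rates(p, k1=250.0)
        assert mr.K_m == pytest.approx(p.K_m, rel=1e-15)
        assert mr.K_p == pytest.approx(p.K_p, rel=1e-15)
        assert mr.K_s == pytest.approx(p.K_s, rel=1e-15)


class TestMassAction:
    def test_enzyme_and_substrate_conservation(self, wt_ctz):
        cond = lk.AssayConditions(E0=0.01, S0=0.5, read_interval_s=1.0, max_duration_s=300)
        curve = lk.simulate_mass_action(lk.derive_micro_rates(wt_ctz, 100.0), cond)
        sp = curve.species
        enzyme = sp["E"] + sp["ES"] + sp["ESS"] + sp["EP"]
        substrate = sp["S"] + sp["ES"] + 2 * sp["ESS"] + sp["EP"] + sp["P"]
        assert np.max(np.abs(enzyme - 0.01)) < 1e-6 * 0.01
        assert np.max(np.abs(substrate - 0.5)) < 1e-6 * 0.5

    def test_complete_conversion_for_irreversible_catalysis(self):
        p = lk.KineticParams(2.48, 0.57)
        cond = lk.AssayConditions(E0=0.05, S0=0.2, read_interval_s=2.0, max_duration_s=1000)
        curve = lk.simulate_mass_action(lk.derive_micro_rates(p, 100.0), cond)
        assert curve.product[-1] == pytest.approx(0.2, abs=1e-6 * 0.2)

    def test_matches_qssa_at_fast_binding(self, wt_ctz):
        cond = lk.AssayConditions(E0=0.01, S0=0.5, read_interval_s=0.5, max_duration_s=600)
        qssa = lk.integrate_progress(wt_ctz, cond)
        ma = lk.simulate_mass_action(lk.derive_micro_rates(wt_ctz, 1000.0), cond)
        assert np.max(np.abs(ma.product - qssa.product)) / 0.5 < 0.01

    def test_qssa_discrepancy_shrinks_with_k1(self, wt_ctz):
        # early window, where the complex-equilibration transient dominates
        times = np.arange(0.01, 2.001, 0.01)
        cond = lk.AssayConditions(
            E0=0.01, S0=0.5, baseline_s=0.0, read_interval_s=0.01, max_duration_s=2.0
        )
        qssa = lk.integrate_progress(wt_ctz, cond, times=times)
        sup = []
        for k1 in (10.0, 100.0, 1000.0):
            ma = lk.simulate_mass_action(lk.derive_micro_rates(wt_ctz, k1), cond, times=times)
            sup.append(np.max(np.abs(ma.product - qssa.product)))
        assert sup[0] > sup[1] > sup[2]

    def test_product_nondecreasing(self, wt_ctz):
        cond = lk.AssayConditions(E0=0.01, S0=0.5, read_interval_s=1.0, max_duration_s=300)
        curve = lk.simulate_mass_action(lk.derive_micro_rates(wt_ctz, 500.0), cond)
        assert np.all(np.diff(curve.product) >= -1e-12)
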
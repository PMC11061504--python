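import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from hillmc import hill_mtu as hm


def central_diff(f, x, h=1e-6):
    return (f(x + h) - f(x - h)) / (2.0 * h)


class TestTendonCurve:
    def test_zero_strain_zero_force(self):
        assert hm.tendon_force_norm(0.0, 35.0) == pytest.approx(0.0, abs=1e-14)

    def test_gradient_at_calibration_strain(self):
        slope = central_diff(lambda s: hm.tendon_force_norm(s, 35.0), 0.04)
        assert slope == pytest.approx(35.0, abs=1e-4)

    def test_value_at_calibration_strain(self):
        # closed form of the calibrated curve: 1 - exp(-1.4)
        assert hm.tendon_force_norm(0.04, 35.0) == pytest.approx(
            1.0 - math.exp(-1.4), abs=1e-12)

    def test_strictly_increasing(self):
        s = np.linspace(-0.02, 0.10, 200)
        f = hm.tendon_force_norm(s, 35.0)
        assert np.all(np.diff(f) > 0)

    @pytest.mark.parametrize("k", [14.0, 20.0, 27.5, 35.0])
    def test_slope_equals_k_for_perturbed_stiffness(self, k):
        slope = central_diff(lambda s: hm.tendon_force_norm(s, k), 0.04)
        assert slope == pytest.approx(k, abs=1e-6)

    def test_nonfinite_strain_rejected(self):
        with pytest.raises(ValueError):
            hm.tendon_force_norm(np.nan, 35.0)

    def test_inversion_round_trip(self):
        rng = np.random.default_rng(1)
        force = rng.uniform(0.0, 2.0, 100)
        strain = hm.tendon_strain_from_force(force, 35.0)
        assert np.max(np.abs(hm.tendon_force_norm(strain, 35.0) - force)) < 1e-12


class TestActiveForceLength:
    def test_unity_at_optimum(self):
        assert hm.active_force_length(1.0) == pytest.approx(1.0, abs=0.01)

    def test_short_fiber_weak(self):
        assert hm.active_force_length(0.5) < 0.3

    def test_descending_limb_monotone(self):
        l = np.linspace(1.0, 1.8, 400)
        f = hm.active_force_length(l)
        assert np.all(np.diff(f) < 0)
        assert hm.active_force_length(1.4) < hm.active_force_length(1.1)

    def test_range_and_global_max(self):
        l = np.linspace(0.05, 2.5, 2000)
        f = hm.active_force_length(l)
        assert np.all(f >= 0.0) and np.all(f <= 1.001)
        assert l[np.argmax(f)] == pytest.approx(1.0, abs=2e-3)

    def test_vanishes_outside_working_range(self):
        assert hm.active_force_length(0.35) < 0.02
        assert hm.active_force_length(1.9) < 0.02

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            hm.active_force_length(0.0)


class TestPassiveForceLength:
    def test_slack_at_optimum(self):
        assert abs(hm.passive_force_length(1.0)) <= 0.02

    def test_unity_at_strain_limit(self):
        assert hm.passive_force_length(1.6) == pytest.approx(1.0, abs=1e-12)

    def test_small_below_optimum(self):
        l = np.linspace(0.4, 1.0, 50)
        assert np.max(np.abs(hm.passive_force_length(l))) <= 0.02

    def test_monotone_above_optimum(self):
        v11, v13, v15 = (hm.passive_force_length(x) for x in (1.1, 1.3, 1.5))
        assert v11 < v13 < v15
        l = np.linspace(1.0, 2.0, 300)
        assert np.all(np.diff(hm.passive_force_length(l)) > 0)


class TestForceVelocity:
    def test_isometric(self):
        assert hm.force_velocity(0.0) == pytest.approx(1.0, abs=0.01)

    def test_maximal_shortening(self):
        assert hm.force_velocity(-1.0) <= 0.05

    def test_eccentric_at_least_isometric(self):
        assert hm.force_velocity(0.5) >= hm.force_velocity(0.0)

    def test_monotone_nondecreasing(self):
        v = np.linspace(-1.2, 3.0, 500)
        assert np.all(np.diff(hm.force_velocity(v)) >= 0)

    def test_eccentric_plateau_bounded(self):
        v = np.linspace(0.0, 3.0, 200)
        assert np.max(hm.force_velocity(v)) <= 1.8


class TestSmoothness:
    """All characteristic curves must be C1 (gradient-based NLP solution)."""

    @pytest.mark.parametrize("fn,lo,hi", [
        (lambda x: hm.tendon_force_norm(x, 35.0), -0.01, 0.09),
        (hm.active_force_length, 0.3, 2.0),
        (hm.passive_force_length, 0.3, 2.0),
        (hm.force_velocity, -1.1, 2.0),
    ])
    def test_slope_continuity(self, fn, lo, hi):
        x = np.linspace(lo, hi, 1500)
        step = x[1] - x[0]
        slopes = (fn(x[2:]) - fn(x[:-2])) / (2.0 * step)
        # a C1 function with bounded curvature has slope jumps O(step);
        # a kink would leave an O(1) jump regardless of step
        jumps = np.abs(np.diff(slopes))
        scale = max(np.max(np.abs(slopes)), 1.0)
        assert np.max(jumps) < 50.0 * step * scale
        assert np.max(jumps) / scale < 1e-4 * (step / 1e-6)


class TestPennation:
    def test_parallel_fibered(self):
        assert hm.pennation_angle(1.3, 0.0) == 0.0

    def test_at_optimal_length(self):
        a0 = math.radians(20.0)
        assert hm.pennation_angle(1.0, a0) == pytest.approx(a0, abs=1e-12)

    def test_long_fiber_closed_form(self):
        assert hm.pennation_angle(2.0, math.radians(30.0)) == pytest.approx(
            math.asin(0.25), abs=1e-12)

    def test_unsolvable_geometry(self):
        with pytest.raises(ValueError, match="pennation"):
            hm.pennation_angle(0.3, math.radians(80.0))


class TestFiberStateFromTendonForce:
    def test_zero_force_slack_tendon(self, baseline_params):
        p = baseline_params
        _, _, l_ten = hm.fiber_state_from_tendon_force(0.0, 0.30, p)
        assert l_ten == pytest.approx(p.l_tendon_slack, abs=1e-14)

    def test_round_trip(self, baseline_params):
        p = baseline_params
        rng = np.random.default_rng(7)
        for _ in range(100):
            ft = rng.uniform(0.0, 2.5)
            l_mtu = rng.uniform(0.28, 0.34)
            _, _, l_ten = hm.fiber_state_from_tendon_force(ft, l_mtu, p)
            strain = l_ten / p.l_tendon_slack - 1.0
            assert hm.tendon_force_norm(strain, p.k_tendon) == pytest.approx(
                ft, abs=1e-10)

    def test_calibration_strain_inversion(self, baseline_params):
        p = baseline_params
        ft = hm.tendon_force_norm(0.04, p.k_tendon)
        _, _, l_ten = hm.fiber_state_from_tendon_force(ft, 0.30, p)
        assert l_ten == pytest.approx(1.04 * p.l_tendon_slack, rel=1e-12)

    def test_negative_fiber_length_rejected(self, baseline_params):
        with pytest.raises(ValueError):
            hm.fiber_state_from_tendon_force(0.0, 0.10, baseline_params)


class TestHillEquilibrium:
    def test_slack_mtu_residual_near_zero(self, baseline_params):
        p = baseline_params
        # mtu length putting the fibre below optimal length at zero force
        l_mtu = p.l_tendon_slack + 0.9 * p.l_opt
        r = hm.hill_equilibrium_residual(
            hm.MTUState(0.0, 0.0), hm.MTUControls(0.0, 0.0), l_mtu, 0.0, p)
        assert abs(r) < 0.02

    @pytest.mark.parametrize("seed", range(4))
    def test_isometric_root_matches_bracketed_rootfind(self, baseline_params,
                                                       seed):
        p = baseline_params
        rng = np.random.default_rng(seed)
        for _ in range(25):
            a = rng.uniform(0.05, 1.0)
            l_mtu = rng.uniform(0.29, 0.33)

            def resid(ft):
                return hm.hill_equilibrium_residual(
                    hm.MTUState(a, ft), hm.MTUControls(0.0, 0.0), l_mtu, 0.0, p)

            root = brentq(resid, 0.0, 3.4, xtol=1e-12)
            assert abs(resid(root)) < 1e-8

    def test_more_activation_makes_residual_negative(self, baseline_params):
        p = baseline_params
        a, l_mtu = 0.5, 0.31

        def resid(ft, a=a):
            return hm.hill_equilibrium_residual(
                hm.MTUState(a, ft), hm.MTUControls(0.0, 0.0), l_mtu, 0.0, p)

        root = brentq(resid, 0.0, 3.4, xtol=1e-12)
        assert hm.hill_equilibrium_residual(
            hm.MTUState(0.7, root), hm.MTUControls(0.0, 0.0),
            l_mtu, 0.0, p) < 0


class TestActivationRateBounds:
    def test_full_activation_cannot_rise(self):
        _, max_rate = hm.activation_rate_bounds(1.0)
        assert max_rate == 0.0

    def test_zero_activation_cannot_fall(self):
        min_rate, _ = hm.activation_rate_bounds(0.0)
        assert min_rate == 0.0

    def test_half_activation_values(self):
        min_rate, max_rate = hm.activation_rate_bounds(0.5)
        assert min_rate == pytest.approx(-0.5 / 0.06)
        assert max_rate == pytest.approx(0.5 / 0.015)

    def test_first_order_response_limit(self):
        # integrating da/dt = (1-a)/t_act from 0 gives 1 - exp(-t/t_act)
        from scipy.integrate import solve_ivp

        ta = hm.ACTIVATION_TIME_CONSTANT
        sol = solve_ivp(lambda t, a: (1.0 - a) / ta, (0.0, 0.1), [0.0],
                        rtol=1e-10, atol=1e-12, dense_output=True)
        t = np.linspace(0.0, 0.1, 50)
        assert np.max(np.abs(sol.sol(t)[0] - (1.0 - np.exp(-t / ta)))) < 1e-8


class TestApplyPerturbation:
    def test_identity_at_100(self, baseline_params):
        out = hm.apply_perturbation(baseline_params, hm.GroupPerturbation())
        assert out == baseline_params

    def test_mif_scaling(self, baseline_params):
        out = hm.apply_perturbation(
            baseline_params, hm.GroupPerturbation(mif_pct=40.0))
        assert out.f_max == pytest.approx(0.40 * baseline_params.f_max)

    def test_tendon_compliance_scaling(self, baseline_params):
        out = hm.apply_perturbation(
            baseline_params, hm.GroupPerturbation(tc_pct=40.0))
        assert out.k_tendon == pytest.approx(14.0)

    def test_slack_length_never_perturbed(self, baseline_params):
        out = hm.apply_perturbation(
            baseline_params,
            hm.GroupPerturbation(80.0, 80.0, 80.0, 80.0, 80.0))
        assert out.l_tendon_slack == baseline_params.l_tendon_slack

    def test_multiplicative_composition(self, baseline_params):
        once = hm.apply_perturbation(
            baseline_params, hm.GroupPerturbation(mif_pct=40.0))
        twice = hm.apply_perturbation(
            hm.apply_perturbation(baseline_params,
                                  hm.GroupPerturbation(mif_pct=80.0)),
            hm.GroupPerturbation(mif_pct=50.0))
        assert twice.f_max == pytest.approx(once.f_max, rel=1e-12)

    def test_out_of_bounds_rejected(self, baseline_params):
        with pytest.raises(ValueError):
            hm.apply_perturbation(baseline_params,
                                  hm.GroupPerturbation(mif_pct=30.0))

    def test_perturbed_tendon_recalibrated(self, baseline_params):
        out = hm.apply_perturbation(baseline_params,
                                    hm.GroupPerturbation(tc_pct=40.0))
        assert hm.tendon_force_norm(0.0, out.k_tendon) == pytest.approx(0.0)
        slope = central_diff(lambda s: hm.tendon_force_norm(s, out.k_tendon),
                             0.04)
        assert slope == pytest.approx(out.k_tendon, abs=1e-6)


class TestParameterValidation:
    @given(st.floats(max_value=0.0, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_nonpositive_fmax_rejected(self, bad):
        with pytest.raises(ValueError):
            hm.MTUParameters("x", bad, 0.1, 0.1, 1.0, 35.0, 0.2, 0.1)

    def test_state_bounds(self):
        with pytest.raises(ValueError):
            hm.MTUState(1.2, 0.0)
        with pytest.raises(ValueError):
            hm.MTUState(0.5, np.nan)
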
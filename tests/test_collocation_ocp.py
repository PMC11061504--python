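import math

import numpy as np
import pytest

from hillmc import collocation_ocp as co
from hillmc import limb_model as lm
from hillmc import reference_gen as rg
from hillmc.hill_mtu import ACTIVATION_TIME_CONSTANT, MTUParameters
from tests.conftest import make_single_mtu_model


class TestRadauScheme:
    def test_degree_one_rectangle_limit(self):
        pts, w, D = co.radau_scheme(1)
        assert pts.tolist() == [1.0]
        assert w.tolist() == [1.0]
        assert D.shape == (1, 2)

    def test_quadrature_tau_squared(self):
        pts, w, _ = co.radau_scheme(3)
        assert np.dot(w, pts**2) == pytest.approx(1.0 / 3.0, abs=1e-14)

    @pytest.mark.parametrize("degree", [2, 3, 4, 5])
    def test_quadrature_exact_to_2d_minus_2(self, degree):
        pts, w, _ = co.radau_scheme(degree)
        for p in range(2 * degree - 1):
            # oracle: symbolic integral of tau^p over [0, 1]
            assert np.dot(w, pts**p) == pytest.approx(1.0 / (p + 1), abs=1e-12)

    def test_differentiation_matrix_on_cubic(self):
        pts, _, D = co.radau_scheme(3)
        nodes = np.concatenate([[0.0], pts])
        deriv = D @ nodes**3
        assert np.max(np.abs(deriv - 3.0 * pts**2)) < 1e-12

    @pytest.mark.parametrize("degree", [2, 4])
    def test_differentiation_exact_to_scheme_degree(self, degree):
        pts, _, D = co.radau_scheme(degree)
        nodes = np.concatenate([[0.0], pts])
        for p in range(degree + 1):
            assert np.max(np.abs(D @ nodes**p - p * pts**np.maximum(p - 1, 0)
                                 * (1.0 if p else 0.0))) < 1e-11

    def test_endpoint_included(self):
        for d in range(1, 8):
            pts, _, _ = co.radau_scheme(d)
            assert pts[-1] == pytest.approx(1.0, abs=1e-14)
            assert np.all(pts > 0)

    @pytest.mark.parametrize("degree", [0, 10])
    def test_unsupported_degree(self, degree):
        with pytest.raises(ValueError):
            co.radau_scheme(degree)


class TestRadauIntegrate:
    def test_first_order_activation_response(self):
        """Collocation trajectory of da/dt=(1-a)/ta matches the closed form."""
        ta = ACTIVATION_TIME_CONSTANT
        times, states = co.radau_integrate(
            lambda t, a: (1.0 - a) / ta, 0.0, 0.1, 50, degree=3)
        exact = 1.0 - np.exp(-times / ta)
        assert np.max(np.abs(states - exact)) < 1e-3

    def test_linear_growth_exact(self):
        times, states = co.radau_integrate(lambda t, x: 2.0, 1.0, 1.0, 4, 2)
        assert np.allclose(states, 1.0 + 2.0 * times, atol=1e-10)


class TestObjectiveTerms:
    def setup_method(self):
        pts, w, _ = co.radau_scheme(3)
        self.w3 = np.tile(w * 1.0, 3)      # 3 intervals of h=1 -> duration 3

    def test_effort_zero_activations(self):
        assert co.effort_term(np.zeros((2, 9)), [0.4, 0.6], self.w3) == 0.0

    def test_effort_full_activation_closed_form(self):
        # one MTU, PV=1, a=1 over 3 s -> integral = 3
        assert co.effort_term(np.ones((1, 9)), [1.0], self.w3) == \
            pytest.approx(3.0, abs=1e-12)

    def test_effort_symmetric_in_volumes_for_equal_activations(self):
        a = np.full((2, 9), 0.37)
        assert co.effort_term(a, [0.3, 0.7], self.w3) == \
            pytest.approx(co.effort_term(a, [0.7, 0.3], self.w3))

    def test_reserve_zero(self):
        assert co.reserve_term(np.zeros((3, 9)), self.w3) == 0.0

    def test_reserve_unit_scaled_half_second(self):
        pts, w, _ = co.radau_scheme(3)
        wq = np.tile(w * 0.25, 2)          # duration 0.5 s
        assert co.reserve_term(np.ones((1, 6)), wq, 1.0) == \
            pytest.approx(0.5, abs=1e-12)

    def test_reserve_linear_in_weight(self):
        r = np.random.default_rng(0).normal(size=(2, 9))
        assert co.reserve_term(r, self.w3, 2.0) == \
            pytest.approx(2.0 * co.reserve_term(r, self.w3, 1.0))

    def test_control_zero_rates(self):
        assert co.control_term(np.zeros((2, 9)), np.zeros((2, 9)),
                               self.w3, 1.0) == 0.0

    def test_control_constant_rate_closed_form(self):
        pts, w, _ = co.radau_scheme(3)
        wq = w * 1.0                        # duration 1 s
        val = co.control_term(np.full((1, 3), 2.0), np.zeros((1, 3)), wq, 1.0)
        assert val == pytest.approx(4.0, abs=1e-12)

    def test_control_sign_invariant(self):
        rng = np.random.default_rng(1)
        ua, uf = rng.normal(size=(2, 9)), rng.normal(size=(2, 9))
        assert co.control_term(ua, uf, self.w3, 0.7) == \
            pytest.approx(co.control_term(-ua, -uf, self.w3, 0.7))


@pytest.fixture(scope="module")
def toy_nlp(request):
    params = MTUParameters("toy", 2000.0, 0.12, 0.12, 1.2, 35.0, 0.16, 1.0)
    model = make_single_mtu_model(params)
    kin = rg.isokinetic_kinematics(30.0, n_samples=11)
    ref = rg.oracle_post_reference(
        model, np.full(15, 100.0), kin,
        activation_profile={lm.KNEE_EXTENSOR: 0.4})
    settings = co.OCPSettings(n_mesh_intervals=2, poly_degree=1)
    return co.transcribe(model, ref, kin, settings)


class TestTranscription:
    def test_hand_counted_toy_problem(self, toy_nlp):
        """1 MTU, 1 coordinate, 2 intervals, degree 1 — enumerated by hand:

        variables: per interval, states (a, Ft) at 2 points (start +
        collocation) = 4, controls at 1 point = 2, reserve at 1 point = 1;
        two intervals -> 14.
        constraints: dynamics 2 per collocation point -> 4; continuity
        2 (one interface); moment balance 1 per collocation point -> 2;
        Hill 1 per collocation point -> 2; rate inequalities 2 per
        collocation point -> 4.
        """
        c = toy_nlp.counts
        assert c["variables"] == 14
        assert c["dynamics"] == 4
        assert c["continuity"] == 2
        assert c["moment_balance"] == 2
        assert c["hill_equilibrium"] == 2
        assert c["rate_inequalities"] == 4
        assert toy_nlp.A_eq.shape == (8, 14)
        assert toy_nlp.A_ineq.shape == (4, 14)

    def test_default_settings_fifty_intervals(self, small_model, scenario):
        nlp = co.transcribe(small_model, scenario["references"][30.0],
                            scenario["kinematics"][30.0], co.OCPSettings())
        assert nlp.counts["n_mesh_intervals"] == 50

    def test_reserve_bounds_unscale_to_25(self, toy_nlp):
        assert toy_nlp.reserve_bounds_nm() == (-25.0, 25.0)

    def test_mismatched_grid_rejected(self, small_model, scenario):
        kin = scenario["kinematics"][30.0]
        bad = lm.CoordinateTrajectory(
            name=kin.name, time=kin.time + 1.0, angle=kin.angle,
            angular_velocity=kin.angular_velocity)
        with pytest.raises(ValueError):
            co.transcribe(small_model, scenario["references"][30.0], bad,
                          co.OCPSettings())

    def test_reduced_space_equivalence(self, toy_nlp):
        red = toy_nlp.reduced()
        rng = np.random.default_rng(0)
        y = rng.uniform(-0.5, 0.5, red.n_vars)
        z = red.full_from_y(y)
        # full-space linear equalities hold by construction of the mapping
        assert np.max(np.abs(toy_nlp.A_eq @ z - toy_nlp.b_eq)
                      [:toy_nlp._r_continuity]) < 1e-12
        # objective agrees between spaces
        assert red.objective(y) == pytest.approx(toy_nlp.objective(z),
                                                 rel=1e-12)
        # Hill residuals agree
        assert np.allclose(red.hill_residuals(y), toy_nlp.hill_residuals(z))


@pytest.fixture(scope="module")
def tracked_solution():
    """Baseline model tracking its own quasi-static oracle reference."""
    sc = rg.recovery_scenario()
    model = sc["model"]
    kin = sc["kinematics"][30.0]
    ref = rg.oracle_post_reference(model, np.full(15, 100.0), kin,
                                   condition="pre")
    settings = co.OCPSettings(n_mesh_intervals=6, poly_degree=3)
    nlp = co.transcribe(model, ref, kin, settings)
    sol = co.solve(nlp, initial_guess=co.quasi_static_guess(nlp))
    return nlp, sol, ref


class TestSolve:
    def test_self_consistency_converges(self, tracked_solution):
        _, sol, ref = tracked_solution
        assert sol.converged
        peak = np.max(np.abs(ref.moment_nm))
        assert np.max(np.abs(sol.knee_reserve)) < 0.01 * peak

    def test_objective_equals_recomputed_terms(self, tracked_solution):
        nlp, sol, _ = tracked_solution
        j_eff = co.effort_term(sol.activation[:, nlp._colloc_state_pts],
                               nlp.volume_fractions, nlp.quad_weights)
        j_res = co.reserve_term(sol.reserves / nlp.settings.reserve_bound,
                                nlp.quad_weights, nlp.settings.w_reserve)
        j_ctl = co.control_term(
            sol.activation_rate / nlp.settings.activation_rate_scale,
            sol.tendon_force_rate / nlp.settings.tendon_force_rate_scale,
            nlp.quad_weights, nlp.settings.w_control)
        assert sol.objective == pytest.approx(j_eff + j_res + j_ctl,
                                              abs=1e-10)
        assert sol.objective >= 0

    def test_moment_balance_on_converged_solution(self, tracked_solution):
        nlp, sol, _ = tracked_solution
        assert np.max(np.abs(sol.knee_moment_residual)) <= \
            10.0 * nlp.settings.constr_tol * nlp.settings.reserve_bound

    def test_activation_within_bounds(self, tracked_solution):
        _, sol, _ = tracked_solution
        assert np.all(sol.activation >= -1e-9)
        assert np.all(sol.activation <= 1.0 + 1e-9)

    def test_activation_rate_constraints_hold(self, tracked_solution):
        nlp, sol, _ = tracked_solution
        a = sol.activation[:, nlp._colloc_state_pts]
        ta, td = 0.015, 0.06
        assert np.all(sol.activation_rate <= (1 - a) / ta + 1e-6)
        assert np.all(sol.activation_rate >= -a / td - 1e-6)

    def test_determinism(self, scenario):
        model, kin = scenario["model"], scenario["kinematics"][30.0]
        ref = scenario["references"][30.0]
        settings = co.OCPSettings(n_mesh_intervals=4, poly_degree=2,
                                  tol=1e-3, max_iter=120)
        sols = []
        for _ in range(2):
            nlp = co.transcribe(model, ref, kin, settings)
            sols.append(co.solve(nlp, settings,
                                 initial_guess=co.quasi_static_guess(nlp)))
        assert sols[0].status == sols[1].status
        assert np.array_equal(sols[0].z, sols[1].z)

    def test_mesh_refinement_consistency(self, scenario):
        model, kin = scenario["model"], scenario["kinematics"][30.0]
        ref = scenario["references"][30.0]
        objs = []
        for n in (5, 10):
            settings = co.OCPSettings(n_mesh_intervals=n, poly_degree=3,
                                      tol=1e-5)
            sol = co.track(model, ref, kin, settings)
            assert sol.converged
            objs.append(sol.objective)
        assert abs(objs[1] - objs[0]) / objs[0] < 0.01

    def test_unattainable_reference_saturates_reserve(self, scenario):
        model, kin = scenario["model"], scenario["kinematics"][30.0]
        big = rg.ReferenceMomentProfile(
            "post", 30.0, kin.time, np.degrees(kin.angle),
            np.full(len(kin.time), 4000.0))
        settings = co.OCPSettings(n_mesh_intervals=4, poly_degree=2,
                                  tol=1e-3, max_iter=120)
        nlp = co.transcribe(model, big, kin, settings)
        sol = co.solve(nlp, settings,
                       initial_guess=co.quasi_static_guess(nlp))
        assert not sol.converged
        assert np.max(np.abs(sol.knee_reserve)) >= \
            0.99 * settings.reserve_bound

    def test_solution_io_round_trip(self, tracked_solution, tmp_path):
        _, sol, _ = tracked_solution
        sol.to_csv(tmp_path / "sol.csv")
        sol.to_json(tmp_path / "sol.json")
        import json

        import pandas as pd

        df = pd.read_csv(tmp_path / "sol.csv")
        assert set(df.columns) == {"time_s", "variable", "value"}
        summary = json.loads((tmp_path / "sol.json").read_text())
        assert summary["status"] == "converged"


class TestClassifyFeasibility:
    def _solution_with_reserve(self, reserve_fraction, ref, status="converged"):
        K = len(ref.time)
        reserves = np.zeros((3, K))
        reserves[1] = reserve_fraction * ref.moment_nm
        return co.CollocationSolution(
            status=status, message="", times_states=ref.time,
            times_colloc=ref.time,
            activation=np.zeros((1, K)), tendon_force=np.zeros((1, K)),
            activation_rate=np.zeros((1, K)),
            tendon_force_rate=np.zeros((1, K)),
            reserves=reserves, coordinates=["hip", "knee", "ankle"],
            knee_coordinate="knee", objective=0.0, j_effort=0.0,
            j_reserves=0.0, j_controls=0.0,
            knee_moment_residual=np.zeros(K), reference_moment=ref.moment_nm)

    @pytest.fixture
    def ref(self, scenario):
        return scenario["references"][30.0]

    def test_zero_reserves_feasible(self, ref):
        feasible, pct = co.classify_feasibility(
            self._solution_with_reserve(0.0, ref), ref)
        assert feasible and pct == 0.0

    def test_exactly_nine_percent_feasible(self, ref):
        feasible, pct = co.classify_feasibility(
            self._solution_with_reserve(0.09, ref), ref)
        assert feasible
        assert pct == pytest.approx(9.0, abs=1e-9)

    def test_violation_at_single_sample_infeasible(self, ref):
        sol = self._solution_with_reserve(0.0, ref)
        sol.reserves[1, 3] = 0.095 * ref.moment_nm[3]
        feasible, pct = co.classify_feasibility(sol, ref)
        assert not feasible
        assert pct == pytest.approx(9.5, abs=1e-9)

    def test_failed_status_infeasible_even_with_zero_reserve(self, ref):
        feasible, _ = co.classify_feasibility(
            self._solution_with_reserve(0.0, ref, status="failed"), ref)
        assert not feasible

    def test_floor_guards_near_zero_reference(self, scenario):
        kin = scenario["kinematics"][30.0]
        ref = rg.ReferenceMomentProfile(
            "post", 30.0, kin.time, np.degrees(kin.angle),
            np.full(len(kin.time), 1e-6))
        sol = self._solution_with_reserve(0.0, ref)
        sol.reserves[1, :] = 0.005
        feasible, pct = co.classify_feasibility(sol, ref, floor_nm=1.0)
        assert feasible  # 0.005 N*m against the 1 N*m floor = 0.5%
        assert pct == pytest.approx(0.5)


class TestSettings:
    def test_yaml_round_trip(self, tmp_path):
        s = co.OCPSettings(n_mesh_intervals=7, w_reserve=3.5)
        s.to_yaml(tmp_path / "s.yaml")
        back = co.OCPSettings.from_yaml(tmp_path / "s.yaml")
        assert back == s

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            co.OCPSettings(n_mesh_intervals=0)
        with pytest.raises(ValueError):
            co.OCPSettings(poly_degree=0)
        with pytest.raises(ValueError):
            co.OCPSettings(reserve_bound=-1.0)
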
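"""Flow-solve and integration tests: scalar solves vs brute-force oracles,
decomposed vs monolithic network solve, and periodic-state properties."""

import numpy as np
import pytest

from lymphnet.model_core import PhysicalParams, cmh2o_to_dyncm2
from lymphnet.oracles import bisection_segment_oracle, monolithic_flow_oracle
from lymphnet.solver import (
    BoundaryConditions, SimulationResult, SolverSettings, initial_diameters,
    mean_outlet_flow, network_flow_solve, ode_rhs, periodic_time_average,
    run_simulation, solve_junction, solve_segment_flow,
)
from lymphnet.topology import (
    VesselId, build_bifurcating_network, contraction_schedule,
)

from conftest import random_diameters


class TestSegmentFlow:
    def test_no_driving_pressure(self, params):
        Q, dp = solve_segment_flow(1000.0, 1000.0, 2e5, 2e5, True, params)
        assert Q == 0.0 and dp == 0.0

    def test_strong_forward_open_valve(self, params):
        # valve fully open: Q ~ dp_total / (R + RVn)
        Q, dp = solve_segment_flow(1e4, 0.0, 1.5e5, 1.5e5, True, params)
        assert Q == pytest.approx(1e4 / (3e5 + params.RVn), rel=5e-3)
        assert dp > 0

    def test_moderate_adverse_shut_valve(self, params):
        Q, dp = solve_segment_flow(0.0, 1e3, 1.5e5, 1.5e5, True, params)
        assert abs(Q) < 1e-6  # |Q| <= |dp| / RVx
        assert Q < 0

    def test_valveless_closed_form(self, params):
        Q, dp = solve_segment_flow(500.0, 200.0, 1e5, 2e5, False, params)
        assert Q == pytest.approx(300.0 / 3e5)
        assert dp == 0.0

    def test_matches_bisection_oracle(self, params, rng):
        for _ in range(200):
            dpt = rng.uniform(-2e4, 2e4)
            R = 10 ** rng.uniform(4.5, 7.0)
            Q, dp = solve_segment_flow(dpt, 0.0, R, 0.0, True, params)
            Q_oracle = bisection_segment_oracle(dpt, R, params)
            assert Q == pytest.approx(Q_oracle, rel=1e-8, abs=1e-16)
            # momentum residual closes to the inner tolerance
            from lymphnet.model_core import valve_resistance
            assert dpt - dp - R * Q == pytest.approx(0.0, abs=1e-9 * max(1, abs(dpt)))
            # the valve relation amplifies the dp tolerance by ~RV/R
            assert valve_resistance(dp, params) * Q == pytest.approx(
                dp, rel=1e-6, abs=1e-4)


class TestJunction:
    def test_symmetric_children(self, params):
        pJ, (Q1, Q2, Qp) = solve_junction((5000.0, 5000.0), (2e5, 2e5),
                                          3000.0, 1e5, params)
        assert Q1 == pytest.approx(Q2, rel=1e-12)
        assert Qp == Q1 + Q2

    def test_all_pressures_equal(self, params):
        pJ, flows = solve_junction((4000.0, 4000.0), (2e5, 2e5), 4000.0, 1e5, params)
        assert pJ == pytest.approx(4000.0)
        assert np.allclose(flows, 0.0)

    def test_random_states_mass_balance(self, params, rng):
        for _ in range(50):
            pc = rng.uniform(-2e3, 2e4, 2)
            ppm = rng.uniform(-2e3, 2e4)
            Rc = 10 ** rng.uniform(5, 6.5, 2)
            Rp = 10 ** rng.uniform(5, 6.5)
            pJ, (Q1, Q2, Qp) = solve_junction(tuple(pc), tuple(Rc), ppm, Rp, params)
            qmax = max(abs(Q1), abs(Q2), abs(Qp), 1e-300)
            assert abs(Q1 + Q2 - Qp) <= 1e-12 * qmax
            # parent momentum closes at the junction-solve tolerance
            assert (pJ - ppm) - Rp * Qp == pytest.approx(0.0, abs=1e-6 * max(abs(pJ), 1))

    def test_node_pressure_matches_grid_search_oracle(self, params, rng):
        """Two-stage dense-grid search for the junction pressure, using the
        independent bisection segment oracle for the child branch flows."""
        for _ in range(5):
            pc = rng.uniform(-2e3, 2e4, 2)
            ppm = rng.uniform(-2e3, 2e4)
            Rc = 10 ** rng.uniform(5, 6.5, 2)
            Rp = 10 ** rng.uniform(5, 6.5)
            pJ, _ = solve_junction(tuple(pc), tuple(Rc), ppm, Rp, params)

            def balance(x):
                return (bisection_segment_oracle(pc[0] - x, Rc[0], params, tol=1e-10)
                        + bisection_segment_oracle(pc[1] - x, Rc[1], params, tol=1e-10)
                        - (x - ppm) / Rp)

            lo, hi = min(*pc, ppm), max(*pc, ppm)
            for _stage in range(3):  # refine the bracket around the sign change
                grid = np.linspace(lo, hi, 401)
                f = np.array([balance(x) for x in grid])
                k = int(np.argmax(f <= 0.0))  # f decreases through the root
                lo, hi = grid[max(k - 1, 0)], grid[k]
            # 4-significant-digit agreement
            assert pJ == pytest.approx(0.5 * (lo + hi),
                                       abs=(hi - lo) + 1e-4 * abs(pJ))


class TestNetworkFlowSolve:
    def test_hydrostatic_rest(self, params, small_topology, small_schedule):
        # no muscle, equal boundary pressures, passive-equilibrium diameters
        p0 = params.with_(M0=0.0)
        bc = BoundaryConditions.from_cmh2o(6.0, 6.0, 2.0)
        D = initial_diameters(small_topology, bc, p0)
        sol = network_flow_solve(0.3, D, small_topology, small_schedule, bc, p0)
        assert np.allclose(sol.seg_Q, 0.0, atol=1e-10)
        assert np.allclose(sol.junction_Q, 0.0, atol=1e-10)

    def test_mirrored_diameters_give_mirrored_flows(self, params):
        topo = build_bifurcating_network(2, 2)
        sched = contraction_schedule(topo, 0.0, 0.0, params.Tc, params.tr)
        bc = BoundaryConditions.from_cmh2o(6.0, 9.0, 2.0)
        rng = np.random.default_rng(7)
        D = np.empty(topo.n_lymphangions)
        vals = rng.uniform(0.7 * params.c9, 1.5 * params.c9, 2)
        for pos in (1, 2):
            D[topo.lymphangion_index(VesselId(2, 1), pos)] = vals[pos - 1]
            D[topo.lymphangion_index(VesselId(2, 2), pos)] = vals[pos - 1]
            D[topo.lymphangion_index(VesselId(1, 1), pos)] = 1.1 * params.c9
        sol = network_flow_solve(0.5, D, topo, sched, bc, params)
        assert sol.junction_Q[0, 0] == pytest.approx(sol.junction_Q[0, 1], rel=1e-9)

    def test_agrees_with_monolithic_oracle(self, params, small_topology,
                                           small_schedule, baseline_bc, rng):
        """Decomposed per-segment/junction solve vs simultaneous root-find on
        the full momentum + mass-balance residual vector, 50 random states."""
        for k in range(50):
            D = random_diameters(rng, params, small_topology.n_lymphangions)
            t = rng.uniform(0, small_schedule.period)
            sol = network_flow_solve(t, D, small_topology, small_schedule,
                                     baseline_bc, params)
            Qo, Qjo, pJo, res = monolithic_flow_oracle(
                t, D, small_topology, small_schedule, baseline_bc, params)
            qscale = max(np.max(np.abs(Qo)), np.max(np.abs(Qjo)))
            np.testing.assert_allclose(sol.seg_Q, Qo, rtol=1e-6,
                                       atol=1e-6 * qscale)
            np.testing.assert_allclose(sol.junction_Q[:, :2], Qjo, rtol=1e-6,
                                       atol=1e-6 * qscale)
            # node pressure is ill-conditioned where valves are shut and the
            # tube law is steep; flows above are the conditioned quantities
            pscale = float(np.max(np.abs(sol.p_mid)))
            np.testing.assert_allclose(sol.junction_p, pJo, rtol=1e-5,
                                       atol=1e-8 * pscale)

    def test_residuals_reported_small(self, params, small_topology,
                                      small_schedule, baseline_bc, rng):
        D = random_diameters(rng, params, small_topology.n_lymphangions)
        sol = network_flow_solve(1.1, D, small_topology, small_schedule,
                                 baseline_bc, params)
        assert sol.residual < 1e-8

    def test_single_lymphangion_closed_form(self, params):
        """Strong forward gradient, open valves: two-valve series chain."""
        topo = build_bifurcating_network(1, 1)
        sched = contraction_schedule(topo, 0.0, 0.0, params.Tc, params.tr)
        p0 = params.with_(M0=0.0)
        bc = BoundaryConditions(3e4, 0.0, 0.0)
        D = np.array([1.5 * params.c9])
        sol = network_flow_solve(params.Tc + 0.1, D, topo, sched, bc, p0)
        from lymphnet.model_core import passive_pressure, poiseuille_resistance
        pm = passive_pressure(D[0], p0)
        R = poiseuille_resistance(D[0], p0)
        # hand algebra with both valves open at RVn
        q_in = (bc.pa - pm) / (R + params.RVn)
        q_out = (pm - bc.pb) / (R + params.RVn)
        assert sol.seg_Q[0] == pytest.approx(q_in, rel=2e-3)
        assert sol.seg_Q[1] == pytest.approx(q_out, rel=2e-3)


class TestOdeRhs:
    def test_filling_and_steady_signs(self, params, small_topology,
                                      small_schedule, baseline_bc):
        D = initial_diameters(small_topology, baseline_bc, params)
        dD = ode_rhs(0.0, D, small_topology, small_schedule, baseline_bc, params)
        assert dD.shape == D.shape
        sol = network_flow_solve(0.0, D, small_topology, small_schedule,
                                 baseline_bc, params)
        expect = 2.0 * (sol.Q_in - sol.Q_out) / (np.pi * D * params.L)
        np.testing.assert_allclose(dD, expect, rtol=1e-12)
        assert np.all(np.sign(dD) == np.sign(sol.Q_in - sol.Q_out))

    def test_volume_consistency_along_integration(self, params, fast_settings,
                                                  baseline_bc):
        """d/dt of total stored volume equals summed inlet minus outlet flow:
        the volume ODE states must match the geometric volume change."""
        topo = build_bifurcating_network(2, 2)
        sched = contraction_schedule(topo, 0.3, 0.3, params.Tc, params.tr)
        res = run_simulation(topo, sched, baseline_bc, params, fast_settings)
        T = sched.period
        # geometric volume at the last two cycle boundaries
        k0 = np.argmin(np.abs(res.times - (res.n_cycles - 1) * T))
        V = np.pi / 4.0 * params.L * np.sum(res.diameters ** 2, axis=0)
        dV_geom = V[-1] - V[k0]
        dV_flux = (res.cycle_in_ml_hr[-1] - res.cycle_out_ml_hr[-1]) / 3600.0 * T
        # exact identity, resolved to the integrator tolerance (~rtol * V)
        assert dV_geom == pytest.approx(dV_flux, abs=5e-6 * V[-1])


class TestRunSimulation:
    def test_passive_conduit_favorable(self, params, fast_settings):
        """No muscle, favorable gradient: steady positive throughflow."""
        topo = build_bifurcating_network(3, 1)
        p0 = params.with_(M0=0.0)
        sched = contraction_schedule(topo, 0.0, 0.0, p0.Tc, p0.tr)
        bc = BoundaryConditions.from_cmh2o(6.0, 3.0, 2.0)
        res = run_simulation(topo, sched, bc, p0, fast_settings)
        assert res.converged
        assert res.qbar_ml_hr > 0.5
        q = res.outlet_flow_series()[-fast_settings.samples_per_cycle:]
        assert np.std(q) < 0.01 * np.mean(q)  # constant after transient

    def test_passive_conduit_adverse_valves_shut(self, params, fast_settings):
        topo = build_bifurcating_network(3, 1)
        p0 = params.with_(M0=0.0)
        sched = contraction_schedule(topo, 0.0, 0.0, p0.Tc, p0.tr)
        bc = BoundaryConditions.from_cmh2o(6.0, 9.0, 2.0)
        res = run_simulation(topo, sched, bc, p0, fast_settings)
        assert abs(res.qbar_ml_hr) < 1e-3

    def test_global_conservation_at_periodic_state(self, params, fast_settings,
                                                   baseline_bc):
        topo = build_bifurcating_network(3, 2)
        sched = contraction_schedule(topo, 0.5, 0.5, params.Tc, params.tr)
        res = run_simulation(topo, sched, baseline_bc, params, fast_settings)
        assert res.converged
        assert res.cycle_in_ml_hr[-1] == pytest.approx(res.cycle_out_ml_hr[-1],
                                                       rel=5e-3)

    def test_mirror_symmetry_of_branch_series(self, params, fast_settings,
                                              baseline_bc):
        topo = build_bifurcating_network(3, 2)
        sched = contraction_schedule(topo, 0.5, 0.5, params.Tc, params.tr)
        res = run_simulation(topo, sched, baseline_bc, params, fast_settings)
        for left, right in ((VesselId(3, 1), VesselId(3, 3)),
                            (VesselId(2, 1), VesselId(2, 2))):
            for pos in (1, 2):
                i = res.topology.lymphangion_index(left, pos)
                j = res.topology.lymphangion_index(right, pos)
                np.testing.assert_allclose(res.diameters[i], res.diameters[j],
                                           rtol=1e-6)

    def test_phase_shift_invariance(self, params, fast_settings, baseline_bc):
        """A rigid shift of every contraction start leaves Q-bar unchanged."""
        topo = build_bifurcating_network(2, 2)
        sched = contraction_schedule(topo, 0.5, 0.5, params.Tc, params.tr)
        res = run_simulation(topo, sched, baseline_bc, params, fast_settings)
        res2 = run_simulation(topo, sched.shifted(0.8), baseline_bc, params,
                              fast_settings)
        assert res2.qbar_ml_hr == pytest.approx(res.qbar_ml_hr, rel=0.01)

    def test_initial_condition_immaterial(self, params, fast_settings,
                                          baseline_bc):
        topo = build_bifurcating_network(2, 2)
        sched = contraction_schedule(topo, 0.5, 0.5, params.Tc, params.tr)
        res = run_simulation(topo, sched, baseline_bc, params, fast_settings)
        D0 = 1.15 * initial_diameters(topo, baseline_bc, params)
        res2 = run_simulation(topo, sched, baseline_bc, params, fast_settings,
                              D0=D0)
        assert res2.qbar_ml_hr == pytest.approx(res.qbar_ml_hr, rel=0.01)

    def test_diameters_stay_positive(self, params, fast_settings, baseline_bc):
        topo = build_bifurcating_network(2, 2)
        sched = contraction_schedule(topo, 0.5, 0.5, params.Tc, params.tr)
        res = run_simulation(topo, sched, baseline_bc, params, fast_settings)
        assert res.diameters.min() > 0


class TestAveraging:
    def _fake_result(self, cycle_means):
        return SimulationResult(
            topology=None, schedule=None, bc=None, params=None, settings=None,
            times=None, diameters=None,
            cycle_out_ml_hr=np.asarray(cycle_means, float),
            cycle_in_ml_hr=np.asarray(cycle_means, float),
            converged=True, n_cycles=len(cycle_means), final_state=None)

    def test_mean_outlet_flow_windows(self):
        res = self._fake_result([5.0, 2.0, 2.0, 2.0])
        assert mean_outlet_flow(res) == 2.0
        assert mean_outlet_flow(res, periods=2) == 2.0
        with pytest.raises(ValueError):
            mean_outlet_flow(res, periods=9)

    def test_periodic_time_average(self):
        t = np.linspace(0.0, 7.0, 4001)
        q = np.full_like(t, 3.0e-4)
        assert periodic_time_average(t, q, 3.5) == pytest.approx(3.0e-4)
        q = np.sin(2 * np.pi * t / 3.5)
        assert periodic_time_average(t, q, 3.5) == pytest.approx(0.0, abs=1e-6)
        with pytest.raises(ValueError):
            periodic_time_average(t[:3000], q[:3000], 3.5)

    def test_averaging_window_stability_at_convergence(self, params,
                                                       fast_settings,
                                                       baseline_bc):
        topo = build_bifurcating_network(2, 2)
        sched = contraction_schedule(topo, 0.5, 0.5, params.Tc, params.tr)
        res = run_simulation(topo, sched, baseline_bc, params, fast_settings)
        assert mean_outlet_flow(res, 2) == pytest.approx(
            mean_outlet_flow(res, 1), rel=5e-3)
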
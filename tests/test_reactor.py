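"""Reactor balances, feed schedules and the simulation driver."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from fedbatch_mab.kinetics import CultureState, reaction_terms
from fedbatch_mab.reactor import (
    FeedArc,
    FeedPolicy,
    ReactorState,
    ScenarioDefinition,
    SolverOptions,
    TRAJECTORY_COLUMNS,
    build_initial_state,
    controls_at,
    ode_rhs,
    simulate,
)

from conftest import random_policy

MU_SPBR = 0.05509107460069346  # frozen kinetics oracle (see test_kinetics)


class TestFeedPolicy:
    def test_equal_arcs_switch_times(self):
        arcs = [FeedArc(1e-3, 50, 10, 1e9)] * 5
        p = FeedPolicy.equal_arcs(100.0, arcs)
        assert p.switch_times == (20.0, 40.0, 60.0, 80.0)
        assert p.arc_durations == (20.0,) * 5

    def test_needs_at_least_one_arc(self):
        with pytest.raises(ValueError, match="at least one arc"):
            FeedPolicy(t_f=100.0, arcs=(), switch_times=())

    def test_rejects_unsorted_switches(self):
        arcs = (FeedArc(0, 1, 1, 1), FeedArc(0, 1, 1, 1))
        with pytest.raises(ValueError, match="increasing"):
            FeedPolicy(t_f=100.0, arcs=arcs, switch_times=(150.0,))

    def test_rejects_negative_controls(self):
        with pytest.raises(ValueError):
            FeedArc(F_L=-1e-3, GLC_in=1, GLN_in=1, Xv_in=1)


class TestControlsAt:
    def test_first_arc_values(self, scenarios):
        arc = controls_at(scenarios["SP1"].policy, 0.0)
        assert arc.F_L == 1e-3 and arc.GLC_in == 96.62

    def test_switch_instant_belongs_to_later_arc(self, scenarios):
        # arcs are left-closed/right-open
        arc = controls_at(scenarios["SP1"].policy, 20.0)
        assert arc.F_L == 9.55e-3

    def test_final_time_maps_to_last_arc(self, scenarios):
        arc = controls_at(scenarios["SP1"].policy, 100.0)
        assert arc.GLC_in == 68.42

    def test_outside_window_rejected(self, scenarios):
        for t in (-0.1, 100.1):
            with pytest.raises(ValueError, match="outside"):
                controls_at(scenarios["SP1"].policy, t)

    def test_identical_arcs_give_constant_controls(self):
        p = FeedPolicy.equal_arcs(60.0, [FeedArc(2e-3, 40, 8, 5e8)] * 3)
        values = {controls_at(p, t) for t in np.linspace(0, 60, 13)}
        assert len(values) == 1


class TestInitialState:
    def test_batch_reference_start(self, scenarios):
        s = build_initial_state(scenarios["SPBR"])
        c = s.culture
        assert (c.Xv, c.Xt, c.GLC, c.GLN) == (2e8, 2e8, 29.1, 4.9)
        assert (c.LAC, c.AMM, c.mAb) == (0.0, 0.31, 80.6)
        assert s.V_L == 1.0

    def test_inlet_coupling_uses_first_arc(self, scenarios):
        c = build_initial_state(scenarios["SP2"]).culture
        assert c.Xv == 4.38e9 and c.Xt == c.Xv
        assert c.GLC == 141.63 and c.GLN == 17.76

    def test_zero_inlet_first_arc_gives_zero_substrate(self, params):
        policy = FeedPolicy.equal_arcs(10.0, [FeedArc(0.0, 0.0, 0.0, 0.0)])
        sc = ScenarioDefinition(name="empty", params=params, policy=policy)
        c = build_initial_state(sc).culture
        assert c.GLC == 0.0 and c.GLN == 0.0 and c.Xv == 0.0


class TestOdeRhs:
    def test_batch_limit_equals_reaction_terms(self, scenarios, params):
        sc = scenarios["SPBR"]
        state = build_initial_state(sc)
        dy = ode_rhs(0.0, state, sc.policy, params)
        np.testing.assert_allclose(
            dy[:7], reaction_terms(state.culture, params), rtol=1e-12)
        assert dy[7] == 0.0

    def test_mab_rate_at_batch_start(self, scenarios, params):
        sc = scenarios["SPBR"]
        dy = ode_rhs(0.0, build_initial_state(sc), sc.policy, params)
        expected = (2 - params.gamma * MU_SPBR) * params.lambda_mab * 2e8
        assert dy[6] == pytest.approx(expected, rel=1e-9)

    def test_no_cells_only_decay_and_dilution(self, params):
        policy = FeedPolicy.equal_arcs(
            10.0, [FeedArc(0.0, 0.0, 0.0, 0.0)])
        culture = CultureState(Xv=0, Xt=0, GLC=0, GLN=2.0, LAC=0, AMM=0,
                               mAb=0)
        dy = ode_rhs(0.0, ReactorState(culture, 1.0), policy, params)
        assert dy[3] == pytest.approx(-params.K_d_gln * 2.0, rel=1e-12)
        assert dy[5] == pytest.approx(params.K_d_gln * 2.0, rel=1e-12)
        assert dy[[0, 1, 2, 4, 6, 7]] == pytest.approx(0.0)

    def test_strict_printed_xt_changes_only_xt(self, scenarios, params):
        sc = scenarios["SP1"]
        state = build_initial_state(sc)
        std = ode_rhs(5.0, state, sc.policy, params)
        strict = ode_rhs(5.0, state, sc.policy, params,
                         strict_printed_xt=True)
        keep = [i for i in range(8) if i != 1]
        np.testing.assert_array_equal(std[keep], strict[keep])
        # at t=0 Xt = Xv so both forms agree; perturb Xt to see the switch
        bumped = ReactorState(
            dataclasses.replace(state.culture, Xt=3e8), state.V_L)
        assert ode_rhs(5.0, bumped, sc.policy, params)[1] != \
            ode_rhs(5.0, bumped, sc.policy, params, strict_printed_xt=True)[1]


class TestSimulate:
    def test_grid_covers_batch_and_switches(self, trajectories, scenarios):
        traj = trajectories["SP1"]
        assert traj.times[0] == 0.0 and traj.times[-1] == 100.0
        for t_switch in scenarios["SP1"].policy.switch_times:
            assert np.any(np.isclose(traj.times, t_switch))

    def test_concentrations_stay_nonnegative(self, trajectories):
        for traj in trajectories.values():
            assert traj.states.min() >= -1e-9

    def test_bit_for_bit_reproducible(self, scenarios):
        a = simulate(scenarios["SP3"])
        b = simulate(scenarios["SP3"])
        np.testing.assert_array_equal(a.states, b.states)

    def test_batch_equivalence_to_pure_kinetics(self, scenarios, params):
        """Zero-feed simulation must coincide with an independent
        integration of the reaction terms alone."""
        sc = scenarios["SPBR"]
        opts = SolverOptions(rtol=1e-10, atol=1e-12)
        traj = simulate(sc, opts)

        y0 = build_initial_state(sc).culture.as_array()
        y0[:2] /= 1e9  # same conditioning as the reactor driver

        def rhs(t, y):
            s = CultureState(y[0] * 1e9, y[1] * 1e9, *y[2:])
            r = reaction_terms(s, params)
            r[:2] /= 1e9
            return r

        ref = solve_ivp(rhs, (0, 100), y0, method="BDF", rtol=1e-10,
                        atol=1e-12, t_eval=traj.times)
        ref_states = ref.y.T.copy()
        ref_states[:, :2] *= 1e9
        scale = np.abs(ref_states).max(axis=0)
        err = np.abs(traj.states[:, :7] - ref_states) / scale
        assert err.max() <= 1e-8

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_volume_matches_closed_form(self, params, seed):
        rng = np.random.default_rng(seed)
        policy = random_policy(rng)
        sc = ScenarioDefinition(name="rand", params=params, policy=policy,
                                mAb_0=80.6, AMM_0=0.31)
        traj = simulate(sc, SolverOptions(samples_per_arc=50))
        bounds = np.array(policy.arc_bounds)
        fl = np.array([a.F_L for a in policy.arcs])
        overlap = (np.minimum(traj.times[:, None], bounds[None, :, 1])
                   - bounds[None, :, 0]).clip(min=0.0)
        expected = sc.V_L0 + (overlap * fl).sum(axis=1)
        np.testing.assert_allclose(traj.volume, expected, rtol=1e-9)

    def test_total_mab_mass_non_decreasing(self, trajectories):
        for name, traj in trajectories.items():
            mass = traj.mab * traj.volume
            assert np.all(np.diff(mass) >= -1e-7 * mass.max()), name

    def test_glucose_bookkeeping_integral_identity(self, scenarios, params):
        """Fed glucose minus in-vessel change equals the integral of
        cellular uptake (trapezoidal quadrature on the dense output)."""
        from fedbatch_mab.kinetics import (glucose_uptake_rate,
                                           specific_growth_rate)
        for name in ("SPBR", "SP1", "SP3"):
            sc = scenarios[name]
            traj = simulate(sc, SolverOptions(samples_per_arc=800))
            glc, xv, v = (traj.species("GLC"), traj.species("Xv"),
                          traj.volume)
            uptake = np.empty_like(glc)
            for i in range(traj.times.size):
                s = CultureState(*traj.states[i, :7])
                mu = specific_growth_rate(s, params)
                uptake[i] = glucose_uptake_rate(mu, params) * xv[i] * v[i]
            consumed = np.trapezoid(uptake, traj.times)
            fed_total = sum(
                a.F_L * a.GLC_in * dt
                for a, dt in zip(sc.policy.arcs, sc.policy.arc_durations))
            balance = sc.V_L0 * glc[0] + fed_total - v[-1] * glc[-1]
            assert balance == pytest.approx(consumed, rel=1e-5), name

    def test_no_synthesis_means_dilution_only(self, scenarios, params):
        p0 = dataclasses.replace(params, lambda_mab=0.0)
        sc = dataclasses.replace(scenarios["SP1"], params=p0)
        traj = simulate(sc)
        assert np.all(np.diff(traj.mab) <= 1e-12)
        assert traj.mab[0] == pytest.approx(80.6)

    def test_tolerance_robustness(self, scenarios, trajectories,
                                  tight_options):
        from fedbatch_mab.metrics import max_mab
        for name, sc in scenarios.items():
            loose = max_mab(trajectories[name])[0]
            tight = max_mab(simulate(sc, tight_options))[0]
            assert abs(tight - loose) / loose < 1e-3, name

    def test_dataframe_round_trip(self, trajectories, tmp_path):
        import pandas as pd
        traj = trajectories["SP3"]
        df = traj.to_dataframe()
        assert tuple(df.columns) == TRAJECTORY_COLUMNS
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = pd.read_csv(path)
        np.testing.assert_allclose(back["mAb_mg_per_L"], traj.mab,
                                   rtol=1e-12)
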
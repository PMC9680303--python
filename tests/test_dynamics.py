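"""Transient cascade: analytic product form, exact ODE integration and the
relationship between the two."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from biofiltersim import (
    InletSchedule,
    cascade_outlet,
    fixtures,
    removal_efficiency,
    segment_response,
    simulate_cascade_ode,
    steady_state_outlet,
)

# long enough that (1 - exp(-gamma2*t))^n is within 1e-12 of 1 for benzene
T_SETTLED = 300.0


class TestInletSchedule:
    def test_must_start_at_zero(self):
        with pytest.raises(ValueError, match="t = 0"):
            InletSchedule(breakpoints=[10.0], levels=[0.1])

    def test_breakpoints_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            InletSchedule(breakpoints=[0.0, 5.0, 5.0], levels=[0.1, 0.2, 0.3])

    def test_negative_levels_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            InletSchedule(breakpoints=[0.0], levels=[-0.1])

    def test_right_continuous_lookup(self):
        s = InletSchedule(breakpoints=[0.0, 10.0], levels=[0.1, 0.2])
        assert s.level_at(0.0) == 0.1
        assert s.level_at(9.999) == 0.1
        assert s.level_at(10.0) == 0.2
        assert s.level_at(1e6) == 0.2

    def test_random_schedule_seeded_and_bounded(self):
        a = InletSchedule.random_uniform(0.05, 0.2, 50.0, 500.0, seed=7)
        b = InletSchedule.random_uniform(0.05, 0.2, 50.0, 500.0, seed=7)
        np.testing.assert_array_equal(a.levels, b.levels)
        assert np.all((a.levels >= 0.05) & (a.levels <= 0.2))
        assert a.breakpoints[0] == 0.0 and a.breakpoints[-1] < 500.0


class TestAnalyticForms:
    def test_segment_starts_clean(self, benzene_derived):
        assert segment_response(0.13, benzene_derived.gamma1, benzene_derived.gamma2, 0.0) == 0.0

    def test_segment_saturates_to_gamma1_fraction(self, benzene_derived):
        d = benzene_derived
        assert segment_response(0.13, d.gamma1, d.gamma2, 1e6) == pytest.approx(
            0.13 * d.gamma1, rel=1e-12)

    def test_negative_time_rejected(self, benzene_derived):
        with pytest.raises(ValueError):
            segment_response(0.13, benzene_derived.gamma1, benzene_derived.gamma2, -1.0)
        with pytest.raises(ValueError):
            cascade_outlet(0.13, benzene_derived.gamma1, benzene_derived.gamma2, 10, -1.0)

    def test_single_segment_cascade_reduces_to_segment(self, benzene_derived):
        d = benzene_derived
        t = np.linspace(0.0, 100.0, 23)
        np.testing.assert_allclose(
            cascade_outlet(0.13, d.gamma1, d.gamma2, 1, t),
            segment_response(0.13, d.gamma1, d.gamma2, t), rtol=1e-15)

    def test_cascade_steady_limit(self, benzene_derived):
        d = benzene_derived
        for n in (1, 5, 10):
            assert cascade_outlet(0.13, d.gamma1, d.gamma2, n, 1e6) == pytest.approx(
                steady_state_outlet(0.13, d.gamma1, n), rel=1e-12)

    def test_invalid_segment_count_rejected(self, benzene_derived):
        d = benzene_derived
        with pytest.raises(ValueError):
            cascade_outlet(0.13, d.gamma1, d.gamma2, 0, 10.0)
        with pytest.raises(ValueError):
            steady_state_outlet(0.13, d.gamma1, 0)

    def test_removal_efficiency(self):
        assert removal_efficiency(0.13, 0.104) == pytest.approx(0.2, rel=1e-10)
        assert np.isnan(removal_efficiency(0.0, 0.0))


class TestCascadeODE:
    def test_constant_inlet_reaches_analytic_steady_state(self, benzene_derived, benzene_bed):
        res = simulate_cascade_ode(benzene_derived, benzene_bed,
                                   InletSchedule.constant(0.13), t_end=T_SETTLED)
        expected = steady_state_outlet(0.13, benzene_derived.gamma1, benzene_bed.n_segments)
        assert res.outlet[-1] == pytest.approx(expected, rel=1e-9)
        assert res.steady_outlet == pytest.approx(expected, rel=1e-15)

    def test_zero_inlet_stays_clean(self, benzene_derived, benzene_bed):
        res = simulate_cascade_ode(benzene_derived, benzene_bed,
                                   InletSchedule.constant(0.0), t_end=100.0)
        assert np.all(res.segment_conc == 0.0)

    def test_outlet_monotone_and_bounded_for_constant_inlet(self, benzene_derived, benzene_bed):
        res = simulate_cascade_ode(benzene_derived, benzene_bed,
                                   InletSchedule.constant(0.13), t_end=T_SETTLED)
        assert np.all(np.diff(res.outlet) >= -1e-15)
        assert np.all(res.outlet <= res.steady_outlet * (1.0 + 1e-12))
        assert np.all(res.segment_conc >= 0.0)

    def test_concentration_decreases_along_bed_at_steady_state(self, benzene_derived, benzene_bed):
        res = simulate_cascade_ode(benzene_derived, benzene_bed,
                                   InletSchedule.constant(0.13), t_end=T_SETTLED)
        final = res.segment_conc[-1]
        assert np.all(np.diff(final) < 0.0)

    def test_single_segment_matches_analytic_transient(self, benzene_derived):
        bed = fixtures.benzene_bed(n_segments=1)
        res = simulate_cascade_ode(benzene_derived, bed, InletSchedule.constant(0.13),
                                   t_end=50.0, dt_out=0.5)
        analytic = segment_response(0.13, benzene_derived.gamma1, benzene_derived.gamma2,
                                    res.times)
        np.testing.assert_allclose(res.outlet[1:], analytic[1:], rtol=1e-8)

    def test_steady_mass_balance_per_segment(self, benzene_derived, benzene_bed,
                                             benzene_compound):
        res = simulate_cascade_ode(benzene_derived, benzene_bed,
                                   InletSchedule.constant(0.13), t_end=T_SETTLED)
        c = np.concatenate([[0.13], res.segment_conc[-1]])
        ug = benzene_bed.superficial_velocity_ug
        dh = benzene_bed.segment_length
        hprime = benzene_compound.henry_dimensionless
        convective = ug * (c[:-1] - c[1:])
        uptake = dh * benzene_derived.flux_coeff * c[1:] / hprime
        np.testing.assert_allclose(convective, uptake, rtol=1e-9)

    def test_steady_state_independent_of_void_fraction(self, benzene_compound, benzene_biofilm):
        from biofiltersim import compute_gammas
        finals = []
        for eps in (0.2, 0.35, 0.6):
            bed = fixtures.benzene_bed(void_fraction_eps=eps)
            d = compute_gammas(benzene_compound, benzene_biofilm, bed)
            res = simulate_cascade_ode(d, bed, InletSchedule.constant(0.13), t_end=600.0)
            finals.append(res.outlet[-1])
        np.testing.assert_allclose(finals, finals[0], rtol=1e-9)

    def test_transient_depends_on_void_fraction(self, benzene_compound, benzene_biofilm):
        from biofiltersim import compute_gammas
        mid = []
        for eps in (0.2, 0.6):
            bed = fixtures.benzene_bed(void_fraction_eps=eps)
            d = compute_gammas(benzene_compound, benzene_biofilm, bed)
            res = simulate_cascade_ode(d, bed, InletSchedule.constant(0.13),
                                       t_end=20.0, dt_out=20.0)
            mid.append(res.outlet[-1])
        assert mid[0] != pytest.approx(mid[1], rel=1e-3)

    def test_step_down_relaxes_to_new_steady_state(self, benzene_derived, benzene_bed):
        sched = InletSchedule(breakpoints=[0.0, 300.0], levels=[0.13, 0.065])
        res = simulate_cascade_ode(benzene_derived, benzene_bed, sched, t_end=700.0, dt_out=1.0)
        new_ss = steady_state_outlet(0.065, benzene_derived.gamma1, benzene_bed.n_segments)
        assert res.outlet[-1] == pytest.approx(new_ss, rel=1e-9)
        # after the step and a transport lag the outlet decays monotonically
        tail = res.outlet[res.times > 320.0]
        assert np.all(np.diff(tail) <= 1e-15)

    def test_schedule_beyond_horizon_rejected(self, benzene_derived, benzene_bed):
        sched = InletSchedule(breakpoints=[0.0, 500.0], levels=[0.1, 0.2])
        with pytest.raises(ValueError, match="beyond"):
            simulate_cascade_ode(benzene_derived, benzene_bed, sched, t_end=100.0)

    def test_matches_independent_integrator_on_step_schedule(self, benzene_derived):
        # dual-route check: expm propagation vs scipy solve_ivp
        d = benzene_derived
        bed = fixtures.benzene_bed(n_segments=4)
        sched = InletSchedule(breakpoints=[0.0, 40.0, 80.0], levels=[0.13, 0.02, 0.09])
        res = simulate_cascade_ode(d, bed, sched, t_end=120.0, dt_out=2.0)
        a = d.gamma1 * d.gamma2

        # integrate interval by interval so the step discontinuities are exact
        state = np.zeros(4)
        ref = {0.0: state.copy()}
        edges = [0.0, 40.0, 80.0, 120.0]
        for lo, hi in zip(edges[:-1], edges[1:]):
            u = sched.level_at(lo)

            def rhs(t, c):
                upstream = np.concatenate([[u], c[:-1]])
                return a * upstream - d.gamma2 * c

            t_eval = res.times[(res.times > lo) & (res.times <= hi)]
            sol = solve_ivp(rhs, (lo, hi), state, t_eval=np.unique(np.append(t_eval, hi)),
                            rtol=1e-11, atol=1e-14)
            for t, col in zip(sol.t, sol.y.T):
                ref[float(t)] = col
            state = sol.y[:, -1]

        ref_mat = np.vstack([ref[float(t)] for t in res.times])
        np.testing.assert_allclose(res.segment_conc, ref_mat, rtol=1e-6, atol=1e-10)


class TestProductFormApproximation:
    """For n > 1 the product form is not the exact cascade transient; the
    gap is real at intermediate times and closes at both time extremes."""

    def test_gap_is_nonzero_at_intermediate_times(self, benzene_derived, benzene_bed):
        d = benzene_derived
        res = simulate_cascade_ode(d, benzene_bed, InletSchedule.constant(0.13),
                                   t_end=30.0, dt_out=1.0)
        analytic = cascade_outlet(0.13, d.gamma1, d.gamma2, benzene_bed.n_segments, res.times)
        gap = np.max(np.abs(analytic - res.outlet))
        # the product form leads the true transient by a measurable margin
        assert gap > 1e-4
        assert np.all(analytic[1:] >= res.outlet[1:])

    def test_gap_vanishes_at_long_times(self, benzene_derived, benzene_bed):
        d = benzene_derived
        res = simulate_cascade_ode(d, benzene_bed, InletSchedule.constant(0.13),
                                   t_end=400.0, dt_out=400.0)
        analytic = cascade_outlet(0.13, d.gamma1, d.gamma2, benzene_bed.n_segments, 400.0)
        assert res.outlet[-1] == pytest.approx(analytic, rel=1e-9)

    def test_gap_vanishes_at_short_times(self, benzene_derived, benzene_bed):
        d = benzene_derived
        res = simulate_cascade_ode(d, benzene_bed, InletSchedule.constant(0.13),
                                   t_end=0.1, dt_out=0.01)
        analytic = cascade_outlet(0.13, d.gamma1, d.gamma2, benzene_bed.n_segments, res.times)
        assert np.max(np.abs(analytic - res.outlet)) < 1e-12
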
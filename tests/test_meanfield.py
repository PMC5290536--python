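"""Mean-field theory: CDN probability, rate equations, roots, spinodals, cusp."""

from fractions import Fraction

import numpy as np
import pytest
import sympy

import failrecov as fr
from failrecov.meanfield import (
    MeanFieldState,
    _stationary_poly,
    cdn_polynomial,
    spinodals,
)


class TestCdnProbability:
    def test_all_failed_neighborhood_certain(self):
        assert fr.cdn_probability(1.0, 4, 1) == pytest.approx(1.0)

    def test_binomial_enumeration_k4_m1_half(self):
        # sum_{j<=1} C(4,j) 0.5^j 0.5^(4-j) = (1+4) * 0.5^4
        assert fr.cdn_probability(0.5, 4, 1) == pytest.approx(0.3125)

    def test_m_at_least_k_is_one_everywhere(self):
        for a in (0.0, 0.3, 1.0):
            assert fr.cdn_probability(a, 4, 4) == pytest.approx(1.0)
            assert fr.cdn_probability(a, 4, 7) == pytest.approx(1.0)

    def test_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fr.cdn_probability(1.2, 4, 1)

    def test_monotone_nondecreasing_below_k(self):
        a = np.linspace(0, 1, 201)
        E = fr.cdn_probability(a, 4, 1)
        assert np.all(np.diff(E) >= -1e-12)
        assert np.all((E >= 0) & (E <= 1))

    def test_mixed_degree_distribution(self):
        fk = {1: 2 / 3, 2: 1 / 3}
        # E = (2/3) * a  +  (1/3) * a^2   for m = 0
        assert fr.cdn_probability(0.5, fk, 0) == pytest.approx(2 / 3 * 0.5 + 1 / 3 * 0.25)


class TestRhs:
    P = fr.ModelParams(p=0.9, r=0.95, q=1.0, q_prime=0.1, m=1)

    def test_all_active_derivative(self):
        d_int, d_ext = fr.rhs(MeanFieldState(0.0, 0.0), self.P, 4)
        assert d_int == pytest.approx(self.P.p)
        assert d_ext == pytest.approx(0.0)  # E(0) = 0 for m < k

    def test_decoupled_internal_fixed_point(self):
        params = fr.ModelParams(p=0.4, r=0.0, q=1.0, q_prime=0.5, m=1)
        a_star = 0.4 / 1.4
        d = fr.rhs(MeanFieldState(a_star, 0.0), params, 4)
        assert abs(d[0]) < 1e-12 and abs(d[1]) < 1e-12

    def test_m_above_k_closed_form_fixed_point(self):
        params = fr.ModelParams(p=0.25, r=0.375, q=1.0, q_prime=0.5, m=5)
        s = 0.25 + 0.75
        a = s / (1 + s)
        st = MeanFieldState(0.25 * (1 - a), 0.75 * (1 - a))
        d = fr.rhs(st, params, 4)
        assert abs(d[0]) < 1e-12 and abs(d[1]) < 1e-12


class TestIntegrate:
    def test_no_failure_stays_all_active(self):
        params = fr.ModelParams(p=0.0, r=0.0, q=1.0, q_prime=1.0, m=1)
        traj = fr.integrate(params, 4, t_max=10, dt_out=0.5)
        assert np.allclose(traj.a, 0.0, atol=1e-10)

    def test_external_failures_take_over(self):
        # high-density operating point with r/q' >> p/q: internal failures
        # rise first, induced failures dominate the stationary state
        params = fr.ModelParams(p=0.9, r=0.95, q=1.0, q_prime=0.1, m=1)
        traj = fr.integrate(params, 4, t_max=200, dt_out=0.05)
        early = traj.times <= 0.5
        assert np.all(traj.u_int[early] >= traj.u_ext[early] - 1e-12)
        assert traj.u_ext[-1] > traj.u_int[-1]

    def test_trajectory_stays_in_simplex(self):
        params = fr.ModelParams(p=0.5, r=3.0, q=1.0, q_prime=0.1, m=1)
        traj = fr.integrate(params, 4, t_max=100, dt_out=0.1)
        assert np.all(traj.u_int >= -1e-9)
        assert np.all(traj.u_ext >= -1e-9)
        assert np.all(traj.a <= 1 + 1e-9)

    def test_limit_cycle_operating_point_oscillates(self):
        fx = fr.make_fixture("limit-cycle")
        traj = fr.integrate(fx.params, 4, t_max=4000, dt_out=1.0)
        late = traj.z[traj.times > 2000]
        assert late.max() - late.min() > 0.1  # sustained, not damped


class TestStationaryStates:
    def test_pure_internal_balance(self):
        br = fr.stationary_states(1.0, 0.0, 4, 1)
        assert br.a_values == pytest.approx([0.5], abs=1e-10)

    def test_m_above_k_unique_root(self):
        br = fr.stationary_states(0.25, 0.75, 4, 5)
        assert br.a_values == pytest.approx([0.5], abs=1e-10)

    def test_cusp_point_is_triple_root(self):
        P, R = 19 / 81, 3125 / 1296
        br = fr.stationary_states(P, R, 4, 1)
        assert any(abs(a - 0.4) < 1e-6 for a in br.a_values)
        F = _stationary_poly(P, R, 4, 1)
        assert abs(F(0.4)) < 1e-12
        assert abs(F.deriv()(0.4)) < 1e-12
        assert abs(F.deriv(2)(0.4)) < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_scan_finds_all_polynomial_roots(self, seed):
        # brute-force oracle: expand F as a polynomial and take numpy roots
        rng = np.random.default_rng(seed)
        P = rng.uniform(0, 0.6)
        R = rng.uniform(0, 12.0)
        br = fr.stationary_states(P, R, 4, 1)
        F = _stationary_poly(P, R, 4, 1)
        ref = sorted(
            float(z.real)
            for z in F.roots()
            if abs(z.imag) < 1e-9 and -1e-9 <= z.real <= 1 + 1e-9
        )
        assert len(br.a_values) == len(ref)
        assert br.a_values == pytest.approx(ref, abs=1e-7)

    def test_depends_only_on_effective_rates(self):
        a1 = fr.stationary_states(0.2, 5.0, 4, 1).a_values
        a2 = fr.stationary_states(0.2, 5.0, 4, 1, params_abs=(3.0, 0.07)).a_values
        assert a1 == pytest.approx(a2, abs=1e-10)

    def test_smallest_root_monotone_in_p(self):
        R = 5.0
        lows = [min(fr.stationary_states(P, R, 4, 1).a_values)
                for P in np.linspace(0.01, 0.5, 25)]
        assert np.all(np.diff(lows) >= -1e-9)

    def test_stability_labels_in_bistable_wedge(self):
        # interior of the k=4, m=1 wedge: two stable states flank one unstable
        br = fr.stationary_states(0.06, 5.0, 4, 1, params_abs=(1.0, 0.1))
        assert len(br.roots) == 3
        assert br.labels == ["stable", "unstable", "stable"]


class TestCusp:
    def test_exact_rational_values_k4_m1(self):
        a, P, R = fr.cusp_point_exact(4, 1)
        assert a == sympy.Rational(2, 5)
        assert P == sympy.Rational(19, 81)
        assert R == sympy.Rational(3125, 1296)

    def test_numeric_agrees_with_exact(self):
        a, P, R = fr.cusp_point(4, 1)
        assert a == pytest.approx(float(Fraction(2, 5)), abs=1e-10)
        assert P == pytest.approx(float(Fraction(19, 81)), abs=1e-10)
        assert R == pytest.approx(float(Fraction(3125, 1296)), abs=1e-10)

    def test_no_bistability_when_m_reaches_degree(self):
        with pytest.raises(ValueError):
            fr.cusp_point(1, 1)
        with pytest.raises(ValueError):
            fr.cusp_point_exact(1, 1)

    def test_k10_m4_cusp_terminates_both_spinodals(self):
        a, P, R = fr.cusp_point(10, 4)
        assert 0 < a < 1 and P > 0 and R > 0
        sp = fr.spinodals(10, 4)
        assert sp.upper[0, 0] == pytest.approx(R, rel=1e-3)
        assert sp.lower[0, 0] == pytest.approx(R, rel=1e-3)
        assert sp.upper[0, 1] == pytest.approx(P, rel=1e-2)


class TestSpinodals:
    def test_curves_exist_only_beyond_cusp(self):
        sp = fr.spinodals(4, 1)
        r_c = 3125 / 1296
        assert sp.cusp[2] == pytest.approx(r_c, abs=1e-9)
        assert sp.upper[:, 0].min() >= r_c - 1e-6
        assert sp.lower[:, 0].min() >= r_c - 1e-6

    def test_two_branches_ordered_at_r5(self):
        sp = fr.spinodals(4, 1)
        pu = np.interp(5.0, sp.upper[:, 0], sp.upper[:, 1])
        pl = np.interp(5.0, sp.lower[:, 0], sp.lower[:, 1])
        assert pu > pl > 0

    def test_saddle_node_conditions_hold_on_curves(self):
        # every stored (r/q', p/q, a) triple satisfies F = F' = 0
        sp = fr.spinodals(4, 1)
        for curve in (sp.upper, sp.lower):
            for R, P, a in curve[:: max(len(curve) // 50, 1)]:
                F = _stationary_poly(P, R, 4, 1)
                assert abs(F(a)) < 1e-9
                assert abs(F.deriv()(a)) < 1e-9

    def test_hysteresis_area_properties(self):
        sp = fr.spinodals(4, 1)
        below = fr.hysteresis_area(sp, ((0.0, 2.0), (0.0, 1.0)))
        assert below == 0.0
        window = ((0.0, 10.0), (0.0, 0.5))
        area = fr.hysteresis_area(sp, window)
        assert area > 0
        wider = fr.hysteresis_area(sp, ((0.0, 20.0), (0.0, 0.5)))
        assert wider >= area


class TestClassifyPhase:
    def test_low_phase_weak_failure(self):
        assert fr.classify_phase(0.01, 0.0, 1.0, 0.1, 4, 1) == "LOW"

    def test_bistable_interior(self):
        assert fr.classify_phase(0.06, 5.0, 1.0, 0.1, 4, 1) == "BISTABLE"

    def test_high_phase_strong_failure(self):
        assert fr.classify_phase(2.0, 5.0, 1.0, 0.1, 4, 1) == "HIGH"

    def test_oscillatory_for_fast_external_recovery(self):
        fx = fr.make_fixture("limit-cycle")
        label = fr.classify_phase(19 / 81, 3125 / 1296, 0.01, 1.0, 4, 1, t_max=4000)
        assert label == "OSCILLATORY"
        assert fx.expected["oscillatory"]


def test_simulator_agrees_with_meanfield_on_rrg():
    # monostable low-density point; perfect mixing is a good approximation
    # on a large random regular graph
    net = fr.make_regular_random_graph(10000, 4, seed=2)
    params = fr.ModelParams(p=0.15, r=0.2, q=1.0, q_prime=0.1, m=1)
    br = fr.stationary_states(0.15, 2.0, 4, 1)
    assert len(br.a_values) == 1
    traj = fr.run_gillespie(net, params, t_max=400, sample_dt=1.0, seed=3)
    keep = traj.times >= 200
    assert traj.a[keep].mean() == pytest.approx(br.a_values[0], abs=0.02)
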
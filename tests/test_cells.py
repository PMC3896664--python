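"""Apoptosis switches, bifurcation structure, trigger gating and the
logistic density dynamics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import tumordrugsim as td


@pytest.fixture(scope="module")
def ip(params):
    return td.to_internal_units(params)


class TestBistableRhs:
    def test_value_at_origin(self, params):
        # Vf/(Km1 + 1) = 27/101 per hour
        assert td.bistable_rhs(0.0, 0.0, params) == pytest.approx(
            0.267327, rel=1e-5)

    def test_value_at_saturation(self, params):
        # only the decay term survives at R = 1
        assert td.bistable_rhs(1.0, 5.0, params) == pytest.approx(
            -0.454455, rel=1e-5)

    def test_time_units_follow_parameter_object(self, params, ip):
        assert td.bistable_rhs(0.3, 0.5, ip) * 3600 == pytest.approx(
            td.bistable_rhs(0.3, 0.5, params), rel=1e-12)

    def test_sign_change_guarantees_interior_root(self, params):
        assert td.bistable_rhs(0.0, 0.0, params) > 0
        assert td.bistable_rhs(1.0, 0.0, params) < 0


class TestMonostable:
    def test_pure_decay_without_drug(self, params):
        assert td.monostable_rhs(0.4, 0.0, params) == pytest.approx(
            -params.k_mono * 0.4)

    @pytest.mark.parametrize("c_I, expected", [
        (1.0, 0.5),            # kh = 1, n = 10: half activation
        (2.0, 1024.0 / 1025.0),
    ])
    def test_fixed_point_closed_form(self, params, c_I, expected):
        assert td.monostable_fixed_point(c_I, params) == pytest.approx(
            expected, rel=1e-9)
        assert td.monostable_rhs(expected, c_I, params) == pytest.approx(
            0.0, abs=1e-12)

    def test_unique_steady_state_for_every_input(self, params):
        """The monostable rhs is affine in R: exactly one root, matching
        a brute-force sign-change scan."""
        for c_I in (0.0, 0.5, 1.0, 3.0, 10.0):
            r_star = td.monostable_fixed_point(c_I, params)
            grid = np.linspace(0, 1, 10001)
            vals = td.monostable_rhs(grid, c_I, params)
            flips = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
            roots_near = (np.abs(vals) < 1e-12).sum()
            assert len(flips) + (roots_near > 0) == 1
            assert abs(grid[flips[0]] - r_star) < 2e-4 if len(flips) else True


class TestR1:
    def test_rest_state(self, params):
        assert td.r1_rhs(0.0, 0.0, params) == 0.0

    def test_fixed_point_under_sustained_drive(self, params):
        # kf/(kf + kr) = 3.6/3.744 exceeds the apoptosis threshold 0.9
        fp = td.r1_fixed_point(1.0, params)
        assert fp == pytest.approx(0.961538, rel=1e-5)
        assert fp > params.R1_th

    def test_minimum_sustained_drive_for_trigger(self, params):
        # solve kf R (1 - th) = kr th for R
        r_min = params.R1_th * params.kr / (
            (1 - params.R1_th) * params.kf)
        assert r_min == pytest.approx(0.36, rel=1e-9)
        assert td.r1_fixed_point(r_min, params) == pytest.approx(
            params.R1_th, rel=1e-9)


class TestBistability:
    def test_three_states_without_drug(self, params):
        roots = td.bistable_steady_states(0.0, params)
        assert len(roots) == 3
        stab = [s for _, s in roots]
        assert stab == [True, False, True]
        # residual at each refined root vanishes
        for r, _ in roots:
            assert abs(td.bistable_rhs(r, 0.0, params)) < 1e-8

    def test_single_state_far_above_threshold(self, params):
        roots = td.bistable_steady_states(50.0, params)
        assert len(roots) == 1
        assert roots[0][1] is True
        assert roots[0][0] > 0.5

    def test_root_count_always_odd(self, params):
        for c_I in (0.0, 0.3, 0.7, 1.5, 2.0, 5.0):
            assert len(td.bistable_steady_states(c_I, params)) % 2 == 1

    def test_saddle_node_defining_property(self, params):
        c_star = td.switch_input_threshold(params)
        assert len(td.bistable_steady_states(0.99 * c_star, params)) == 3
        assert len(td.bistable_steady_states(1.01 * c_star, params)) == 1

    def test_stronger_input_coupling_lowers_threshold(self, params):
        base = td.switch_input_threshold(params)
        strong = td.switch_input_threshold(params.with_overrides(q=0.6))
        assert strong < base

    def test_decoupled_input_rejected(self, params):
        with pytest.raises(ValueError, match="decoupled"):
            td.switch_input_threshold(params.with_overrides(q=0.0))

    def test_initial_rest_relaxes_to_low_state(self, params):
        """From R = 0 with no drug the switch settles on the low stable
        root, not the high one."""
        low = td.bistable_steady_states(0.0, params)[0][0]
        sol = solve_ivp(lambda t, y: td.bistable_rhs(y, 0.0, params),
                        (0, 200), [0.0], rtol=1e-9, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(low, rel=1e-4)

    def test_hysteresis_loop_bistable_but_not_monostable(self, params):
        """A slow ramp of c_I up past the fold and back produces
        different trajectories on the two legs for the bistable switch;
        the monostable response retraces itself."""
        t_ramp = 1500.0  # hours: slow against the switch kinetics
        c_peak = 2.0

        def c_of_t(t):
            return c_peak * (t / t_ramp if t < t_ramp
                             else (2 * t_ramp - t) / t_ramp)

        def run(rhs):
            up = solve_ivp(lambda t, y: rhs(y, c_of_t(t), params),
                           (0, t_ramp), [0.0], rtol=1e-8, atol=1e-10,
                           dense_output=True)
            down = solve_ivp(lambda t, y: rhs(y, c_of_t(t), params),
                             (t_ramp, 2 * t_ramp), up.y[:, -1],
                             rtol=1e-8, atol=1e-10, dense_output=True)
            cs = np.linspace(0.1, 1.9, 40)
            leg_up = [float(up.sol(c / c_peak * t_ramp)[0]) for c in cs]
            leg_dn = [float(down.sol(2 * t_ramp - c / c_peak * t_ramp)[0])
                      for c in cs]
            return np.array(leg_up), np.array(leg_dn)

        up_b, dn_b = run(td.bistable_rhs)
        assert np.abs(up_b - dn_b).max() > 0.3       # open loop
        up_m, dn_m = run(td.monostable_rhs)
        assert np.abs(up_m - dn_m).max() < 0.05      # retraces


class TestInvariantRectangle:
    def test_vector_field_points_inward_on_the_unit_box(self, params):
        """R and R1 stay in [0,1]: the rhs is non-negative on the lower
        face and non-positive on the upper face for any drug level."""
        for c_I in (0.0, 1.0, 10.0, 100.0):
            assert td.bistable_rhs(0.0, c_I, params) >= 0
            assert td.bistable_rhs(1.0, c_I, params) <= 0
            assert td.monostable_rhs(0.0, c_I, params) >= 0
            assert td.monostable_rhs(1.0, c_I, params) <= 0
        for R in (0.0, 0.5, 1.0):
            assert td.r1_rhs(0.0, R, params) >= 0
            assert td.r1_rhs(1.0, R, params) <= 0


class TestEffectiveGrowth:
    def _state(self, R1):
        s = td.CellState.uniform((3,), 10.0)
        s.R1 = np.asarray(R1, dtype=float)
        return s

    def test_no_signal_full_growth(self, params):
        s = self._state([0.0, 0.0, 0.0])
        a = td.effective_growth(s, "bistable", params.a1, params.R1_th)
        assert np.all(a == params.a1)
        assert not s.triggered.any()

    def test_monostable_latch_is_permanent(self, params):
        s = self._state([0.95, 0.5, 0.0])
        a = td.effective_growth(s, "monostable", params.a1, params.R1_th)
        assert list(a) == [0.0, params.a1, params.a1]
        s.R1[:] = 0.0  # signal collapses; the latch must hold
        a = td.effective_growth(s, "monostable", params.a1, params.R1_th)
        assert list(a) == [0.0, params.a1, params.a1]

    def test_bistable_gate_is_reversible(self, params):
        s = self._state([0.95, 0.0, 0.0])
        a = td.effective_growth(s, "bistable", params.a1, params.R1_th)
        assert a[0] == 0.0
        s.R1[0] = 0.5
        a = td.effective_growth(s, "bistable", params.a1, params.R1_th)
        assert a[0] == params.a1


class TestLogistic:
    def test_extinction_is_absorbing(self, params):
        assert td.logistic_rhs(0.0, params.a1, params) == 0.0

    def test_nontrivial_steady_state_matches_initial_density(self, params):
        """(a1 - a2)/b = 10.03 in 10^5 cells/mm^3, within 0.5% of the
        tabulated initial density of 10^6 cells/mm^3."""
        ss = (params.a1 - params.a2) / params.b
        assert ss == pytest.approx(10.0309, rel=1e-4)
        assert abs(ss * 1e5 - params.c_t0) / params.c_t0 < 0.005
        assert td.logistic_rhs(ss, params.a1, params) == pytest.approx(
            0.0, abs=1e-12)

    def test_gated_growth_decays_to_zero(self, params):
        for c_t in (0.1, 5.0, 20.0):
            assert td.logistic_rhs(c_t, 0.0, params) < 0
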
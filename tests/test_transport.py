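"""Pulse input, Kedem-Katchalsky wall flux, membrane exchange and the
split transport steppers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tumordrugsim as td
from tumordrugsim.transport import TransportSolver


@pytest.fixture(scope="module")
def ip(params):
    return td.to_internal_units(params)


@pytest.fixture(scope="module")
def small(ip):
    grid = td.build_grid(ip, 24, 12, 2.0)
    flow = td.solve_flow(grid, ip)
    return grid, flow


class TestInletConcentration:
    def test_baseline_pulse(self):
        pulse = td.PulseInput(S=1.0, T=1.5 * 3600)
        assert td.inlet_concentration(pulse, 0.5 * 3600) == 1.0
        assert td.inlet_concentration(pulse, 2.0 * 3600) == 0.0

    def test_right_continuity_at_switch(self):
        pulse = td.PulseInput(S=2.0, T=100.0)
        assert td.inlet_concentration(pulse, 100.0) == 0.0
        assert td.inlet_concentration(pulse, 99.999) == 2.0

    def test_fractionated_segment(self):
        pulse = td.PulseInput(segments=((0.5, 4 * 3600, 0.0),))
        assert td.inlet_concentration(pulse, 3.9 * 3600) == 0.5
        assert pulse.dose == pytest.approx(0.5 * 4 * 3600)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            td.PulseInput(segments=((1.0, 10.0, 0.0), (1.0, 10.0, 5.0)))


class TestLogMean:
    def test_direct_value(self):
        assert td.log_mean(1.0, 0.5) == pytest.approx(0.5 / np.log(2.0))

    def test_equal_arguments_limit(self):
        assert td.log_mean(0.7, 0.7) == pytest.approx(0.7)

    def test_both_zero(self):
        assert td.log_mean(0.0, 0.0) == 0.0

    def test_one_side_zero_tends_to_zero(self):
        assert td.log_mean(1.0, 0.0) == pytest.approx(
            1.0 / np.log(1.0 / 1e-12), rel=1e-6)
        assert td.log_mean(1.0, 0.0) < 0.04

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0.0, 10.0), st.floats(0.0, 10.0))
    def test_between_min_and_max(self, a, b):
        lm = td.log_mean(a, b)
        assert 0.0 <= lm <= max(a, b) + 1e-12


class TestKedemKatchalsky:
    def test_zero_at_zero_concentrations(self):
        assert td.kedem_katchalsky_flux(0.0, 0.0, 1e-6, 1e-7, 0.0) == 0.0

    def test_direct_evaluation(self):
        P, JF = 2.778e-6, 1.5e-7
        js = td.kedem_katchalsky_flux(1.0, 0.5, P, JF, 0.0)
        assert js == pytest.approx(0.5 * P + (0.5 / np.log(2.0)) * JF)

    def test_equal_concentrations_pure_drag(self):
        js = td.kedem_katchalsky_flux(0.8, 0.8, 2.778e-6, 1.5e-7, 0.25)
        assert js == pytest.approx(1.5e-7 * 0.75 * 0.8)

    def test_diffusive_part_antisymmetric(self):
        P = 2.778e-6
        a = td.kedem_katchalsky_flux(1.0, 0.25, P, 0.0, 0.0)
        b = td.kedem_katchalsky_flux(0.25, 1.0, P, 0.0, 0.0)
        assert a == pytest.approx(-b)


class TestMembraneExchange:
    def test_zero_state(self, ip):
        up, ef = td.membrane_exchange(0.0, 0.0, ip)
        assert up == 0.0 and ef == 0.0

    def test_half_saturation(self, ip):
        up, _ = td.membrane_exchange(ip.k1, 0.0, ip)
        assert up == pytest.approx(ip.V1 / 2)

    def test_equilibrium_ratio(self, ip):
        """With V1 = V2 the exchange balances at c_I = (k2/k1) c_E: the
        drug is concentrated ~6.3-fold inside cells at c_E = 1 ug/ml."""
        c_eq = ip.k2 / ip.k1  # 1.37/0.219 = 6.256
        assert c_eq == pytest.approx(6.2557, rel=1e-4)
        up, ef = td.membrane_exchange(1.0, c_eq, ip)
        assert up == pytest.approx(ef, rel=1e-12)

    def test_relaxation_toward_equilibrium_is_monotone(self, ip):
        c_E = 1.0
        target = ip.k2 / ip.k1 * c_E
        c_I, dt = 0.0, 30.0
        prev_gap = target
        for _ in range(2000):
            up, ef = td.membrane_exchange(c_E, c_I, ip)
            c_I += dt * (up - ef)
            gap = abs(target - c_I)
            assert gap <= prev_gap + 1e-12
            prev_gap = gap
        assert c_I == pytest.approx(target, rel=1e-2)


class TestVascularStep:
    def test_zero_inlet_stays_zero(self, small, ip):
        grid, flow = small
        solver = TransportSolver(grid, ip, flow, dt=10.0)
        state = td.DrugState(np.zeros(grid.nz), np.zeros((grid.nr, grid.nz)),
                             np.zeros((grid.nr, grid.nz)))
        pulse = td.PulseInput(S=0.0, T=100.0)
        for _ in range(5):
            state, fx = solver.step(state, pulse)
        assert np.abs(state.c_v).max() == 0.0
        assert np.abs(state.c_E).max() == 0.0

    def test_lumen_mass_conservation_without_wall(self, small, params):
        """Sealed wall (P_wall ~ 0, L_p ~ 0): inflow = lumen mass + outflow."""
        ip0 = td.to_internal_units(
            params.with_overrides(P_wall=1e-30, L_p=1e-30))
        grid = td.build_grid(ip0, 8, 16, 1.0)
        flow = td.solve_flow(grid, ip0)
        solver = TransportSolver(grid, ip0, flow, dt=5.0)
        state = td.DrugState(np.zeros(grid.nz), np.zeros((grid.nr, grid.nz)),
                             np.zeros((grid.nr, grid.nz)))
        pulse = td.PulseInput(S=1.0, T=600.0)
        cum_in = cum_out = 0.0
        for _ in range(240):
            state, fx = solver.step(state, pulse)
            cum_in += fx.inflow
            cum_out += fx.outflow
        lumen = float((state.c_v * grid.lumen_volume).sum())
        assert lumen + cum_out == pytest.approx(cum_in, rel=1e-3)

    def test_post_pulse_wall_flux_reverses(self, small, ip):
        """After the pulse the interstitium returns drug to the blood
        where c_E exceeds c_v."""
        grid, flow = small
        solver = TransportSolver(grid, ip, flow, dt=20.0)
        state = td.DrugState(np.zeros(grid.nz), np.zeros((grid.nr, grid.nz)),
                             np.zeros((grid.nr, grid.nz)))
        pulse = td.PulseInput(S=1.0, T=1200.0)
        transfer_during = transfer_after = None
        for _ in range(60):
            state, fx = solver.step(state, pulse)
        transfer_during = fx.wall_transfer
        for _ in range(60):
            state, fx = solver.step(state, pulse)
        transfer_after = fx.wall_transfer
        assert transfer_during > 0
        assert transfer_after < 0
        assert state.c_E[0, grid.nz // 2] > state.c_v[grid.nz // 2]


class TestInterstitialStep:
    def test_closed_domain_mass_constant(self, small, params):
        """Sealed wall, no exchange: interstitial drug mass is invariant
        under diffusion + advection."""
        ip0 = td.to_internal_units(
            params.with_overrides(P_wall=1e-30, L_p=1e-30))
        grid, _ = small
        flow = td.solve_flow(grid, ip0)
        solver = TransportSolver(grid, ip0, flow, dt=50.0)
        rng = np.random.default_rng(0)
        state = td.DrugState(np.zeros(grid.nz),
                             rng.uniform(0.1, 1.0, (grid.nr, grid.nz)),
                             np.zeros((grid.nr, grid.nz)))
        m0 = float((state.c_E * grid.cell_volumes).sum())
        std0 = float(state.c_E.std())
        pulse = td.PulseInput(S=0.0, T=1.0)
        for _ in range(100):
            state, _ = solver.step(state, pulse)
        m1 = float((state.c_E * grid.cell_volumes).sum())
        assert m1 == pytest.approx(m0, rel=1e-3)
        # diffusion smooths: the field flattens toward its mean
        assert state.c_E.std() < 0.5 * std0

    def test_positivity_preserved(self, small, ip):
        grid, flow = small
        solver = TransportSolver(grid, ip, flow, dt=20.0)
        state = td.DrugState(np.zeros(grid.nz), np.zeros((grid.nr, grid.nz)),
                             np.zeros((grid.nr, grid.nz)))
        pulse = td.PulseInput(S=1.0, T=1800.0)
        for _ in range(200):
            state, _ = solver.step(state, pulse)
            assert state.c_E.min() >= 0.0
            assert state.c_v.min() >= 0.0

    def test_little_drug_beyond_five_radii(self, baseline_bistable):
        """At the end of the baseline pulse, c_E five vessel radii out
        is a tiny fraction of its wall value."""
        res = baseline_bistable
        k = int(np.argmin(np.abs(res.times - 1.5 * 3600)))
        r, c_E = res.mid_profile("c_E", snapshot=k)
        wall = c_E[0]
        far = float(np.interp(res.grid.R_C + 5 * res.grid.R_C, r, c_E))
        assert far < 0.05 * wall

    def test_post_pulse_interior_rise_then_fall(self, baseline_bistable):
        """At a fixed interior radius c_E rises, peaks after the pulse
        ends, then falls off."""
        res = baseline_bistable
        iz = res.grid.nz // 2
        ir = int(np.searchsorted(res.grid.r_centers,
                                 res.grid.R_C + 2.0e-4))
        series = np.array([s.c_E[ir, iz] for s in res.drug_snapshots])
        k_peak = int(np.argmax(series))
        t_peak = res.times[k_peak]
        assert t_peak > 1.5 * 3600  # peak after the pulse ends
        assert series[k_peak] > series[-1]  # falls off afterwards
        assert np.all(np.diff(series[: k_peak + 1]) >= -1e-12)
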
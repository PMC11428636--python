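"""Pulse solver: grid construction, analytic oracles, invariants."""

import numpy as np
import pytest

from hemowall.pulse_solver import (
    WaveformSeries,
    build_radial_grid,
    flow_rate,
    is_laminar,
    reynolds_number,
    solve_flow_driven,
    solve_pressure_driven,
    solve_steady,
    wall_velocity_gradient,
    womersley_analytic,
    womersley_number,
)
from hemowall.rheology import CarreauParameters

from conftest import MU_NEWT, OMEGA, RHO, carreau_profile_oracle


class TestRadialGrid:
    def test_inflation_layer_gaps(self):
        grid = build_radial_grid(0.01794)
        gaps_mm = np.diff(grid.radii)[::-1][:5] * 1e3  # wall-inward
        assert gaps_mm == pytest.approx([0.1, 0.12, 0.144, 0.1728, 0.20736], rel=1e-12)

    def test_uniform_when_no_layers(self):
        grid = build_radial_grid(0.01, n_layers=0, n_interior=16)
        assert grid.n_nodes == 17
        assert np.allclose(np.diff(grid.radii), 0.01 / 16)

    @pytest.mark.parametrize("R,n_interior", [(0.002, 12), (0.01794, 48), (0.03, 100)])
    def test_constructive_reconstruction(self, R, n_interior):
        """Node count and monotone spacing match a direct reconstruction."""
        grid = build_radial_grid(R, n_interior=n_interior)
        assert grid.n_nodes == n_interior + 5 + 1
        gaps = np.diff(grid.radii)
        assert np.all(gaps > 0)
        assert grid.radii[0] == 0.0 and grid.radii[-1] == R
        # boundary-layer gaps continue geometrically into the interior fill
        bl = gaps[::-1][:5]
        assert bl == pytest.approx(1e-4 * 1.2 ** np.arange(5), rel=1e-12)
        assert abs(gaps.sum() - R) < 1e-15 * max(1.0, R)

    def test_layers_thicker_than_radius_rejected(self):
        with pytest.raises(ValueError):
            build_radial_grid(5e-4)  # 5 layers of >=0.1 mm do not fit


class TestWaveformSeries:
    def test_validation(self):
        t = np.linspace(0, 1, 16, endpoint=False)
        with pytest.raises(ValueError):
            WaveformSeries(t[:4], np.zeros(4), 1.0)  # too few samples
        with pytest.raises(ValueError):
            WaveformSeries(t + 0.1, np.zeros(16), 1.0)  # does not start at 0
        with pytest.raises(ValueError):
            WaveformSeries(t, np.full(16, np.nan), 1.0)

    def test_periodic_sampling_wraps(self):
        t = np.linspace(0, 1, 16, endpoint=False)
        w = WaveformSeries(t, np.sin(2 * np.pi * t), 1.0)
        assert w.sample(1.0) == pytest.approx(w.sample(0.0))
        assert w.sample(2.25) == pytest.approx(w.sample(0.25))


class TestPressureDriven:
    def test_steady_poiseuille_wall_shear_and_flow(self, poiseuille_case):
        sol = poiseuille_case["sol"]
        R, G = poiseuille_case["R"], poiseuille_case["G"]
        tau_exact = G * R / 2.0  # 0.5 Pa
        assert sol.converged
        assert sol.tau_wall[-1] == pytest.approx(tau_exact, rel=1e-3)
        Q_exact = np.pi * G * R**4 / (8 * MU_NEWT)
        assert sol.Q[-1] == pytest.approx(Q_exact, rel=1e-3)

    def test_womersley_velocity_profiles(self, womersley_case):
        sol, u_exact = womersley_case["sol"], womersley_case["u_exact"]
        err = np.linalg.norm(sol.u - u_exact) / np.linalg.norm(u_exact)
        assert err < 0.01

    def test_womersley_wall_shear(self, womersley_case):
        sol, tau_exact = womersley_case["sol"], womersley_case["tau_exact"]
        err = np.linalg.norm(sol.tau_wall_signed - tau_exact) / np.linalg.norm(tau_exact)
        assert err < 0.01

    def test_periodicity_after_two_cycles(self, womersley_case):
        assert womersley_case["sol"].periodicity_error < 1e-3

    def test_carreau_steady_matches_inversion_oracle(self, carreau_steady_case, blood):
        sol = carreau_steady_case["sol"]
        u_oracle = carreau_profile_oracle(blood, carreau_steady_case["grid"],
                                          carreau_steady_case["G"])
        err = np.linalg.norm(sol.u[-1] - u_oracle) / np.linalg.norm(u_oracle)
        assert err < 0.005

    def test_no_slip_and_axis_symmetry(self, womersley_case):
        sol = womersley_case["sol"]
        assert np.all(sol.u[:, -1] == 0.0)
        r = sol.grid.radii
        # second-order one-sided du/dr at the axis
        h1, h2 = r[1], r[2]
        d_axis = (
            -(h1 + h2) / (h1 * h2) * sol.u[:, 0]
            + h2 / (h1 * (h2 - h1)) * sol.u[:, 1]
            - h1 / (h2 * (h2 - h1)) * sol.u[:, 2]
        )
        scale = np.max(np.abs(wall_velocity_gradient(sol.grid, sol.u)))
        assert np.max(np.abs(d_axis)) < 1e-3 * scale

    def test_flow_rate_internal_consistency(self, womersley_case):
        sol = womersley_case["sol"]
        Q = flow_rate(sol.grid, sol.u)
        scale = np.max(np.abs(sol.Q))
        assert np.max(np.abs(Q - sol.Q)) <= 1e-10 * scale

    def test_time_step_robustness(self, newtonian, womersley_case):
        """tau_wall waveforms at dt = 0.005/0.001/0.0005 agree within 1% L2."""
        grid, wave = womersley_case["grid"], womersley_case["wave"]
        tg = np.linspace(0, 1, 200, endpoint=False)
        taus = {}
        for dt in (0.005, 0.0005):
            s = solve_pressure_driven(newtonian, grid, wave, dt=dt, n_cycles=3)
            taus[dt] = np.interp(tg, s.times, s.tau_wall, period=1.0)
        sol = womersley_case["sol"]
        taus[0.001] = np.interp(tg, sol.times, sol.tau_wall, period=1.0)
        ref = np.linalg.norm(taus[0.0005])
        for a in (0.005, 0.001):
            assert np.linalg.norm(taus[a] - taus[0.0005]) / ref < 0.01

    def test_grid_refinement_insensitivity(self, newtonian, womersley_case):
        """Doubling the interior resolution moves the tau_wall peak < 0.5%."""
        R, wave = womersley_case["R"], womersley_case["wave"]
        fine = build_radial_grid(R, first_layer=1.5e-5, n_layers=5, growth=1.2,
                                 n_interior=80)
        s = solve_pressure_driven(newtonian, fine, wave, dt=0.001, n_cycles=3)
        peak_coarse = womersley_case["sol"].tau_wall.max()
        assert abs(s.tau_wall.max() - peak_coarse) / peak_coarse < 0.005

    def test_period_not_divisible_by_dt_rejected(self, newtonian):
        grid = build_radial_grid(0.002, first_layer=2e-5, n_interior=12)
        wave = WaveformSeries.constant(-100.0, 1.0, "Pa/m")
        with pytest.raises(ValueError):
            solve_pressure_driven(newtonian, grid, wave, dt=0.3)

    def test_nonconvergence_flagged_not_raised(self, blood):
        grid = build_radial_grid(0.002, first_layer=2e-5, n_interior=12)
        tt = np.linspace(0, 1, 16, endpoint=False)
        wave = WaveformSeries(tt, -4e3 * np.cos(OMEGA * tt), 1.0, "Pa/m")
        sol = solve_pressure_driven(blood, grid, wave, dt=0.05, n_cycles=1,
                                    picard_tol=1e-14, max_picard=2)
        assert sol.converged is False
        assert np.all(np.isfinite(sol.u))


class TestFlowDriven:
    def test_constant_flow_recovers_poiseuille_gradient(self, newtonian):
        R, Q0 = 0.00155, 1e-6
        grid = build_radial_grid(R, first_layer=1.5e-5, n_interior=40)
        wave = WaveformSeries.constant(Q0, 1.0, "m^3/s")
        sol = solve_flow_driven(newtonian, grid, wave, dt=0.01, n_cycles=3)
        assert sol.dpdx[-1] == pytest.approx(-8 * MU_NEWT * Q0 / (np.pi * R**4), rel=1e-3)
        assert sol.tau_wall[-1] == pytest.approx(4 * MU_NEWT * Q0 / (np.pi * R**3), rel=1e-3)

    def test_zero_flow_gives_zero_field(self, newtonian):
        grid = build_radial_grid(0.002, first_layer=2e-5, n_interior=12)
        wave = WaveformSeries.constant(0.0, 1.0, "m^3/s")
        sol = solve_flow_driven(newtonian, grid, wave, dt=0.01, n_cycles=1)
        assert np.max(np.abs(sol.u)) == 0.0
        assert np.max(sol.tau_wall) == 0.0

    def test_pulsatile_round_trip(self, newtonian):
        """dpdx recovered from a flow-driven solve reproduces Q when fed back."""
        R = 0.00155
        grid = build_radial_grid(R, first_layer=1.5e-5, n_interior=40)
        qt = np.linspace(0, 1, 100, endpoint=False)
        Q0 = 1e-6
        q_wave = WaveformSeries(qt, Q0 * (1 + 0.5 * np.sin(OMEGA * qt)), 1.0, "m^3/s")
        fwd = solve_flow_driven(newtonian, grid, q_wave, dt=0.002, n_cycles=3)
        # rebuild a periodic dpdx waveform starting at phase 0
        t0 = np.concatenate([[0.0], fwd.times[:-1]])
        g0 = np.concatenate([[fwd.dpdx[-1]], fwd.dpdx[:-1]])
        dp_wave = WaveformSeries(t0, g0, 1.0, "Pa/m")
        back = solve_pressure_driven(newtonian, grid, dp_wave, dt=0.002, n_cycles=3)
        err = np.max(np.abs(back.Q - q_wave.sample(back.times))) / Q0
        assert err < 1e-3

    def test_imposed_flow_matched_each_step(self, newtonian):
        grid = build_radial_grid(0.002, first_layer=2e-5, n_interior=16)
        qt = np.linspace(0, 1, 50, endpoint=False)
        q_wave = WaveformSeries(qt, 1e-6 * (1 + 0.3 * np.cos(OMEGA * qt)), 1.0, "m^3/s")
        sol = solve_flow_driven(newtonian, grid, q_wave, dt=0.005, n_cycles=2)
        # q_tol = 1e-6 relative to the waveform scale (~1.3e-6 m^3/s)
        assert np.max(np.abs(sol.Q - q_wave.sample(sol.times))) < 1.5e-12


class TestWomersleyAnalytic:
    def test_quasi_steady_limit_is_poiseuille(self):
        R, G = 0.002, 500.0
        r = np.linspace(0, R, 64)
        u, _ = womersley_analytic(RHO, MU_NEWT, R, G, 1e-6, r, np.array([0.0]))
        u_pois = G * (R**2 - r**2) / (4 * MU_NEWT)
        assert np.max(np.abs(u[0] - u_pois)) / u_pois[0] < 1e-4

    def test_no_slip_built_in(self):
        r = np.linspace(0, 0.01794, 32)
        t = np.linspace(0, 1, 40)
        u, _ = womersley_analytic(RHO, MU_NEWT, 0.01794, 300.0, OMEGA, r, t)
        assert np.max(np.abs(u[:, -1])) < 1e-12 * np.max(np.abs(u))

    def test_high_alpha_against_independent_bessel(self):
        """alpha = 23 profile cross-checked against an arbitrary-precision
        evaluation of the same Bessel expression with mpmath."""
        import mpmath as mp

        R, G = 0.01794, 300.0
        r = np.linspace(0, R, 9)
        t = np.array([0.0, 0.3, 0.7])
        u, tau = womersley_analytic(RHO, MU_NEWT, R, G, OMEGA, r, t)
        beta = mp.sqrt(mp.mpc(0, -1) * OMEGA * RHO / MU_NEWT)
        j0R = mp.besselj(0, beta * R)
        for i, ti in enumerate(t):
            for j, rj in enumerate(r):
                prof = (G / (mp.mpc(0, 1) * RHO * OMEGA)) * (
                    1 - mp.besselj(0, beta * rj) / j0R
                )
                expected = float(mp.re(prof * mp.exp(mp.mpc(0, 1) * OMEGA * ti)))
                assert u[i, j] == pytest.approx(expected, abs=1e-12 + 1e-10 * abs(expected))

    def test_domain_errors(self):
        r = np.linspace(0, 0.01, 8)
        with pytest.raises(ValueError):
            womersley_analytic(RHO, -0.004, 0.01, 100.0, OMEGA, r, np.array([0.0]))
        with pytest.raises(ValueError):
            womersley_analytic(RHO, MU_NEWT, 0.01, 100.0, 0.0, r, np.array([0.0]))


class TestDimensionlessNumbers:
    def test_aortic_reynolds_number(self):
        re = reynolds_number(1060.0, 0.14, 0.03588, 0.004)
        assert round(re) == 1331
        assert is_laminar(re)

    def test_reynolds_edge_cases(self):
        assert reynolds_number(1060.0, 0.0, 0.03, 0.004) == 0.0
        assert reynolds_number(1050.0, 0.2, 0.02, 0.004) == pytest.approx(1050.0, rel=1e-14)
        with pytest.raises(ValueError):
            reynolds_number(1060.0, 0.1, 0.03, 0.0)
        assert not is_laminar(2500.0)

    def test_womersley_number(self):
        assert womersley_number(0.01794, OMEGA, 1060.0, 0.004) == pytest.approx(
            23.149163902037428, rel=1e-12
        )
        assert womersley_number(0.01794, 0.0, 1060.0, 0.004) == 0.0
        a1 = womersley_number(0.005, 3.0, 1060.0, 0.004)
        assert womersley_number(0.005, 12.0, 1060.0, 0.004) == pytest.approx(2 * a1)
        with pytest.raises(ValueError):
            womersley_number(-0.01, OMEGA, 1060.0, 0.004)


def test_steady_solver_newtonian_is_exact_poiseuille(newtonian):
    grid = build_radial_grid(0.01, n_interior=32)
    u = solve_steady(newtonian, grid, -100.0)
    u_exact = 100.0 * (0.01**2 - grid.radii**2) / (4 * MU_NEWT)
    assert np.max(np.abs(u - u_exact)) < 1e-10 * u_exact[0]
    tau = MU_NEWT * abs(wall_velocity_gradient(grid, u)[0])
    assert tau == pytest.approx(0.5, rel=1e-12)
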
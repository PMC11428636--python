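"""Shared fixtures: fluids, grids and the heavier pulsatile solves.

The pulsatile validation solves (Womersley, Carreau steady, flow-driven
round trip) are session-scoped so the unit tests and the acceptance tests
reuse one solve each instead of repeating multi-thousand-step marches.
"""

from __future__ import annotations

import numpy as np
import pytest

from hemowall.pulse_solver import (
    WaveformSeries,
    build_radial_grid,
    solve_pressure_driven,
    womersley_analytic,
)
from hemowall.rheology import BLOOD, CarreauParameters

RHO = 1060.0
MU_NEWT = 0.004
OMEGA = 2.0 * np.pi  # 1 Hz cardiac frequency


@pytest.fixture(scope="session")
def newtonian():
    return CarreauParameters.newtonian(MU_NEWT, RHO)


@pytest.fixture(scope="session")
def blood():
    return BLOOD


@pytest.fixture(scope="session")
def womersley_case(newtonian):
    """Oscillatory Newtonian validation solve at alpha ~ 2.

    At this pulsatility the viscous start-up transient decays fast enough
    (rate nu*j01^2/R^2 ~ 9 per cycle) for the flow to be periodic by the
    third cycle, which is the regime the three-cycle protocol targets.
    """
    R = 0.00155
    G = 800.0
    grid = build_radial_grid(R, first_layer=1.5e-5, n_layers=5, growth=1.2,
                             n_interior=40)
    tt = np.linspace(0.0, 1.0, 200, endpoint=False)
    wave = WaveformSeries(tt, -G * np.cos(OMEGA * tt), 1.0, units="Pa/m")
    sol = solve_pressure_driven(newtonian, grid, wave, dt=0.001, n_cycles=3)
    u_exact, tau_exact = womersley_analytic(RHO, MU_NEWT, R, G, OMEGA,
                                            grid.radii, sol.times)
    return {"R": R, "G": G, "grid": grid, "wave": wave, "sol": sol,
            "u_exact": u_exact, "tau_exact": tau_exact}


@pytest.fixture(scope="session")
def poiseuille_case(newtonian):
    """Steady Newtonian solve: R = 0.01 m, G = 100 Pa/m, mu = 0.004 Pa*s."""
    R, G = 0.01, 100.0
    grid = build_radial_grid(R, n_interior=48)
    wave = WaveformSeries.constant(-G, 1.0, "Pa/m")
    sol = solve_pressure_driven(newtonian, grid, wave, dt=0.001, n_cycles=3)
    return {"R": R, "G": G, "grid": grid, "sol": sol}


@pytest.fixture(scope="session")
def carreau_steady_case(blood):
    """Carreau fluid under a constant pressure gradient, marched to steady."""
    R, G = 0.002, 4000.0
    grid = build_radial_grid(R, first_layer=2e-5, n_layers=5, growth=1.2,
                             n_interior=40)
    wave = WaveformSeries.constant(-G, 1.0, "Pa/m")
    sol = solve_pressure_driven(blood, grid, wave, dt=0.001, n_cycles=3)
    return {"R": R, "G": G, "grid": grid, "sol": sol}


def carreau_profile_oracle(params, grid, G, n_fine: int = 20001) -> np.ndarray:
    """Independent steady-profile oracle by inverting the stress balance.

    The steady momentum balance integrates to mu(|u'|) u' = -G r / 2, a
    scalar nonlinear equation for the velocity gradient at every radius;
    the profile follows by quadrature with u(R) = 0.  No finite-difference
    machinery is shared with the solver under test.
    """
    from scipy.integrate import cumulative_trapezoid
    from scipy.optimize import brentq

    from hemowall.rheology import carreau_viscosity

    rf = np.linspace(0.0, grid.R, n_fine)

    def gradient(s):
        if s == 0.0:
            return 0.0
        return brentq(lambda g: carreau_viscosity(params, abs(g)) * g - s,
                      -1e9, 1e9, xtol=1e-16, rtol=8.9e-16)

    gvals = np.array([gradient(-G * r / 2.0) for r in rf])
    F = cumulative_trapezoid(gvals, rf, initial=0.0)
    u_fine = F - F[-1]  # u(r) = -int_r^R u' dr'
    return np.interp(grid.radii, rf, u_fine)
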
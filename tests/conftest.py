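"""Shared fixtures.

The expensive stochastic runs (regime histograms, the deterministic surfing
run, the density/cell-length scan) are session-scoped and shared between the
unit tests and the acceptance suite.
"""

import numpy as np
import pytest
from hypothesis import settings

import chemoengine as ce

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

FIG2 = dict(l_b=0.2, L=40.0, eps=5.0)


@pytest.fixture(scope="session")
def fig2_geom():
    """Ring geometry of the analytic track: l_b=0.2, L=40, eps=5."""
    return ce.WaveGeometry(**FIG2)


@pytest.fixture(scope="session")
def chi_c(fig2_geom):
    return ce.critical_chi(fig2_geom, tol=1e-7)


@pytest.fixture(scope="session")
def surfing_run(fig2_geom):
    """Deterministic periodic simulation in the surfing regime
    (chi=10, K_d=0.001, no noise), with the analytic branch speed."""
    v_branch = float(ce.find_velocities(10.0, fig2_geom).max())
    p = ce.ModelParams(chi=10.0, eps=5.0, K_d=0.001, l_b=0.2, M=1, L=40.0,
                      dx=0.05, noise_D=0.0, bc_field="periodic", seed=1)
    # start from the analytic traveling profile (positive everywhere); the
    # full finite-K_d dynamics relaxes to its own nearby wave, whose speed
    # is then measured independently of the analytic branch
    sw = ce.solve_profile(v_branch, 10.0, fig2_geom)
    x = (np.arange(p.n_cells) + 0.5) * p.dx
    traj = ce.simulate(p, 100.0, sample_every=0.5, u0=sw(x - 20.0),
                       xi0=[20.0])
    return traj, v_branch


def _regime_run(chi, M, t_end, sample_every=0.01):
    p = ce.ModelParams(chi=chi, eps=5.0, K_d=0.1, l_b=0.2, M=M, L=5.0,
                      dx=0.1, noise_D=0.05, bc_field="neumann", seed=42)
    return ce.simulate(p, t_end, sample_every=sample_every)


@pytest.fixture(scope="session")
def regime_runs():
    """M=1 runs in the three regimes of increasing hydrolysis rate:
    thermal (chi=0.5), steady centering (2.5), pole-to-pole (10)."""
    return {
        0.5: _regime_run(0.5, 1, 500.0, 0.005),
        2.5: _regime_run(2.5, 1, 1000.0, 0.01),
        10.0: _regime_run(10.0, 1, 500.0, 0.005),
    }


@pytest.fixture(scope="session")
def multi_plasmid_runs():
    """M=2 and M=3 runs at chi=2.5 (equi-positioning)."""
    return {2: _regime_run(2.5, 2, 2000.0, 0.02),
            3: _regime_run(2.5, 3, 2000.0, 0.02)}


@pytest.fixture(scope="session")
def invivo_results():
    """Reduced-grid density/cell-length scans for M=1 and M=2."""
    dp = ce.DimensionalParams()  # k=0.1, D=0.05, l_b=0.075um, l=0.4um
    rho = [0.0, 60.0, 100.0, 140.0]
    scans = {}
    scans[1] = ce.invivo_scan(dp, rho, [0.6, 0.8, 2.0], M=1, seed=5,
                              t_end=200.0)
    scans[2] = ce.invivo_scan(dp, rho, [1.2, 1.6, 4.0], M=2, seed=5,
                              t_end=200.0)
    return scans
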
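"""Co-moving steady-wave solver: profiles against a finite-difference BVP
oracle, the self-consistent velocity equation, bifurcations and limits."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from hypothesis import given, settings, strategies as st

import chemoengine as ce
from chemoengine.errors import ConvergenceError, DomainError
from chemoengine.wave import residual_slope

SURFING_V_CHI10 = 4.76337  # root of the self-consistency at chi=10


def fd_profile(v, chi, geom, n=4096):
    """Independent oracle: second-order periodic finite-difference solve of
    U'' + vU' + (1-U) = chi*theta, with the indicator entered as exact
    cell-coverage fractions."""
    L, l_b = geom.L, geom.l_b
    dz = L / n
    z = -L / 2 + (np.arange(n) + 0.5) * dz
    A = sp.diags([np.full(n, -2 / dz**2 - 1.0),
                  np.full(n - 1, 1 / dz**2 + v / (2 * dz)),
                  np.full(n - 1, 1 / dz**2 - v / (2 * dz))],
                 [0, 1, -1], format="lil")
    A[0, -1] = 1 / dz**2 - v / (2 * dz)
    A[-1, 0] = 1 / dz**2 + v / (2 * dz)
    lo = np.clip((-l_b - (z - dz / 2)) / dz, 0, 1)
    hi = np.clip((l_b - (z - dz / 2)) / dz, 0, 1)
    rhs = -1.0 + chi * (hi - lo)
    return z, spla.spsolve(A.tocsc(), rhs)


class TestSolveProfile:
    def test_no_sink_trivial(self, fig2_geom):
        sw = ce.solve_profile(1.3, 0.0, fig2_geom)
        z = np.linspace(-20, 20, 100)
        assert np.allclose(sw(z), 1.0, atol=1e-12)

    def test_localized_symmetric_minimum(self, fig2_geom):
        sw = ce.solve_profile(0.0, 2.5, fig2_geom)
        z = np.linspace(0.0, 19.9, 500)
        assert np.allclose(sw(z), sw(-z), atol=1e-12)
        assert sw.U0 > 0
        assert sw.U0 == np.min(sw(np.linspace(-19.9, 19.9, 2001)))

    def test_surfing_asymmetric_displaced_minimum(self, fig2_geom):
        sw = ce.solve_profile(SURFING_V_CHI10, 10.0, fig2_geom)
        z = np.linspace(-19.9, 19.9, 4001)
        vals = sw(z)
        zmin = z[np.argmin(vals)]
        assert abs(zmin) > 0.01  # minimum shifted off the cargo
        assert not np.allclose(vals, vals[::-1], atol=1e-6)

    @pytest.mark.parametrize("v,chi", [(0.0, 2.5), (SURFING_V_CHI10, 10.0),
                                       (1.0, 5.0), (-2.0, 7.5)])
    def test_collocation_residual(self, fig2_geom, v, chi):
        sw = ce.solve_profile(v, chi, fig2_geom)
        z = np.linspace(-fig2_geom.L / 2, fig2_geom.L / 2, 1003)
        res = sw.ode_residual(z)
        assert np.nanmax(np.abs(res)) < 1e-9

    @pytest.mark.parametrize("v,chi", [(0.0, 2.5), (SURFING_V_CHI10, 10.0),
                                       (1.0, 5.0)])
    def test_matches_fd_bvp_oracle(self, fig2_geom, v, chi):
        z, Ufd = fd_profile(v, chi, fig2_geom)
        sw = ce.solve_profile(v, chi, fig2_geom)
        assert np.max(np.abs(Ufd - sw(z))) < 1e-4

    def test_c1_matching_at_edges(self, fig2_geom):
        sw = ce.solve_profile(1.7, 6.0, fig2_geom)
        lb = fig2_geom.l_b
        for edge in (lb, -lb):
            inside = sw(edge - np.sign(edge) * 1e-9)
            outside = sw(edge + np.sign(edge) * 1e-9)
            assert inside == pytest.approx(outside, abs=1e-7)
            din = sw.derivative(edge - np.sign(edge) * 1e-9)
            dout = sw.derivative(edge + np.sign(edge) * 1e-9)
            assert din == pytest.approx(dout, abs=1e-6)

    @settings(deadline=None, max_examples=30)
    @given(v=st.floats(-4, 4), chi=st.floats(0.0, 9.0))
    def test_ring_mass_balance(self, fig2_geom, v, chi):
        # integral of (1 - U) over the ring equals the total sink 2*l_b*chi
        sw = ce.solve_profile(v, chi, fig2_geom)
        assert sw.mass_defect() == pytest.approx(2 * fig2_geom.l_b * chi,
                                                 abs=1e-9, rel=1e-9)

    def test_localized_U0_decreasing_in_chi(self, fig2_geom):
        chis = np.linspace(0.5, 6.0, 23)
        u0 = [ce.solve_profile(0.0, c, fig2_geom).U0 for c in chis]
        assert np.all(np.diff(u0) < 0)


class TestResidual:
    def test_zero_at_v0(self, fig2_geom):
        for chi in (0.5, 2.5, 5.0):
            assert ce.residual(0.0, chi, fig2_geom) == 0.0

    @settings(deadline=None, max_examples=30)
    @given(v=st.floats(0.05, 4.0), chi=st.floats(0.1, 5.0))
    def test_odd_parity(self, fig2_geom, v, chi):
        assert ce.residual(v, chi, fig2_geom) == pytest.approx(
            -ce.residual(-v, chi, fig2_geom), rel=1e-9, abs=1e-12)

    def test_mirror_symmetry_of_profiles(self, fig2_geom):
        swp = ce.solve_profile(1.5, 8.0, fig2_geom)
        swm = ce.solve_profile(-1.5, 8.0, fig2_geom)
        z = np.linspace(-19.9, 19.9, 501)
        assert np.allclose(swp(z), swm(-z), atol=1e-9)

    def test_single_root_below_threshold(self, fig2_geom):
        roots = ce.find_velocities(2.5, fig2_geom)
        assert roots.tolist() == [0.0]


class TestFindVelocities:
    def test_chi0_only_trivial_root(self, fig2_geom):
        assert ce.find_velocities(0.0, fig2_geom).tolist() == [0.0]

    def test_three_roots_above_threshold(self, fig2_geom):
        roots = ce.find_velocities(10.0, fig2_geom)
        assert roots.size == 3
        assert roots[1] == 0.0
        assert roots[2] == pytest.approx(SURFING_V_CHI10, abs=1e-4)
        assert roots[0] == pytest.approx(-roots[2], abs=1e-12)
        # polished to the stated residual tolerance
        assert abs(ce.residual(roots[2], 10.0, fig2_geom)) < 1e-8

    def test_pitchfork_square_root_scaling(self, fig2_geom, chi_c):
        offs = np.array([0.03, 0.06, 0.1, 0.15, 0.2, 0.3])
        v = np.array([ce.find_velocities(chi_c + o, fig2_geom).max()
                      for o in offs])
        slope = np.polyfit(np.log(offs), np.log(v), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)


class TestCriticalChi:
    def test_value_and_detector_agreement(self, fig2_geom, chi_c):
        assert chi_c == pytest.approx(3.1, abs=0.1)
        by_scan = ce.critical_chi(fig2_geom, method="scan", tol=1e-5)
        assert by_scan == pytest.approx(chi_c, abs=1e-3)

    def test_slope_changes_sign_at_chic(self, fig2_geom, chi_c):
        assert residual_slope(chi_c - 0.05, fig2_geom) < 0
        assert residual_slope(chi_c + 0.05, fig2_geom) > 0

    def test_finite_size_critical_k(self):
        k_c = ce.critical_k(40, 0.05, l_b=0.2, L=40.0)
        assert k_c == pytest.approx(0.031, abs=0.002)

    def test_no_bifurcation_without_force(self):
        geom = ce.WaveGeometry(l_b=0.2, L=40.0, eps=0.0)
        with pytest.raises(ConvergenceError):
            ce.critical_chi(geom, chi_max=5.0)


class TestVanishingSizeLimit:
    def test_closed_form_critical_rate(self):
        assert ce.critical_k_limit(40, 0.05) == 0.025

    def test_velocity_zero_at_kc(self):
        kc = ce.critical_k_limit(40, 0.05)
        assert ce.limit_velocity(kc, 0.05, 40).tolist() == [0.0]
        assert ce.limit_velocity(0.9 * kc, 0.05, 40).tolist() == [0.0]

    def test_limit_formula_value(self):
        # sqrt(v^2+4) = kN(DN/2+1) -> v = sqrt(g^2 - 4)
        g = 0.1 * 40 * (0.05 * 40 / 2 + 1)
        assert ce.limit_velocity(0.1, 0.05, 40).max() == pytest.approx(
            np.sqrt(g**2 - 4))

    def test_finite_size_extrapolation_fixes_radical(self):
        # the l_b -> 0 extrapolation of the finite-size solver converges to
        # the square-root reading of the closed form, not to the plain
        # bracket product
        target = ce.limit_velocity(0.1, 0.05, 40).max()  # 7.746
        product_reading = (0.1 * 40 * 3 + 2) * (0.1 * 40 * 3 - 2)  # no sqrt
        vs = []
        for lb in (0.1, 0.05, 0.025, 0.0125):
            chi = 0.1 * 40 / (2 * lb)
            geom = ce.WaveGeometry(l_b=lb, L=400.0,
                                   eps=0.05 * 40 / (2 * lb))
            vs.append(ce.find_velocities(chi, geom).max())
        vs = np.array(vs)
        assert np.all(np.diff(vs) > 0)  # monotone approach from below
        richardson = vs[-1] + (vs[-1] - vs[-2])
        assert richardson == pytest.approx(target, rel=0.02)
        assert abs(richardson - target) < abs(richardson - product_reading)


class TestScanBranch:
    def test_n10_no_directed_motion(self):
        lbs = np.linspace(0.05, 1.0, 12)
        br = ce.scan_branch("l_b", lbs, N=10, k=0.1, D_rel=0.05, L=40.0)
        assert br.kind == "none"
        assert not np.any(np.isfinite(br.v_surfing))

    def test_n40_inverse_pitchfork_in_lb(self):
        lbs = np.linspace(0.05, 1.9, 20)
        br = ce.scan_branch("l_b", lbs, N=40, k=0.1, D_rel=0.05, L=40.0)
        v = br.v_surfing
        ok = np.isfinite(v)
        assert ok[0] and not ok[-1]  # branch dies at large l_b
        assert np.all(np.diff(v[ok]) < 0)  # |v| decreasing with l_b
        assert br.kind == "inverse pitchfork"

    def test_chi_eps_plane_has_critical_curve(self):
        chis = np.linspace(0.5, 10, 8)
        moving = []
        for eps in (1.0, 5.0, 9.0):
            br = ce.scan_branch("chi", chis, eps=eps, l_b=0.2, L=40.0)
            moving.append(np.isfinite(br.v_surfing))
        moving = np.array(moving)
        # motion region is monotone: once above the critical curve in chi,
        # it stays; larger eps moves the onset to smaller chi
        for row in moving:
            assert np.all(np.diff(row.astype(int)) >= 0)
        assert moving[2].sum() >= moving[1].sum() >= moving[0].sum()
        assert moving[0].sum() < len(chis)  # below the curve |v| = 0

    def test_unsorted_grid_rejected(self):
        with pytest.raises(DomainError):
            ce.scan_branch("chi", [3.0, 1.0])
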
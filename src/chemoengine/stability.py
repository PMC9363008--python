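"""Linear stability of steady co-moving solutions.

Perturbing U(z, t) = U^st(z) + e^{lt} dU(z) and z_xi(t) = e^{lt} dz about a
steady wave gives a coupled eigenproblem: the field perturbation feels
diffusion, advection v d/dz, exchange, and delta-like sources at the
footprint edges from the moving sink indicator, while the cargo row
linearizes the log-difference force.

Two independent solvers are provided.

* ``spectrum_matrix`` discretizes the problem on a periodic grid.  It works
  in the cargo-attached gauge dU~ = dU + dz * dU^st/dz, an exact change of
  variables in which the edge delta terms cancel and the eigenproblem
  reduces to the smooth rank-one-updated operator  Lop + U^st' r^T  (Lop the
  advection-diffusion-exchange operator, r the force-sampling row at the
  footprint edges).  Translation invariance appears as an exact eigenvalue 0
  (the Goldstone mode), which is appended explicitly.

* ``spectrum_dispersion`` keeps the piecewise-exponential ansatz: dU is
  built from exponents mu_+-(l) = (-v +- sqrt(v^2+4(1+l)))/2 on the inner
  and outer intervals, matched with the edge jump conditions and the cargo
  equation; eigenvalues are roots of the resulting 5x5 determinant, polished
  by complex Newton iteration with the trivial root deflated.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from .errors import ConvergenceError, UnphysicalProfileError
from .wave import SteadyWave, WaveGeometry, solve_profile

__all__ = [
    "Spectrum",
    "spectrum_matrix",
    "spectrum_dispersion",
    "destabilizing_eigenvalue",
    "exchange_of_stability_chi",
    "restabilization_chi",
    "unphysical_onset",
]


@dataclass
class Spectrum:
    """Eigenvalues of the linearized dynamics about a steady wave."""

    eigenvalues: np.ndarray  # complex, sorted by real part, descending
    base: SteadyWave
    method: str  # "matrix" | "dispersion"
    goldstone_index: int | None
    flags: list[str] = dc_field(default_factory=list)

    @property
    def leading(self) -> complex:
        """Largest-real-part eigenvalue excluding the Goldstone zero."""
        for i, ev in enumerate(self.eigenvalues):
            if i != self.goldstone_index:
                return complex(ev)
        raise ValueError("spectrum contains only the Goldstone mode")

    @property
    def stable(self) -> bool:
        return self.leading.real < 0


def _force_row_terms(sw: SteadyWave):
    up, um = sw.edge_values
    if up <= 0 or um <= 0:
        raise UnphysicalProfileError(
            f"U^st(+-l_b) <= 0 at chi={sw.chi}: force linearization singular")
    l_b = sw.geom.l_b
    a = sw.geom.eps * (sw.derivative(l_b) / up - sw.derivative(-l_b) / um)
    return up, um, a


def _aligned_grid(sw: SteadyWave, n_grid: int):
    """Periodic cell-centered grid with +-l_b exactly on cell centers."""
    l_b, L = sw.geom.l_b, sw.geom.L
    m = max(1, round(l_b * n_grid / L - 0.5))
    dz = l_b / (m + 0.5)
    n = round(L / dz)
    if n % 2:
        m += 1
        dz = l_b / (m + 0.5)
        n = round(L / dz)
    if abs(n * dz - L) > 1e-8 * L:
        raise ConvergenceError(
            f"cannot align footprint edges on a grid of ~{n_grid} cells for "
            f"l_b={l_b}, L={L}")
    z = -L / 2 + (np.arange(n) + 0.5) * dz
    jp = round((l_b + L / 2) / dz - 0.5)
    jm = round((-l_b + L / 2) / dz - 0.5)
    return z, dz, n, jp, jm


def _matrix_parts(sw: SteadyWave, n_grid: int):
    z, dz, n, jp, jm = _aligned_grid(sw, n_grid)
    v = sw.v
    main = -2.0 / dz**2 - 1.0
    up = 1.0 / dz**2 + v / (2 * dz)
    lo = 1.0 / dz**2 - v / (2 * dz)
    Lop = sp.diags(
        [np.full(n, main), np.full(n - 1, up), np.full(n - 1, lo)],
        [0, 1, -1], format="lil")
    Lop[0, n - 1] = lo
    Lop[n - 1, 0] = up
    Up_lb, Um_lb, _ = _force_row_terms(sw)
    r = np.zeros(n)
    r[jp] = sw.geom.eps / Up_lb
    r[jm] = -sw.geom.eps / Um_lb
    ustp = sw.derivative(z)
    return Lop.tocsc(), ustp, r, n, dz


def _rightmost_eigs(Lop, u, r, n, sigmas, k=8):
    """Eigenvalues of Lop + u r^T near each shift, via Sherman-Morrison
    shift-invert Arnoldi (the rank-one update keeps the LU sparse)."""
    found: list[complex] = []
    eye = sp.identity(n, format="csc", dtype=complex)
    A = Lop.astype(complex)
    for sigma in sigmas:
        lu = spla.splu((A - complex(sigma) * eye).tocsc())
        w = lu.solve(u.astype(complex))
        denom = 1.0 + r @ w
        if abs(denom) < 1e-14:
            continue

        def opinv(b):
            y = lu.solve(np.asarray(b, complex))
            return y - (r @ y) / denom * w

        OP = spla.LinearOperator((n, n), matvec=opinv, dtype=complex)
        try:
            vals = spla.eigs(OP, k=min(k, n - 2), which="LM",
                             return_eigenvectors=False)
        except spla.ArpackNoConvergence as exc:
            vals = exc.eigenvalues
        found.extend(sigma + 1.0 / v for v in vals if v != 0)
    # deduplicate
    out: list[complex] = []
    for v in sorted(found, key=lambda c: (-c.real, abs(c.imag))):
        if not any(abs(v - o) < 1e-8 * max(1.0, abs(o)) for o in out):
            out.append(v)
    return out


def _shifts_for(sw: SteadyWave) -> list[float]:
    """Shift-invert targets: near zero for the soft modes plus, on the
    localized branch, the static-force rate a (the unstable mode tracks it
    once the footprint-edge concentration gets small)."""
    shifts = [0.35, -0.6]
    try:
        _, _, a = _force_row_terms(sw)
        if a > 1.0:
            shifts.insert(0, float(a))
    except UnphysicalProfileError:
        pass
    return shifts


def spectrum_matrix(sw: SteadyWave, n_grid: int = 4096, k: int = 8,
                    check_convergence: bool = False) -> Spectrum:
    """Rightmost eigenvalues of the discretized linearization.

    ``check_convergence=True`` recomputes on a doubled grid and raises
    :class:`ConvergenceError` if the leading eigenvalue moves by more than
    1e-3 (relative for large eigenvalues).
    """
    if n_grid < 256:
        raise ValueError("n_grid must be at least 256")
    Lop, ustp, r, n, dz = _matrix_parts(sw, n_grid)
    vals = _rightmost_eigs(Lop, ustp, r, n, _shifts_for(sw), k=k)
    vals = [v for v in vals if abs(v) > 1e-7]  # drop the discretized
    # translation mode; the exact Goldstone zero is appended instead
    vals.append(0.0 + 0.0j)
    evs = np.array(sorted(vals, key=lambda c: -c.real), dtype=complex)
    gi = int(np.argmin(np.abs(evs)))
    flags = []
    if sw.U0 <= 0:
        flags.append("unphysical_profile")
    spec = Spectrum(eigenvalues=evs, base=sw, method="matrix",
                    goldstone_index=gi, flags=flags)
    if check_convergence:
        fine = spectrum_matrix(sw, 2 * n_grid, k=k)
        lead, lead2 = spec.leading, fine.leading
        if abs(lead - lead2) / max(1.0, abs(lead)) > 1e-3:
            raise ConvergenceError(
                f"unconverged spectrum: leading {lead} -> {lead2} on "
                "grid doubling")
    return spec


# ---------------------------------------------------------------------------
# dispersion relation

def _dispersion_matrix(lam: complex, sw: SteadyWave) -> np.ndarray:
    l_b, L = sw.geom.l_b, sw.geom.L
    v, chi, eps = sw.v, sw.chi, sw.geom.eps
    s = cmath.sqrt(v * v + 4.0 * (1.0 + lam))
    if s.real < 0:
        s = -s
    mp, mm = (-v + s) / 2.0, (-v - s) / 2.0
    Up_lb, Um_lb, a = _force_row_terms(sw)
    e_in_p = cmath.exp(-2 * mp * l_b)
    e_in_m = cmath.exp(2 * mm * l_b)
    e_out_p = cmath.exp(mp * (2 * l_b - L))
    e_out_m = cmath.exp(mm * (L - 2 * l_b))
    # unknowns: c1, c2 (inner), c3, c4 (outer), dz
    return np.array([
        # continuity at +l_b
        [-1.0, -e_in_m, e_out_p, 1.0, 0.0],
        # derivative jump at +l_b: outer' - inner' = chi*dz
        [-mp, -mm * e_in_m, mp * e_out_p, mm, -chi],
        # continuity at -l_b (outer side reached around the ring)
        [e_in_p, 1.0, -1.0, -e_out_m, 0.0],
        # derivative jump at -l_b: inner' - outer' = -chi*dz
        [mp * e_in_p, mm, -mp, -mm * e_out_m, chi],
        # cargo equation: (a - lam) dz + eps*[dU(+)/U(+) - dU(-)/U(-)] = 0
        [eps / Up_lb - eps * e_in_p / Um_lb,
         eps * e_in_m / Up_lb - eps / Um_lb, 0.0, 0.0, a - lam],
    ], dtype=complex)


def dispersion_det(lam: complex, sw: SteadyWave,
                   deflate_goldstone: bool = True) -> complex:
    """Characteristic determinant; its roots are the eigenvalues.

    Translation invariance makes lambda = 0 a root for every profile, so by
    default the determinant is deflated by 1/lambda to expose the physical
    modes near zero.
    """
    d = complex(np.linalg.det(_dispersion_matrix(lam, sw)))
    return d / lam if deflate_goldstone else d


def _newton_root(f, lam0: complex, tol: float = 1e-12,
                 itmax: int = 100) -> complex | None:
    lam = complex(lam0)
    for _ in range(itmax):
        h = 1e-7 * max(1.0, abs(lam))
        d = (f(lam + h) - f(lam - h)) / (2 * h)
        if d == 0:
            return None
        step = f(lam) / d
        lam -= step
        if abs(step) <= tol * max(1.0, abs(lam)):
            return lam
    return None


def spectrum_dispersion(sw: SteadyWave, init_guesses=None,
                        n_grid: int = 2048) -> Spectrum:
    """Polished eigenvalues from the transcendental dispersion relation.

    Initial guesses default to the matrix method's rightmost eigenvalues.
    Non-converging guesses are dropped; duplicates are merged at 1e-8.  The
    exact Goldstone root 0 (verified on the non-deflated determinant) is
    included.
    """
    if init_guesses is None:
        init_guesses = [complex(ev) for ev in
                        spectrum_matrix(sw, n_grid).eigenvalues
                        if abs(ev) > 1e-7]
    f = lambda lam: dispersion_det(lam, sw, deflate_goldstone=True)
    roots: list[complex] = []
    for g in init_guesses:
        r = _newton_root(f, g)
        if r is None:
            continue
        if not any(abs(r - o) <= 1e-8 * max(1.0, abs(o)) for o in roots):
            roots.append(r)
    roots.append(0.0 + 0.0j)  # Goldstone
    evs = np.array(sorted(roots, key=lambda c: -c.real), dtype=complex)
    gi = int(np.argmin(np.abs(evs)))
    flags = ["unphysical_profile"] if sw.U0 <= 0 else []
    return Spectrum(eigenvalues=evs, base=sw, method="dispersion",
                    goldstone_index=gi, flags=flags)


# ---------------------------------------------------------------------------
# scans along the localized branch

def destabilizing_eigenvalue(chi: float, geom: WaveGeometry,
                             n_grid: int = 2048) -> float:
    """Real part of the leading non-Goldstone mode of the localized branch.

    Matrix-method guesses polished by the dispersion relation.  Raises
    :class:`UnphysicalProfileError` once U^st(l_b) <= 0 (the force, and with
    it the coupled eigenproblem, ceases to exist there).
    """
    sw = solve_profile(0.0, chi, geom)
    spec = spectrum_dispersion(sw, n_grid=n_grid)
    return float(spec.leading.real)


def exchange_of_stability_chi(geom: WaveGeometry, lo: float = 1.0,
                              hi: float = 4.5, tol: float = 1e-4) -> float:
    """chi at which the localized branch first destabilizes (crosses zero
    upward); coincides with the pitchfork point chi_c."""
    f = lambda chi: destabilizing_eigenvalue(chi, geom)
    return float(brentq(f, lo, hi, xtol=tol))


def restabilization_chi(geom: WaveGeometry, lo: float = 4.0,
                        hi: float = 8.0, tol: float = 1e-4) -> float:
    """chi above which the localized branch is no longer unstable.

    The unstable mode's rate grows with chi and diverges where the
    footprint-edge concentration U^st(l_b) reaches zero; beyond that point
    the leading finite eigenvalue is negative again.  The returned boundary
    is the edge of the unstable region (bisection to ``tol``).  Note the
    localized profile is already unphysical there (U^st(0) < 0, see
    :func:`unphysical_onset`), so the regained stability is flagged.
    """

    def unstable(chi: float) -> bool:
        try:
            return destabilizing_eigenvalue(chi, geom) > 0
        except UnphysicalProfileError:
            return False  # force singular: unstable mode has left the system

    if not unstable(lo):
        raise ConvergenceError(f"localized branch not unstable at chi={lo}")
    if unstable(hi):
        raise ConvergenceError(f"localized branch still unstable at chi={hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if unstable(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def unphysical_onset(geom: WaveGeometry, lo: float = 1.0, hi: float = 10.0,
                     tol: float = 1e-4) -> float:
    """chi* where U^st(0) of the localized branch crosses zero.

    U^st(0) is monotone decreasing in chi, so the root is unique; beyond it
    the u >> K_d simplification has broken down and the localized solution
    is unphysical.
    """
    f = lambda chi: solve_profile(0.0, chi, geom).U0
    if f(lo) <= 0:
        raise ConvergenceError("U^st(0) already non-positive at scan start")
    if f(hi) > 0:
        raise ConvergenceError(f"no onset in range ({lo}, {hi})")
    return float(brentq(f, lo, hi, xtol=tol))
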
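"""Analytic co-moving-frame solutions of the simplified engine.

For a single cargo on a 1D ring, without noise, and in the strong-binding
regime u >> K_d (Hill factor = 1), the steady state in the frame z = x - vt
with the cargo pinned at z = 0 obeys

    U'' + v U' + (1 - U) - chi * theta(l_b - |z|) = 0 .

The general solution is piecewise exponential with exponents
lambda_+- = (-v +- sqrt(v^2 + 4)) / 2; four coefficients are fixed by C^1
matching at z = +-l_b and periodic closure on [-L/2, L/2].  The cargo's
velocity must equal the chemophoresis force it feels, which for the
simplified force law collapses to a log difference:

    v = eps * [ln U(l_b) - ln U(-l_b)] =: eps * delta_mu(v, chi).

Roots of the residual eps*delta_mu - v are the steady velocities: v = 0
(localized) always, and a +-v pair (surfing on the traveling wave) beyond a
supercritical pitchfork at chi_c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, DomainError, UnphysicalProfileError

__all__ = [
    "WaveGeometry",
    "SteadyWave",
    "BifurcationBranch",
    "solve_profile",
    "residual",
    "residual_slope",
    "find_velocities",
    "critical_chi",
    "critical_k",
    "limit_velocity",
    "critical_k_limit",
    "scan_branch",
]

ROOT_TOL = 1e-10
_EDGE = 1.0 - 1e-12  # evaluate U at the footprint edge from just inside


@dataclass(frozen=True)
class WaveGeometry:
    """Geometry/force parameters of the simplified analytic problem."""

    l_b: float = 0.2
    L: float = 40.0
    eps: float = 5.0

    def __post_init__(self):
        if not (0 < self.l_b < self.L / 2):
            raise DomainError(f"need 0 < l_b < L/2, got l_b={self.l_b}")
        if self.eps < 0:
            raise DomainError("eps must be non-negative")


@dataclass(frozen=True)
class SteadyWave:
    """Piecewise-exponential steady profile U^st(z) in the co-moving frame.

    Basis functions are anchored at the matching points so that every
    exponential stays bounded by one on its interval (well-conditioned for
    arbitrarily large L):

    inner  |z| < l_b:        1 - chi + C e^{lp (z - l_b)} + D e^{lm (z + l_b)}
    outer  l_b < z < L - l_b: 1 + A e^{lp (z - (L - l_b))} + B e^{lm (z - l_b)}

    with lp, lm = (-v +- sqrt(v^2+4))/2 and the outer branch parameterized
    around the ring (z and z - L identified).
    """

    v: float
    chi: float
    geom: WaveGeometry
    coeffs: tuple[float, float, float, float]  # (A, B, C, D)
    branch: str  # localized | surfing_plus | surfing_minus

    @property
    def exponents(self) -> tuple[float, float]:
        s = math.sqrt(self.v**2 + 4.0)
        return (-self.v + s) / 2.0, (-self.v - s) / 2.0

    def __call__(self, z) -> np.ndarray:
        lp, lm = self.exponents
        A, B, C, D = self.coeffs
        l_b, L = self.geom.l_b, self.geom.L
        z = np.asarray(z, dtype=float)
        zm = np.mod(z + L / 2, L) - L / 2
        out = np.empty_like(zm)
        inner = np.abs(zm) < l_b
        zi = zm[inner]
        out[inner] = ((1 - self.chi) + C * np.exp(lp * (zi - l_b))
                      + D * np.exp(lm * (zi + l_b)))
        zo = np.mod(zm[~inner] - l_b, L) + l_b
        out[~inner] = (1 + A * np.exp(lp * (zo - (L - l_b)))
                       + B * np.exp(lm * (zo - l_b)))
        return out if out.shape else float(out)

    def derivative(self, z) -> np.ndarray:
        lp, lm = self.exponents
        A, B, C, D = self.coeffs
        l_b, L = self.geom.l_b, self.geom.L
        z = np.asarray(z, dtype=float)
        zm = np.mod(z + L / 2, L) - L / 2
        out = np.empty_like(zm)
        inner = np.abs(zm) < l_b
        zi = zm[inner]
        out[inner] = (C * lp * np.exp(lp * (zi - l_b))
                      + D * lm * np.exp(lm * (zi + l_b)))
        zo = np.mod(zm[~inner] - l_b, L) + l_b
        out[~inner] = (A * lp * np.exp(lp * (zo - (L - l_b)))
                       + B * lm * np.exp(lm * (zo - l_b)))
        return out if out.shape else float(out)

    @property
    def U0(self) -> float:
        """Profile value at the cargo center z = 0."""
        return float(self(0.0))

    @property
    def edge_values(self) -> tuple[float, float]:
        """U at the footprint edges, (U(+l_b), U(-l_b))."""
        l_b = self.geom.l_b
        return float(self(l_b * _EDGE)), float(self(-l_b * _EDGE))

    @property
    def delta_mu(self) -> float:
        """Chemical-potential difference ln U(l_b) - ln U(-l_b)."""
        up, um = self.edge_values
        if up <= 0 or um <= 0:
            raise UnphysicalProfileError(
                f"U^st <= 0 at footprint edge (chi={self.chi}, v={self.v}); "
                "log-force undefined")
        return math.log(up) - math.log(um)

    def mass_defect(self) -> float:
        """Ring integral of (1 - U^st) dz, analytically.

        Integrating the steady ODE over the ring kills the derivative
        terms, so this must equal 2*l_b*chi for every valid profile.
        """
        lp, lm = self.exponents
        A, B, C, D = self.coeffs
        l_b, L = self.geom.l_b, self.geom.L

        def seg(coef, lam, z0, z1, anchor):
            # integral of coef*exp(lam*(z - anchor)) over [z0, z1]
            return coef / lam * (math.exp(lam * (z1 - anchor))
                                 - math.exp(lam * (z0 - anchor)))

        inner = (2 * l_b * self.chi
                 - seg(C, lp, -l_b, l_b, l_b) - seg(D, lm, -l_b, l_b, -l_b))
        outer = (- seg(A, lp, l_b, L - l_b, L - l_b)
                 - seg(B, lm, l_b, L - l_b, l_b))
        return inner + outer

    def ode_residual(self, z, h: float = 0.005) -> np.ndarray:
        """U'' + v U' + (1 - U) - chi*theta at collocation points.

        Derivatives are taken by 6th-order central differences of the
        piecewise evaluation itself, so the check exercises the actual
        representation (coefficients, region selection, ring wrap).
        Points within 3h of a footprint edge are skipped (the profile is
        only C^1 there).
        """
        l_b, L = self.geom.l_b, self.geom.L
        z = np.asarray(z, dtype=float)
        zm = np.mod(z + L / 2, L) - L / 2
        keep = np.abs(np.abs(zm) - l_b) > 3.5 * h
        zs = zm[keep]
        c1 = np.array([-1.0, 9.0, -45.0, 0.0, 45.0, -9.0, 1.0]) / 60.0
        c2 = np.array([2.0, -27.0, 270.0, -490.0, 270.0, -27.0, 2.0]) / 180.0
        offs = np.arange(-3, 4)
        vals = np.stack([self(zs + k * h) for k in offs])
        d1 = np.tensordot(c1, vals, axes=1) / h
        d2 = np.tensordot(c2, vals, axes=1) / h**2
        theta = (np.abs(zs) < l_b).astype(float)
        res = d2 + self.v * d1 + (1.0 - self(zs)) - self.chi * theta
        out = np.full(zm.shape, np.nan)
        out[keep] = res
        return out


def _solve_coeffs(v: float, chi: float, geom: WaveGeometry):
    l_b, L = geom.l_b, geom.L
    s = math.sqrt(v * v + 4.0)
    lp, lm = (-v + s) / 2.0, (-v - s) / 2.0
    e1 = math.exp(lp * (2 * l_b - L))   # outer lp basis at z = l_b
    e2 = math.exp(lm * (L - 2 * l_b))   # outer lm basis at z = L - l_b
    e3 = math.exp(2 * lm * l_b)         # inner lm basis at z = +l_b
    e4 = math.exp(-2 * lp * l_b)        # inner lp basis at z = -l_b
    M = np.array([
        [e1, 1.0, -1.0, -e3],           # continuity at +l_b
        [lp * e1, lm, -lp, -lm * e3],   # C^1 at +l_b
        [1.0, e2, -e4, -1.0],           # continuity at -l_b (ring wrap)
        [lp, lm * e2, -lp * e4, -lm],   # C^1 at -l_b
    ])
    rhs = np.array([-chi, 0.0, -chi, 0.0])
    try:
        A, B, C, D = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:  # cannot occur for v^2 + 4 > 0
        raise ConvergenceError(f"singular matching system: {exc}") from exc
    return (float(A), float(B), float(C), float(D))


def solve_profile(v: float, chi: float,
                  geom: WaveGeometry | None = None, **geom_kw) -> SteadyWave:
    """Exact piecewise steady profile for given wave speed and chi."""
    geom = geom if geom is not None else WaveGeometry(**geom_kw)
    if chi < 0:
        raise DomainError("chi must be non-negative")
    if not math.isfinite(v):
        raise DomainError("v must be finite")
    branch = ("localized" if v == 0
              else "surfing_plus" if v > 0 else "surfing_minus")
    return SteadyWave(v=v, chi=chi, geom=geom,
                      coeffs=_solve_coeffs(v, chi, geom), branch=branch)


def residual(v: float, chi: float,
             geom: WaveGeometry | None = None, **geom_kw) -> float:
    """Self-consistency residual eps*delta_mu(v, chi) - v.

    Odd in v; its roots are the steady cargo velocities.
    """
    geom = geom if geom is not None else WaveGeometry(**geom_kw)
    if v == 0.0:
        return 0.0  # exact by mirror symmetry
    sw = solve_profile(v, chi, geom)
    return geom.eps * sw.delta_mu - v


def residual_slope(chi: float, geom: WaveGeometry, h: float = 1e-6) -> float:
    """d(residual)/dv at v = 0 by central differences.

    Positive slope means the odd residual has nonzero roots (the surfing
    pair exists); the sign change locates the pitchfork.
    """
    return (residual(h, chi, geom) - residual(-h, chi, geom)) / (2 * h)


def find_velocities(chi: float, geom: WaveGeometry | None = None,
                    v_max: float | None = None, n_scan: int = 400,
                    **geom_kw) -> np.ndarray:
    """All steady velocities at this chi: {0} or {-v, 0, +v}.

    The trivial root is deflated (the residual is odd, so only v > 0 is
    scanned); sign-change brackets from a coarse grid are polished by
    Brent's method to |residual| < 1e-10 in v.  By mirror symmetry the
    negative root is the reflection of the positive one.
    """
    geom = geom if geom is not None else WaveGeometry(**geom_kw)
    if chi < 0:
        raise DomainError("chi must be non-negative")
    if v_max is None:
        # the vanishing-size limit bounds the attainable speed from above
        v_max = 2.0 * (chi * geom.l_b * (geom.eps * geom.l_b + 1.0) + 2.0)

    def f(v):
        try:
            return residual(v, chi, geom)
        except UnphysicalProfileError:
            return math.nan

    vs = np.linspace(1e-6, v_max, n_scan)
    fs = np.array([f(v) for v in vs])
    roots = [0.0]
    ok = np.isfinite(fs)
    for i in range(n_scan - 1):
        if ok[i] and ok[i + 1] and fs[i] * fs[i + 1] < 0:
            r = brentq(f, vs[i], vs[i + 1], xtol=ROOT_TOL)
            if abs(f(r)) < 1e-8 and r > 1e-5:
                roots.append(r)
                roots.append(-r)
    return np.array(sorted(set(np.round(roots, 12))))


def critical_chi(geom: WaveGeometry | None = None, chi_max: float = 20.0,
                 tol: float = 1e-4, method: str = "slope",
                 **geom_kw) -> float:
    """Pitchfork location chi_c where the surfing pair emerges.

    ``method='slope'`` bisects the sign change of d(residual)/dv at v = 0
    (the linearized criterion); ``method='scan'`` bisects on the emergence
    of nonzero roots of the full residual.  The two detectors agree to
    better than 1e-3 and the default tolerance is 1e-4.
    """
    geom = geom if geom is not None else WaveGeometry(**geom_kw)
    if method == "slope":
        f = lambda chi: residual_slope(chi, geom)
    elif method == "scan":
        f = lambda chi: 1.0 if find_velocities(chi, geom).size > 1 else -1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    lo = 1e-6
    if f(lo) > 0:
        raise ConvergenceError("surfing branch already present at chi ~ 0")
    # walk up to bracket the onset; stop where the localized profile itself
    # turns log-singular (no bifurcation below the singularity)
    hi = None
    for cand in np.linspace(lo, chi_max, 41)[1:]:
        try:
            val = f(cand)
        except UnphysicalProfileError:
            break
        if val > 0:
            hi = cand
            break
        lo = cand
    if hi is None:
        raise ConvergenceError(
            f"no bifurcation found for chi in (0, {chi_max}]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def critical_k(N: int, D_rel: float, l_b: float = 0.2, L: float = 40.0,
               tol: float = 1e-5) -> float:
    """Critical per-ParB rate k_c at finite cargo radius.

    Same bifurcation as :func:`critical_chi`, expressed through
    chi = k*N/(2*l_b) and eps = D*N/(2*l_b).
    """
    eps = D_rel * N / (2 * l_b)
    geom = WaveGeometry(l_b=l_b, L=L, eps=eps)
    chi_c = critical_chi(geom, tol=tol * N / (2 * l_b))
    return chi_c * 2 * l_b / N


def critical_k_limit(N: int, D_rel: float) -> float:
    """Closed-form critical rate in the vanishing-size limit:
    k_c = 2 / [N (D N / 2 + 1)]."""
    if N <= 0 or D_rel <= 0:
        raise DomainError("N and D_rel must be positive")
    return 2.0 / (N * (D_rel * N / 2.0 + 1.0))


def limit_velocity(k: float, D_rel: float, N: int) -> np.ndarray:
    """Steady velocities in the l_b -> 0, L -> infinity limit.

    The cargo becomes a point sink of strength k*N and the self-consistency
    closes in closed form: sqrt(v^2 + 4) = k N (D N / 2 + 1), so

        v = +- sqrt([kN(DN/2+1) + 2] [kN(DN/2+1) - 2])   for k > k_c,

    and v = 0 otherwise (the bracket product sits under a square root; the
    small-(k - k_c) scaling is the usual pitchfork square root).
    """
    if k < 0 or D_rel <= 0 or N <= 0:
        raise DomainError("k >= 0 and D_rel, N > 0 required")
    g = k * N * (D_rel * N / 2.0 + 1.0)
    if g <= 2.0:
        return np.array([0.0])
    v = math.sqrt((g + 2.0) * (g - 2.0))
    return np.array([-v, 0.0, v])


@dataclass
class BifurcationBranch:
    """|v| along a parameter scan, with the detected critical point."""

    parameter: str
    grid: np.ndarray
    v_surfing: np.ndarray  # |v| of the surfing pair, NaN where absent
    v_localized: np.ndarray  # always 0 where the profile exists
    critical_value: float | None
    kind: str  # "supercritical pitchfork" | "inverse pitchfork" | "none"


def scan_branch(parameter: str, grid, *, N: int = 40, k: float = 0.1,
                D_rel: float = 0.05, l_b: float = 0.2, L: float = 40.0,
                eps: float | None = None) -> BifurcationBranch:
    """Continue the surfing branch along a sorted parameter grid.

    Supported parameters: ``chi`` (eps fixed), ``k``, ``l_b``, ``N`` (the
    latter three update chi = k N/(2 l_b) and eps = D N/(2 l_b) per point).
    Newton/Brent solves are warm-started from the previous grid point; a
    root jumping by much more than the local trend triggers a local refine.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise DomainError("grid must be sorted ascending")

    def setup(p):
        if parameter == "chi":
            e = eps if eps is not None else D_rel * N / (2 * l_b)
            return p, WaveGeometry(l_b=l_b, L=L, eps=e)
        if parameter == "k":
            return p * N / (2 * l_b), WaveGeometry(
                l_b=l_b, L=L, eps=D_rel * N / (2 * l_b))
        if parameter == "l_b":
            return k * N / (2 * p), WaveGeometry(
                l_b=p, L=L, eps=D_rel * N / (2 * p))
        if parameter == "N":
            return k * p / (2 * l_b), WaveGeometry(
                l_b=l_b, L=L, eps=D_rel * p / (2 * l_b))
        raise ValueError(f"unknown scan parameter {parameter!r}")

    vs = np.full(grid.size, np.nan)
    for i, p in enumerate(grid):
        chi, geom = setup(p)
        roots = find_velocities(chi, geom)
        if roots.size > 1:
            cand = roots.max()
            prev = vs[i - 1] if i and np.isfinite(vs[i - 1]) else None
            if prev is not None and prev > 0 and cand > 10 * max(prev, 1e-3):
                # branch jump: refine with a denser local scan
                roots = find_velocities(chi, geom, v_max=3 * prev, n_scan=2000)
                cand = roots.max() if roots.size > 1 else np.nan
            vs[i] = cand

    finite = np.isfinite(vs) & (vs > 0)
    if not finite.any():
        crit, kind = None, "none"
    else:
        first, last = np.flatnonzero(finite)[[0, -1]]
        if parameter == "l_b":
            crit = grid[last]
            kind = "inverse pitchfork"
        else:
            crit = grid[first]
            kind = "supercritical pitchfork"
    return BifurcationBranch(parameter=parameter, grid=grid, v_surfing=vs,
                             v_localized=np.zeros_like(vs),
                             critical_value=crit, kind=kind)
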
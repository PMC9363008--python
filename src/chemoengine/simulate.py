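"""Hybrid integrator: explicit Euler for the ParA-ATP field coupled to
Euler-Maruyama dynamics for finite-size plasmids, in 1D and 2D.

The field obeys (normalized)

    du/dt = laplacian(u) + (1 - u) - chi * u^m/(K_d^m + u^m) * sum_i theta_i

and each plasmid follows

    dxi_i/dt = eps * int_fp u^m/(K_d^m + u^m) * grad(u)/u  dr + eta_i(t)

with Gaussian white noise of per-component variance 2*D per unit time.
Neumann (no-flux) field boundaries pair with reflecting walls for the
plasmids, periodic with periodic wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .errors import DomainError, StepError, UnphysicalProfileError
from .geometry import Footprint, cell_centers
from .params import ModelParams

__all__ = [
    "ScalarField",
    "PlasmidSet",
    "Trajectory",
    "step_field",
    "chemophoresis_force",
    "step_plasmids",
    "simulate",
]


@dataclass
class ScalarField:
    """ParA-ATP concentration u on a regular grid (1D: (n,), 2D: (n, n))."""

    values: np.ndarray
    dx: float
    bc_field: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DomainError("field contains non-finite values")

    @classmethod
    def uniform(cls, params: ModelParams, value: float = 1.0) -> "ScalarField":
        shape = (params.n_cells,) * params.dim
        return cls(np.full(shape, float(value)), params.dx, params.bc_field)


@dataclass
class PlasmidSet:
    """Positions xi_i of M plasmids; shape (M,) in 1D, (M, 2) in 2D."""

    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))

    @property
    def M(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def equispaced(cls, params: ModelParams, jitter: float = 0.0,
                   rng: np.random.Generator | None = None) -> "PlasmidSet":
        """Regular positions (2i-1)L/(2M), optionally with seeded jitter."""
        base = (2 * np.arange(params.M) + 1) * params.L / (2 * params.M)
        if params.dim == 2:
            base = np.column_stack([base, np.full(params.M, params.L / 2)])
        if jitter > 0:
            rng = rng if rng is not None else np.random.default_rng(params.seed)
            base = base + jitter * rng.standard_normal(base.shape)
        return cls(base)


@dataclass
class Trajectory:
    """Sampled plasmid positions over time, with provenance."""

    times: np.ndarray
    positions: np.ndarray  # (n_samples, M) in 1D, (n_samples, M, 2) in 2D
    params: ModelParams
    seed: int
    snapshots: list = dc_field(default_factory=list)  # (t, u.copy()) pairs

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("trajectory times must be strictly increasing")
        if self.positions.shape[0] != self.times.size:
            raise DomainError("times/positions length mismatch")

    def to_tsv(self, path) -> None:
        """Tab-separated table: time, then xi_1 ... xi_M per axis."""
        pos = self.positions.reshape(self.times.size, -1)
        M = self.params.M
        if self.params.dim == 1:
            names = [f"xi_{i+1}" for i in range(M)]
        else:
            names = [f"xi_{i+1}_{ax}" for i in range(M) for ax in ("x", "y")]
        header = "time\t" + "\t".join(names)
        np.savetxt(path, np.column_stack([self.times, pos]),
                   delimiter="\t", header=header, comments="")


# ---------------------------------------------------------------------------
# spatial operators

def _laplacian(u: np.ndarray, dx: float, bc: str) -> np.ndarray:
    if bc == "periodic":
        out = -2.0 * u.ndim * u
        for ax in range(u.ndim):
            out = out + np.roll(u, 1, axis=ax) + np.roll(u, -1, axis=ax)
    else:  # neumann: mirror ghost cells, i.e. replicate the edge value
        out = np.zeros_like(u)
        for ax in range(u.ndim):
            up = np.concatenate([u.take(range(1, u.shape[ax]), axis=ax),
                                 u.take([-1], axis=ax)], axis=ax)
            um = np.concatenate([u.take([0], axis=ax),
                                 u.take(range(0, u.shape[ax] - 1), axis=ax)],
                                axis=ax)
            out = out + up + um - 2.0 * u
    return out / dx**2


def _gradient(u: np.ndarray, dx: float, bc: str, axis: int = 0) -> np.ndarray:
    """Central differences; at Neumann walls one-sided differences are used
    so that footprint cells adjacent to a wall keep a non-degenerate force
    (mirrored ghosts would zero the gradient there and pin the cargo)."""
    if bc == "periodic":
        return (np.roll(u, -1, axis=axis) - np.roll(u, 1, axis=axis)) / (2 * dx)
    g = np.empty_like(u)
    n = u.shape[axis]
    sl = [slice(None)] * u.ndim

    def at(i):
        s = sl.copy()
        s[axis] = i
        return tuple(s)

    g[at(slice(1, n - 1))] = (u[at(slice(2, n))] - u[at(slice(0, n - 2))]) / (2 * dx)
    g[at(0)] = (u[at(1)] - u[at(0)]) / dx
    g[at(n - 1)] = (u[at(n - 1)] - u[at(n - 2)]) / dx
    return g


def _hill(u: np.ndarray, K_d: float, m: int) -> np.ndarray:
    if m == 1:
        return u / (K_d + u)
    um = u**m
    return um / (K_d**m + um)


def _footprint_mask(xi: np.ndarray, params: ModelParams) -> np.ndarray:
    """Boolean mask of cells strictly within l_b of xi (wraps if periodic)."""
    x = cell_centers(params)
    periodic = params.bc_field == "periodic"

    def dist(c):
        d = x - c
        if periodic:
            d = (d + params.L / 2) % params.L - params.L / 2
        return d

    if params.dim == 1:
        return dist(float(xi)) ** 2 < params.l_b**2
    d0, d1 = dist(xi[0]), dist(xi[1])
    return (d0[:, None] ** 2 + d1[None, :] ** 2) < params.l_b**2


# ---------------------------------------------------------------------------
# single steps (functional style; `simulate` fuses them in one loop)

def step_field(field: ScalarField, plasmids: PlasmidSet,
               params: ModelParams) -> ScalarField:
    """One explicit Euler step of the reaction-diffusion equation."""
    u = field.values
    sink = np.zeros_like(u)
    for i in range(plasmids.M):
        sink[_footprint_mask(plasmids.positions[i], params)] += 1.0
    rhs = (_laplacian(u, params.dx, params.bc_field) + (1.0 - u)
           - params.chi * _hill(u, params.K_d, params.m) * sink)
    new = u + params.dt * rhs
    if np.any(new < 0):
        raise StepError("negative concentration after field step; dt too large")
    return ScalarField(new, field.dx, field.bc_field)


def chemophoresis_force(field: ScalarField, fp: Footprint,
                        params: ModelParams) -> np.ndarray:
    """Force on one cargo: eps * sum_fp hill(u) * grad(u)/u * dx^dim.

    Points up the concentration gradient.  Raises
    :class:`UnphysicalProfileError` if u vanishes inside the footprint.
    """
    u = field.values
    flat = u.ravel()[fp.cell_indices]
    if np.any(flat <= 0):
        raise UnphysicalProfileError(
            "u <= 0 inside footprint: chemophoresis force is singular")
    hill = _hill(flat, params.K_d, params.m)
    meas = params.dx**params.dim
    out = np.empty(params.dim)
    for ax in range(params.dim):
        g = _gradient(u, params.dx, params.bc_field, axis=ax).ravel()
        out[ax] = params.eps * np.sum(hill * g[fp.cell_indices] / flat) * meas
    return out


def step_plasmids(plasmids: PlasmidSet, field: ScalarField,
                  params: ModelParams,
                  rng: np.random.Generator) -> PlasmidSet:
    """One Euler-Maruyama step with reflecting or periodic boundaries."""
    pos = plasmids.positions
    forces = np.zeros((plasmids.M, params.dim))
    for i in range(plasmids.M):
        mask = _footprint_mask(pos[i], params)
        fp = Footprint(tuple(np.atleast_1d(pos[i])), params.l_b,
                       np.flatnonzero(mask.ravel()), params.volume)
        forces[i] = chemophoresis_force(field, fp, params)
    forces = forces.reshape(pos.shape)
    noise = np.sqrt(2.0 * params.noise_D * params.dt) * rng.standard_normal(pos.shape)
    new = pos + params.dt * forces + noise
    if not np.all(np.isfinite(new)):
        raise StepError("non-finite plasmid position")
    return PlasmidSet(_apply_walls(new, params))


def _apply_walls(pos: np.ndarray, params: ModelParams) -> np.ndarray:
    if params.bc_plasmid == "periodic":
        return pos % params.L
    pos = np.abs(pos)  # fold xi < 0 -> -xi
    over = pos > params.L
    pos[over] = 2 * params.L - pos[over]
    return np.clip(pos, 0.0, params.L)


# ---------------------------------------------------------------------------
# the main loop

def simulate(params: ModelParams, t_end: float, *, sample_every: float = 0.5,
             snapshot_stride: int | None = None, u0: np.ndarray | None = None,
             xi0: np.ndarray | None = None, u_perturb: float = 0.0,
             xi_jitter: float | None = None) -> Trajectory:
    """Integrate the coupled system and return a sampled :class:`Trajectory`.

    The field starts uniform at 1 (optionally with a sinusoidal perturbation
    of amplitude ``u_perturb`` to seed symmetry breaking in noiseless runs)
    and plasmids start equispaced with a small seeded jitter; both are
    overridable via ``u0`` / ``xi0``.  Deterministic for a fixed seed.

    ``snapshot_stride``: store a field snapshot every that many samples.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    x = cell_centers(params)

    if u0 is not None:
        u = np.asarray(u0, dtype=float).copy()
    else:
        u = np.ones((n,) * params.dim)
        if u_perturb:
            wave = np.sin(2 * np.pi * x / params.L)
            u += u_perturb * (wave if params.dim == 1 else wave[:, None])
    if np.any(u < 0):
        raise DomainError("initial field must be non-negative")

    if xi0 is not None:
        pos = np.atleast_1d(np.asarray(xi0, dtype=float)).copy()
    else:
        jit = 0.01 * params.L if xi_jitter is None else xi_jitter
        pos = PlasmidSet.equispaced(params, jitter=jit, rng=rng).positions

    dt, dx = params.dt, params.dx
    n_steps = int(round(t_end / dt))
    stride = max(1, int(round(sample_every / dt)))
    periodic = params.bc_field == "periodic"
    meas = dx**params.dim
    sqrt_noise = np.sqrt(2.0 * params.noise_D * dt)
    M = pos.shape[0]
    # thermal noise is pre-drawn so the compiled and plain loops agree
    # exactly for a given seed
    noise = sqrt_noise * rng.standard_normal(
        (n_steps, M) if params.dim == 1 else (n_steps, M, 2))

    if _kernels.HAVE_NUMBA and params.dim == 1 and snapshot_stride is None:
        n_samples = n_steps // stride + 1
        out_pos = np.empty((n_samples, M))
        code = _kernels.run_1d(u, pos, noise, n_steps, stride, dt, dx,
                               params.chi, params.K_d, params.m, params.eps,
                               params.l_b, params.L, periodic, out_pos)
        if code >= 0:
            raise StepError(
                "negative concentration or singular force; dt too large",
                step=int(code))
        times_arr = np.arange(n_samples) * (stride * dt)
        return Trajectory(times=times_arr, positions=out_pos, params=params,
                          seed=params.seed, snapshots=[])

    times, samples, snaps = [], [], []
    pos2 = pos if pos.ndim == 2 else pos[:, None]  # (M, dim) view semantics

    for s in range(n_steps + 1):
        if s % stride == 0:
            times.append(s * dt)
            samples.append(pos.copy())
            if snapshot_stride and (s // stride) % snapshot_stride == 0:
                snaps.append((s * dt, u.copy()))
        if s == n_steps:
            break

        hill = _hill(u, params.K_d, params.m)
        lap = _laplacian(u, dx, params.bc_field)
        sink = np.zeros_like(u)
        forces = np.zeros_like(pos2, dtype=float)
        grads = [_gradient(u, dx, params.bc_field, axis=ax).ravel()
                 for ax in range(params.dim)]
        uflat, hflat = u.ravel(), hill.ravel()
        for i in range(pos2.shape[0]):
            xi = pos2[i] if params.dim == 2 else pos2[i, 0]
            mask = _footprint_mask(xi, params)
            sink[mask] += 1.0
            idx = np.flatnonzero(mask.ravel())
            ui = uflat[idx]
            if np.any(ui <= 0):
                raise StepError(
                    "u <= 0 inside footprint: force singular", step=s)
            for ax in range(params.dim):
                forces[i, ax] = params.eps * np.sum(
                    hflat[idx] * grads[ax][idx] / ui) * meas

        u = u + dt * (lap + (1.0 - u) - params.chi * hill * sink)
        if np.any(u < 0):
            raise StepError("negative concentration; dt too large", step=s)

        pos2 = pos2 + dt * forces + noise[s].reshape(pos2.shape)
        if periodic:
            pos2 %= params.L
        else:
            pos2 = np.abs(pos2)
            over = pos2 > params.L
            pos2[over] = 2 * params.L - pos2[over]
        pos = pos2 if params.dim == 2 else pos2[:, 0]

    positions = np.stack(samples)
    return Trajectory(times=np.asarray(times), positions=positions,
                      params=params, seed=params.seed, snapshots=snaps)
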
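"""Parameter containers and dimensional <-> dimensionless normalization.

The model lives in normalized units: lengths are scaled by the ParA-ATP
diffusion length ``l = sqrt(D_u / a)`` (0.4 um for the in-vivo reference
values), times by the cytoplasmic exchange time ``tau = 1/a``, and
concentrations by the reservoir concentration ``u_0``.  The two composite
rates that govern the engine are

    chi = k * N / V      (maximum hydrolysis rate per partition complex)
    eps = D * N / V      (chemophoresis force prefactor)

with ``V`` the d-dimensional bead volume, ``V = 2*l_b`` in 1D and
``pi*l_b**2`` in 2D, ``N`` the number of ParB molecules on the partition
complex, ``k`` the per-ParB catalytic rate and ``D = D_xi/D_u`` the relative
diffusion coefficient of the cargo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

from .errors import DomainError

__all__ = [
    "ModelParams",
    "DimensionalParams",
    "bead_volume",
    "derive_rates",
    "normalize",
    "denormalize",
    "load_config",
]

#: fraction of the explicit-Euler diffusion stability bound used by default
DT_SAFETY = 0.2


def bead_volume(l_b: float, dim: int) -> float:
    """Continuum d-dimensional bead volume: 2*l_b (1D) or pi*l_b**2 (2D)."""
    if l_b <= 0:
        raise DomainError(f"l_b must be positive, got {l_b}")
    if dim == 1:
        return 2.0 * l_b
    if dim == 2:
        return math.pi * l_b**2
    raise DomainError(f"dim must be 1 or 2, got {dim}")


@dataclass(frozen=True)
class ModelParams:
    """Normalized parameter set of the coupled RD/Langevin system.

    Field and cargo boundary conditions are paired: a Neumann (no-flux)
    field goes with reflecting walls for the cargo, a periodic field with
    periodic cargo wrapping.
    """

    chi: float = 2.5
    eps: float = 5.0
    K_d: float = 0.1
    m: int = 1
    l_b: float = 0.2
    M: int = 1
    L: float = 5.0
    dim: Literal[1, 2] = 1
    bc_field: Literal["neumann", "periodic"] = "neumann"
    dx: float = 0.05
    dt: float | None = None
    noise_D: float = 0.05
    seed: int = 0
    # normalization provenance (set by `normalize`, used by `denormalize`)
    n_parb: int | None = None
    length_scale: float | None = None

    def __post_init__(self):
        if self.K_d <= 0:
            raise DomainError(f"K_d must be positive, got {self.K_d}")
        if self.chi < 0 or self.eps < 0:
            raise DomainError("chi and eps must be non-negative")
        if not (0 < self.l_b < self.L / 2):
            raise DomainError(f"l_b must lie in (0, L/2), got {self.l_b}")
        if self.dx <= 0:
            raise DomainError("dx must be positive")
        if self.M < 1 or self.m < 1:
            raise DomainError("M and m must be positive integers")
        if self.noise_D < 0:
            raise DomainError("noise_D must be non-negative")
        n = self.L / self.dx
        if abs(n - round(n)) > 1e-9:
            raise DomainError(f"L/dx must be an integer, got {n}")
        if self.dt is None:
            object.__setattr__(self, "dt", DT_SAFETY * self.dx**2 / self.dim)
        if self.dt <= 0:
            raise DomainError("dt must be positive")
        if self.dt > self.dx**2 / (2 * self.dim):
            raise DomainError(
                f"dt={self.dt} violates the explicit-Euler diffusion bound "
                f"dx^2/(2*dim) = {self.dx**2 / (2 * self.dim)}"
            )

    @property
    def bc_plasmid(self) -> str:
        """Cargo boundary condition, paired with the field one."""
        return "reflecting" if self.bc_field == "neumann" else "periodic"

    @property
    def n_cells(self) -> int:
        return int(round(self.L / self.dx))

    @property
    def volume(self) -> float:
        return bead_volume(self.l_b, self.dim)

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class DimensionalParams:
    """Physical parameters, in um / seconds-free reduced rates.

    ``u0``, ``a`` and ``tau`` are the reservoir concentration, the
    cytoplasmic exchange rate and the time scale used in the normalization.
    Their absolute values never enter the normalized dynamics (only the
    derived length scale does); they are carried as documented assumptions
    and default to 1.
    """

    k: float = 0.1
    D_rel: float = 0.05
    N: int = 40
    l_b_phys: float = 0.075  # um, reported in-cell partition-complex radius
    cell_length: float = 2.0  # um
    length_scale: float = 0.4  # um, l = sqrt(D_u/a)
    u0: float = 1.0
    a: float = 1.0
    tau: float = 1.0

    def __post_init__(self):
        for name in ("k", "D_rel", "l_b_phys", "cell_length", "length_scale",
                     "u0", "a", "tau"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.N < 0:
            raise DomainError("N must be non-negative")
        if self.length_scale <= 0:
            raise DomainError("length_scale must be positive")
        if self.cell_length < 2 * self.l_b_phys:
            raise DomainError(
                f"cell_length {self.cell_length} um is smaller than the bead "
                f"diameter {2 * self.l_b_phys} um"
            )

    @property
    def l_b(self) -> float:
        """Normalized bead radius."""
        return self.l_b_phys / self.length_scale

    @property
    def rho(self) -> float:
        """Local ParB density on the partition complex, N/(2*l_b)."""
        return self.N / (2.0 * self.l_b)


def derive_rates(dp: DimensionalParams, dim: int = 1) -> tuple[float, float]:
    """Composite rates (chi, eps) = (k*N/V, D*N/V) from dimensional inputs.

    In 1D this is chi = k*N/(2*l_b) and eps = D*N/(2*l_b); both vanish for
    N = 0 (no ParB, hence neither reaction nor force).
    """
    if dp.N == 0:
        return 0.0, 0.0
    V = bead_volume(dp.l_b, dim)
    return dp.k * dp.N / V, dp.D_rel * dp.N / V


def normalize(dp: DimensionalParams, *, dx: float = 0.05, dim: int = 1,
              bc_field: str = "neumann", K_d: float = 0.1, m: int = 1,
              M: int = 1, seed: int = 0, dt: float | None = None,
              noise_D: float | None = None) -> ModelParams:
    """Build a normalized :class:`ModelParams` from physical parameters.

    The domain length is ``cell_length / length_scale``; it is snapped to an
    integer number of grid cells.  The cargo noise coefficient defaults to
    the relative diffusion D itself, as in the Langevin equation.
    """
    chi, eps = derive_rates(dp, dim)
    L = dp.cell_length / dp.length_scale
    n = max(2, round(L / dx))
    return ModelParams(
        chi=chi, eps=eps, K_d=K_d, m=m, l_b=dp.l_b, M=M, L=n * dx, dim=dim,
        bc_field=bc_field, dx=dx, dt=dt,
        noise_D=dp.D_rel if noise_D is None else noise_D, seed=seed,
        n_parb=dp.N, length_scale=dp.length_scale,
    )


def denormalize(mp: ModelParams, *, N: int | None = None,
                length_scale: float | None = None) -> DimensionalParams:
    """Invert :func:`normalize` (round-trips to machine precision).

    Needs the ParB copy number and length scale, either recorded on the
    ModelParams by `normalize` or passed explicitly.
    """
    N = N if N is not None else mp.n_parb
    ls = length_scale if length_scale is not None else mp.length_scale
    if N is None or ls is None:
        raise DomainError(
            "denormalize needs N and length_scale (not recorded on params)")
    V = bead_volume(mp.l_b, mp.dim)
    return DimensionalParams(
        k=mp.chi * V / N if N else 0.0,
        D_rel=mp.eps * V / N if N else 0.0,
        N=N,
        l_b_phys=mp.l_b * ls,
        cell_length=mp.L * ls,
        length_scale=ls,
    )


def load_config(path: str | Path) -> dict:
    """Read a flat ``key = value`` config file.

    One assignment per line; ``#`` starts a comment; values are parsed as
    int, then float, then left as strings.  Keys mirror ModelParams /
    DimensionalParams field names.
    """
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        for cast in (int, float):
            try:
                out[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            out[key] = val
    return out
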
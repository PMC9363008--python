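"""Footprints: the grid cells a finite-radius partition complex occupies.

The hydrolysis sink and the chemophoresis force both act only inside the
step-function footprint theta(l_b - |r - xi|).  Membership is decided by a
strict inequality on the cell-center distance (the boundary itself has
measure zero).  Under periodic boundaries the footprint wraps; at Neumann
walls it is truncated to in-domain cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .params import ModelParams, bead_volume

__all__ = ["Footprint", "make_footprint", "cell_centers"]


def cell_centers(params: ModelParams) -> np.ndarray:
    """Cell-center coordinates along one axis: (j + 1/2) dx, j = 0..n-1."""
    return (np.arange(params.n_cells) + 0.5) * params.dx


@dataclass(frozen=True)
class Footprint:
    """Grid realization of one cargo's reaction footprint."""

    center: tuple[float, ...]
    radius: float
    cell_indices: np.ndarray  # flat indices into the (raveled) field array
    volume: float  # continuum bead volume, not the discretized measure

    def __len__(self) -> int:
        return self.cell_indices.size


def _axis_distance(x: np.ndarray, c: float, L: float, periodic: bool) -> np.ndarray:
    d = x - c
    if periodic:
        d = (d + L / 2.0) % L - L / 2.0
    return d


def make_footprint(center, params: ModelParams) -> Footprint:
    """Cells whose centers lie strictly within ``l_b`` of ``center``.

    1D uses |x - xi| < l_b, 2D the Euclidean distance.  Raises
    :class:`DomainError` if the footprint is empty (the warning for
    l_b < dx/2 fires first, explaining why that can happen).
    """
    center = np.atleast_1d(np.asarray(center, dtype=float))
    if center.size != params.dim:
        raise DomainError(
            f"center has {center.size} coordinates for dim={params.dim}")
    if np.any(center < 0) or np.any(center > params.L):
        raise DomainError(f"center {center} outside [0, {params.L}]")
    if params.l_b < params.dx / 2:
        warnings.warn(
            "l_b < dx/2: footprint may be empty at this resolution",
            stacklevel=2)

    periodic = params.bc_field == "periodic"
    x = cell_centers(params)
    if params.dim == 1:
        d2 = _axis_distance(x, center[0], params.L, periodic) ** 2
    else:
        dx0 = _axis_distance(x, center[0], params.L, periodic)
        dx1 = _axis_distance(x, center[1], params.L, periodic)
        d2 = (dx0[:, None] ** 2 + dx1[None, :] ** 2).ravel()
    idx = np.flatnonzero(d2 < params.l_b**2)
    if idx.size == 0:
        raise DomainError(
            f"empty footprint at center={center}, l_b={params.l_b}, "
            f"dx={params.dx}")
    return Footprint(
        center=tuple(center),
        radius=params.l_b,
        cell_indices=idx,
        volume=bead_volume(params.l_b, params.dim),
    )
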
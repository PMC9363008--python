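"""Trajectory analytics and the in-vivo-style density/cell-length scan.

Estimators used throughout:

* mean speed — time average of |central-difference velocity| of the sampled
  positions, after discarding an initial transient (default 20%);
* position histogram — normalized to sum to one, with peaks detected by
  prominence;
* oscillation period — lag of the first prominent positive-lag peak of the
  position autocorrelation, reported only when that peak is pronounced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import DomainError
from .params import DimensionalParams, normalize
from .simulate import Trajectory, simulate

__all__ = [
    "TrajectoryMetrics",
    "analyze",
    "mean_speed",
    "InVivoScan",
    "invivo_scan",
]

#: directed motion must exceed this multiple of the rho = 0 noise floor
MOTION_THRESHOLD_FACTOR = 3.0
#: autocorrelation peak prominence required to report an oscillation
OSCILLATION_PROMINENCE = 0.05


@dataclass
class TrajectoryMetrics:
    mean_speed: float
    histogram: tuple[np.ndarray, np.ndarray]  # (bin_edges, normalized counts)
    modes: np.ndarray  # positions of detected histogram peaks, sorted
    oscillation_period: float | None
    transient_fraction: float
    mean_positions: np.ndarray  # time-averaged position per plasmid
    sem_positions: np.ndarray  # batch-means standard error per plasmid


def _drop_transient(traj: Trajectory, fraction: float):
    n = traj.times.size
    i0 = int(fraction * n)
    if n - i0 < 8:
        raise DomainError(
            f"trajectory too short after transient removal: {n} samples, "
            f"need at least {int(np.ceil(8 / (1 - fraction)))}")
    return traj.times[i0:], traj.positions[i0:]


def mean_speed(traj: Trajectory, transient_fraction: float = 0.2) -> float:
    """Time-averaged |v| from central differences of sampled positions."""
    t, pos = _drop_transient(traj, transient_fraction)
    pos2 = pos.reshape(t.size, -1)
    v = (pos2[2:] - pos2[:-2]) / (t[2:] - t[:-2])[:, None]
    if traj.params.dim == 2:
        v = v.reshape(t.size - 2, traj.params.M, 2)
        return float(np.mean(np.linalg.norm(v, axis=-1)))
    return float(np.mean(np.abs(v)))


def _autocorr_period(t: np.ndarray, x: np.ndarray) -> float | None:
    x = x - x.mean()
    if np.allclose(x, 0):
        return None
    nfft = 1 << int(np.ceil(np.log2(2 * x.size)))
    f = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(f * np.conj(f), nfft)[:x.size].real
    ac = ac / ac[0]
    peaks, props = find_peaks(ac, prominence=OSCILLATION_PROMINENCE)
    if peaks.size == 0:
        return None
    lag = peaks[np.argmax(props["prominences"])]
    return float(t[lag] - t[0])


def analyze(traj: Trajectory, transient_fraction: float = 0.2,
            bins: int = 50) -> TrajectoryMetrics:
    """Summary metrics of a (1D) trajectory."""
    t, pos = _drop_transient(traj, transient_fraction)
    L = traj.params.L
    flat = pos.reshape(-1)
    counts, edges = np.histogram(flat, bins=bins, range=(0.0, L))
    hist = counts / counts.sum()
    centers = 0.5 * (edges[1:] + edges[:-1])
    pk, _ = find_peaks(hist, prominence=0.25 * hist.max())
    if pk.size == 0:
        pk = np.array([int(np.argmax(hist))])
    modes = np.sort(centers[pk])

    period = _autocorr_period(t, pos.reshape(t.size, -1)[:, 0])

    pos2 = pos.reshape(t.size, -1)[:, :traj.params.M] \
        if traj.params.dim == 1 else pos[..., 0]
    # few long batches: block length must exceed the position correlation
    # time for the batch-means standard error to be honest
    nb = max(5, min(10, t.size // 20))
    batches = np.array_split(pos2, nb, axis=0)
    bm = np.array([b.mean(axis=0) for b in batches])
    sem = bm.std(axis=0, ddof=1) / np.sqrt(nb)

    return TrajectoryMetrics(
        mean_speed=mean_speed(traj, transient_fraction),
        histogram=(edges, hist),
        modes=modes,
        oscillation_period=period,
        transient_fraction=transient_fraction,
        mean_positions=pos2.mean(axis=0),
        sem_positions=sem,
    )


# ---------------------------------------------------------------------------
# in-vivo-style scan

@dataclass
class InVivoScan:
    """Mean speeds over a (rho, cell length) grid and detected onsets."""

    M: int
    rho_grid: np.ndarray
    length_grid: np.ndarray  # cell lengths in um
    speeds: np.ndarray  # (n_length, n_rho), averaged over reps
    floors: np.ndarray  # noise-floor speed per length (rho -> 0 row)
    rho_c: dict  # length -> first rho exceeding the motion threshold (or None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ell in enumerate(self.length_grid):
            for j, rho in enumerate(self.rho_grid):
                rows.append({"M": self.M, "cell_length_um": ell, "rho": rho,
                             "mean_speed": self.speeds[i, j],
                             "noise_floor": self.floors[i]})
        return pd.DataFrame(rows)

    def collapse_key(self) -> dict:
        """rho_c keyed by (cell length)/M; M = 1 and M = 2 scans overlay
        in this variable."""
        return {ell / self.M: rc for ell, rc in self.rho_c.items()}


def invivo_scan(dp_template: DimensionalParams, rho_grid, length_grid,
                M: int = 1, reps: int = 1, seed: int = 0,
                t_end: float = 150.0, dx: float = 0.05,
                sample_every: float = 0.25,
                transient_fraction: float = 0.2) -> InVivoScan:
    """Scan ParB surface density rho and cell length, Neumann walls.

    For each grid point the composite rates follow the density,
    chi = k*rho and eps = D*rho (since rho = N/(2 l_b)), and the mean cargo
    speed is averaged over ``reps`` seeded runs.  The onset density rho_c
    for each length is the first grid value whose speed exceeds
    ``MOTION_THRESHOLD_FACTOR`` times that length's rho = 0 noise floor.
    The central-difference speed estimator spans two sampling intervals,
    and that window must stay below the pole-to-pole half-period (about one
    normalized time unit) or the oscillation aliases away; hence the
    default sampling interval 0.25.
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    length_grid = np.asarray(length_grid, dtype=float)
    if np.any(np.diff(rho_grid) <= 0) or np.any(np.diff(length_grid) <= 0):
        raise DomainError("grids must be sorted ascending")
    if reps < 1:
        raise DomainError("reps must be >= 1")

    def run(ell_um, rho, rep):
        N = max(0, round(rho * 2 * dp_template.l_b))
        dp = DimensionalParams(
            k=dp_template.k, D_rel=dp_template.D_rel, N=N,
            l_b_phys=dp_template.l_b_phys, cell_length=ell_um,
            length_scale=dp_template.length_scale)
        mp = normalize(dp, dx=dx, M=M, bc_field="neumann",
                       seed=seed + 1000 * rep + hash((round(ell_um * 100),
                                                      round(rho))) % 9973)
        # rates follow the density exactly (avoid integer-N rounding)
        mp = mp.with_(chi=dp_template.k * rho, eps=dp_template.D_rel * rho,
                      noise_D=dp_template.D_rel)
        traj = simulate(mp, t_end, sample_every=sample_every)
        return mean_speed(traj, transient_fraction)

    speeds = np.zeros((length_grid.size, rho_grid.size))
    floors = np.zeros(length_grid.size)
    for i, ell in enumerate(length_grid):
        floors[i] = np.mean([run(ell, 0.0, rep) for rep in range(reps)])
        for j, rho in enumerate(rho_grid):
            if rho == 0.0:
                speeds[i, j] = floors[i]
                continue
            speeds[i, j] = np.mean([run(ell, rho, rep)
                                    for rep in range(reps)])

    rho_c: dict = {}
    for i, ell in enumerate(length_grid):
        above = speeds[i] > MOTION_THRESHOLD_FACTOR * floors[i]
        idx = np.flatnonzero(above)
        rho_c[float(ell)] = float(rho_grid[idx[0]]) if idx.size else None

    return InVivoScan(M=M, rho_grid=rho_grid, length_grid=length_grid,
                      speeds=speeds, floors=floors, rho_c=rho_c)
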
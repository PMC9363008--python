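"""Compiled inner loop for the 1D hybrid integrator.

The kernel repeats exactly the arithmetic of ``step_field`` /
``step_plasmids`` (an equivalence test pins the two together); thermal
noise is pre-drawn by the caller so that results are identical whether or
not the compiled path is available.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in
    HAVE_NUMBA = False  # practice, but the numpy loop remains functional

    def njit(*a, **k):
        def deco(f):
            return f
        return deco(a[0]) if a and callable(a[0]) else deco


@njit(cache=True)
def run_1d(u, pos, noise, n_steps, stride, dt, dx, chi, K_d, m, eps, l_b, L,
           periodic, out_pos):
    """Integrate ``n_steps`` steps, sampling positions every ``stride``.

    Returns -1 on success, else the step index at which the field went
    negative (reaction overshoot: dt too large) or a footprint cell hit
    u <= 0 (singular force).
    """
    n = u.shape[0]
    M = pos.shape[0]
    inv2dx = 1.0 / (2.0 * dx)
    invdx2 = 1.0 / (dx * dx)
    meas = dx
    hill = np.empty(n)
    lap = np.empty(n)
    grad = np.empty(n)
    sink = np.empty(n)
    forces = np.empty(M)
    sample = 0
    for s in range(n_steps + 1):
        if s % stride == 0:
            for i in range(M):
                out_pos[sample, i] = pos[i]
            sample += 1
        if s == n_steps:
            break

        for j in range(n):
            if m == 1:
                hill[j] = u[j] / (K_d + u[j])
            else:
                um = u[j] ** m
                hill[j] = um / (K_d**m + um)
            sink[j] = 0.0
        if periodic:
            for j in range(n):
                jp = j + 1 if j + 1 < n else 0
                jm = j - 1 if j - 1 >= 0 else n - 1
                lap[j] = (u[jp] - 2.0 * u[j] + u[jm]) * invdx2
                grad[j] = (u[jp] - u[jm]) * inv2dx
        else:
            for j in range(1, n - 1):
                lap[j] = (u[j + 1] - 2.0 * u[j] + u[j - 1]) * invdx2
                grad[j] = (u[j + 1] - u[j - 1]) * inv2dx
            lap[0] = (u[1] - u[0]) * invdx2
            lap[n - 1] = (u[n - 2] - u[n - 1]) * invdx2
            grad[0] = (u[1] - u[0]) / dx
            grad[n - 1] = (u[n - 1] - u[n - 2]) / dx

        for i in range(M):
            xi = pos[i]
            jlo = int(np.floor((xi - l_b) / dx - 0.5)) + 1
            jhi = int(np.ceil((xi + l_b) / dx - 0.5)) - 1
            if not periodic:
                jlo = max(jlo, 0)
                jhi = min(jhi, n - 1)
            f = 0.0
            for j in range(jlo, jhi + 1):
                idx = j % n
                if u[idx] <= 0.0:
                    return s
                sink[idx] += 1.0
                f += hill[idx] * grad[idx] / u[idx]
            forces[i] = eps * f * meas

        neg = False
        for j in range(n):
            u[j] = u[j] + dt * (lap[j] + (1.0 - u[j])
                                - chi * hill[j] * sink[j])
            if u[j] < 0.0:
                neg = True
        if neg:
            return s

        for i in range(M):
            x = pos[i] + dt * forces[i] + noise[s, i]
            if periodic:
                x = x % L
            else:
                if x < 0.0:
                    x = -x
                if x > L:
                    x = 2.0 * L - x
                if x < 0.0:
                    x = 0.0
                elif x > L:
                    x = L
            pos[i] = x
    return -1
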
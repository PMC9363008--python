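"""Figure-reproduction recipes: documented parameter sets and pipelines.

Each recipe runs the corresponding computation at the requested scale,
writes its data tables (TSV), a plot (PNG) and a JSON manifest of the
parameters and seeds used.  ``scale="desk"`` uses reduced sampling/grids
suitable for a laptop run; ``scale="full"`` approaches publication-quality
statistics.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import stability, wave
from .metrics import analyze, invivo_scan
from .params import DimensionalParams, ModelParams
from .simulate import simulate

__all__ = ["reproduce", "RECIPES"]

_FIG2_GEOM = dict(l_b=0.2, L=40.0, eps=5.0)


def _fig1_like(outdir, seed, scale, M=1):
    t_end = 4000.0 if scale == "full" else 800.0
    rows = {}
    for chi in (0.5, 2.5, 10.0):
        p = ModelParams(chi=chi, eps=5.0, K_d=0.1, l_b=0.2, M=M, L=5.0,
                        dx=0.1, noise_D=0.05, bc_field="neumann", seed=seed)
        traj = simulate(p, t_end, sample_every=0.25)
        met = analyze(traj)
        edges, hist = met.histogram
        rows[chi] = (edges, hist, met)
        traj.to_tsv(outdir / f"trajectory_chi{chi}.tsv")
    fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharey=True)
    for ax, (chi, (edges, hist, met)) in zip(axes, rows.items()):
        ax.stairs(hist, edges)
        ax.set_title(f"chi = {chi}")
        ax.set_xlabel("position")
    axes[0].set_ylabel("probability")
    return {"t_end": t_end, "M": M,
            "modes": {str(chi): rows[chi][2].modes.tolist() for chi in rows}}


def _fig2a(outdir, seed, scale):
    n = 50 if scale == "full" else 15
    chis = np.linspace(0.2, 10, n)
    epss = np.linspace(0.2, 10, n)
    vmap = np.zeros((n, n))
    for i, e in enumerate(epss):
        geom = wave.WaveGeometry(l_b=0.2, L=40.0, eps=e)
        for j, c in enumerate(chis):
            roots = wave.find_velocities(c, geom, n_scan=150)
            vmap[i, j] = roots.max()
    np.savetxt(outdir / "speed_map.tsv", vmap, delimiter="\t")
    plt.pcolormesh(chis, epss, vmap, shading="auto")
    plt.xlabel("chi"); plt.ylabel("eps"); plt.colorbar(label="|v|")
    return {"chi_grid": [chis[0], chis[-1], n],
            "eps_grid": [epss[0], epss[-1], n]}


def _fig2b(outdir, seed, scale):
    geom = wave.WaveGeometry(**_FIG2_GEOM)
    chis = np.linspace(0.2, 10, 80 if scale == "full" else 40)
    branch = wave.scan_branch("chi", chis, eps=geom.eps, l_b=geom.l_b,
                              L=geom.L)
    chi_c = wave.critical_chi(geom)
    tab = np.column_stack([chis, np.zeros_like(chis),
                           np.nan_to_num(branch.v_surfing),
                           -np.nan_to_num(branch.v_surfing)])
    np.savetxt(outdir / "branches.tsv", tab, delimiter="\t",
               header="chi\tv_localized\tv_plus\tv_minus", comments="")
    plt.plot(chis, branch.v_surfing, "g-", label="surfing |v|")
    plt.plot(chis, np.zeros_like(chis), "m-", label="localized")
    plt.axvline(chi_c, ls=":", c="k")
    plt.xlabel("chi"); plt.ylabel("v"); plt.legend()
    return {"chi_c": chi_c}


def _fig2c(outdir, seed, scale):
    geom = wave.WaveGeometry(**_FIG2_GEOM)
    z = np.linspace(-geom.L / 2, geom.L / 2, 2001)
    loc = wave.solve_profile(0.0, 2.5, geom)
    vstar = wave.find_velocities(10.0, geom).max()
    surf = wave.solve_profile(vstar, 10.0, geom)
    np.savetxt(outdir / "profiles.tsv",
               np.column_stack([z, loc(z), surf(z)]), delimiter="\t",
               header="z\tU_localized_chi2.5\tU_surfing_chi10", comments="")
    plt.plot(z / geom.L, loc(z), "m-", label="chi=2.5, v=0")
    plt.plot(z / geom.L, surf(z), "g-", label=f"chi=10, v={vstar:.2f}")
    plt.xlabel("z/L"); plt.ylabel("U^st"); plt.legend()
    return {"v_surfing": vstar, "U0_localized": loc.U0}


def _fig2d(outdir, seed, scale):
    lbs = np.linspace(0.05, 1.9, 40 if scale == "full" else 24)
    res = {}
    for N in (10, 20, 30, 40, 50):
        br = wave.scan_branch("l_b", lbs, N=N, k=0.1, D_rel=0.05, L=40.0)
        res[N] = br
        plt.plot(lbs, br.v_surfing, label=f"N={N}")
    tab = np.column_stack([lbs] + [np.nan_to_num(res[N].v_surfing)
                                   for N in res])
    np.savetxt(outdir / "lb_scan.tsv", tab, delimiter="\t",
               header="l_b\t" + "\t".join(f"v_N{N}" for N in res),
               comments="")
    plt.xlabel("l_b"); plt.ylabel("|v|"); plt.legend()
    return {"critical_l_b": {str(N): res[N].critical_value for N in res}}


def _s3(outdir, seed, scale):
    # start from the analytic steady profile: the uniform start's deep
    # depletion transient is reaction-stiff at K_d = 0.001
    out = {}
    geom = wave.WaveGeometry(**_FIG2_GEOM)
    for chi in (2.5, 10.0):
        p = ModelParams(chi=chi, eps=5.0, K_d=0.001, l_b=0.2, M=1, L=40.0,
                        dx=0.1, noise_D=0.0, bc_field="periodic", seed=seed)
        roots = wave.find_velocities(chi, geom)
        sw = wave.solve_profile(float(roots.max()), chi, geom)
        x = (np.arange(p.n_cells) + 0.5) * p.dx
        traj = simulate(p, 60.0, sample_every=1.0, snapshot_stride=10,
                        u0=sw(x - 20.0), xi0=[20.0])
        traj.to_tsv(outdir / f"trajectory_chi{chi}.tsv")
        for t, u in traj.snapshots[-3:]:
            plt.plot(np.arange(u.size) * p.dx, u,
                     label=f"chi={chi}, t={t:.0f}")
        out[str(chi)] = {"final_position": float(traj.positions[-1, 0])}
    plt.xlabel("x"); plt.ylabel("u"); plt.legend(fontsize=6)
    return out


def _s4(outdir, seed, scale):
    geom = wave.WaveGeometry(**_FIG2_GEOM)
    vs = np.linspace(-6, 6, 601)
    cols = [vs]
    for chi in (2.0, 3.1, 5.0, 10.0):
        row = []
        for v in vs:
            try:
                row.append(wave.residual(v, chi, geom))
            except Exception:
                row.append(np.nan)
        cols.append(np.array(row))
        plt.plot(vs, cols[-1], label=f"chi={chi}")
    plt.axhline(0, c="k", lw=0.5)
    plt.xlabel("v"); plt.ylabel("eps*dmu - v"); plt.legend()
    np.savetxt(outdir / "residual_curves.tsv", np.column_stack(cols),
               delimiter="\t", header="v\tchi2\tchi3.1\tchi5\tchi10",
               comments="")
    zero_crossings = {}
    for chi, col in zip((2.0, 3.1, 5.0, 10.0), cols[1:]):
        vals = col[np.isfinite(col)]
        s = np.sign(vals[vals != 0])
        zero_crossings[str(chi)] = int(np.sum(s[:-1] * s[1:] < 0))
    return {"zero_crossings": zero_crossings}


def _s5(outdir, seed, scale):
    geom = wave.WaveGeometry(**_FIG2_GEOM)
    chis = np.linspace(3.3, 6.0, 16 if scale == "full" else 8)
    lead = []
    for chi in chis:
        try:
            lead.append(stability.destabilizing_eigenvalue(chi, geom))
        except Exception:
            lead.append(np.nan)
    np.savetxt(outdir / "leading_eigenvalue.tsv",
               np.column_stack([chis, lead]), delimiter="\t",
               header="chi\tRe_lambda_localized", comments="")
    plt.semilogy(chis, lead, "r.-")
    plt.xlabel("chi"); plt.ylabel("Re lambda (localized)")
    return {"restabilization_chi": stability.restabilization_chi(geom),
            "unphysical_onset": stability.unphysical_onset(geom)}


def _s6(outdir, seed, scale):
    ks = np.linspace(0.0, 0.1, 200)
    v = [wave.limit_velocity(k, 0.05, 40).max() for k in ks]
    np.savetxt(outdir / "limit_branch.tsv", np.column_stack([ks, v]),
               delimiter="\t", header="k\tv_plus", comments="")
    plt.plot(ks, v); plt.xlabel("k"); plt.ylabel("|v|")
    return {"k_c": wave.critical_k_limit(40, 0.05)}


def _s7(outdir, seed, scale):
    dp = DimensionalParams()
    rho = [0., 60., 100., 140.] if scale == "desk" else \
        [0., 40., 60., 80., 100., 120., 140., 160.]
    out = {}
    for M, lengths in ((1, (0.6, 0.8, 2.0)), (2, (1.2, 1.6, 4.0))):
        scan = invivo_scan(dp, rho, list(lengths), M=M, seed=seed,
                           t_end=120.0 if scale == "desk" else 400.0)
        scan.to_frame().to_csv(outdir / f"invivo_M{M}.tsv", sep="\t",
                               index=False)
        for i, ell in enumerate(scan.length_grid):
            plt.plot(scan.rho_grid, scan.speeds[i],
                     label=f"M={M}, {ell} um")
        out[f"M{M}"] = {str(k): v for k, v in scan.rho_c.items()}
    plt.xlabel("rho"); plt.ylabel("mean |v|"); plt.legend(fontsize=6)
    return out


def _s8(outdir, seed, scale):
    # 2D periodic box; K_d raised to 0.01 so that the explicit scheme's
    # reaction-limited time step stays affordable (see docs/methods.md)
    out = {}
    for chi in (10.0, 50.0):
        p = ModelParams(chi=chi, eps=5.0, K_d=0.01, l_b=0.2, M=1, L=10.0,
                        dim=2, dx=0.1, dt=2e-4, noise_D=0.0,
                        bc_field="periodic", seed=seed)
        traj = simulate(p, 15.0 if scale == "desk" else 60.0,
                        sample_every=0.5, snapshot_stride=10,
                        u_perturb=0.01, xi0=[[5.0, 5.0]])
        disp = np.linalg.norm(traj.positions[-1] - traj.positions[0])
        out[str(chi)] = {"net_displacement": float(disp)}
        t, u = traj.snapshots[-1]
        plt.figure()
        plt.imshow(u.T, origin="lower", extent=(0, 10, 0, 10))
        plt.plot(*traj.positions[-1, 0], "ro")
        plt.title(f"chi={chi}, t={t:.0f}")
        plt.savefig(outdir / f"field2d_chi{chi}.png", dpi=100)
    return out


RECIPES = {
    "fig1": _fig1_like,
    "fig2a": _fig2a,
    "fig2b": _fig2b,
    "fig2c": _fig2c,
    "fig2d": _fig2d,
    "s1": lambda o, s, sc: _fig1_like(o, s, sc, M=2),
    "s2": lambda o, s, sc: _fig1_like(o, s, sc, M=3),
    "s3": _s3,
    "s4": _s4,
    "s5": _s5,
    "s6": _s6,
    "s7": _s7,
    "s8": _s8,
}


def reproduce(figure_id: str, scale: str = "desk",
              outdir: str | Path = "artifacts", seed: int = 0) -> dict:
    """Run one documented recipe; returns (and writes) its manifest."""
    if figure_id not in RECIPES:
        raise ValueError(
            f"unknown figure id {figure_id!r}; choose from {sorted(RECIPES)}")
    if scale not in ("desk", "full"):
        raise ValueError("scale must be 'desk' or 'full'")
    outdir = Path(outdir) / figure_id
    outdir.mkdir(parents=True, exist_ok=True)
    plt.figure()
    summary = RECIPES[figure_id](outdir, seed, scale)
    plt.savefig(outdir / f"{figure_id}.png", dpi=120)
    plt.close("all")
    manifest = {"figure": figure_id, "scale": scale, "seed": seed,
                "summary": summary}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
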
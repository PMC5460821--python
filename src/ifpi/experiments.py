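"""Canonical reproduction experiments.

These functions pin down the study conditions used by the acceptance
script and the acceptance tests: the single-inclusion cube phantom at a
stated mesh resolution, the noise model, and the scaled-down inversion
settings (zone size, polynomial degree, pass counts) chosen for the
package's reproduction runs.  Everything is deterministic given the seed.
"""
from __future__ import annotations

import numpy as np

from .phantom import PhantomConfig
from .gfp import run_forward
from .pbc import fit_polynomials, peak_slice_laplacian
from .inversion import IFPIConfig, run_ifpi


def derivative_magnitude_experiment(nodes_per_axis: int = 21,
                                    degree: int = 10) -> dict:
    """Forward-solve the noiseless two-parameter phantom, fit the
    displacement polynomials, and evaluate the peak |div grad u| of the
    real x-displacement over the x-z slice at y = 4.2 cm (the scale check
    of the second-derivative estimation)."""
    cfg = PhantomConfig.two_parameter(nodes_per_axis=nodes_per_axis)
    mesh = cfg.build_mesh("ifpi")
    mesh_g = cfg.build_mesh("gfp")
    theta = cfg.build_properties(mesh_g)
    u, p = run_forward(mesh_g, theta, cfg.build_bcs(mesh_g, "gfp"))
    model = fit_polynomials(u, mesh, degree)
    peak = peak_slice_laplacian(mesh, model, axis=1, coordinate=0.042,
                                component=0, part=np.real)
    return {"peak_laplacian": peak, "n": nodes_per_axis, "u": u, "p": p,
            "mesh": mesh, "mesh_gfp": mesh_g, "theta": theta, "model": model}


def reconstruction_run(mode: str, noise_percent: float, seed: int,
                       nodes_per_axis: int = 13, degree: int = 8,
                       zone_edge: float = 0.04, overlap: float = 1 / 3,
                       max_global: int = 8, n_inner: int = 2,
                       averaged: bool = False) -> dict:
    """One scaled-down IFPI reconstruction cell; returns the normalized RMS
    errors of the recovered fields."""
    if mode == "two":
        ph = PhantomConfig.two_parameter(
            nodes_per_axis=nodes_per_axis, noise_percent=noise_percent,
            noise_seed=seed, spatially_averaged=averaged)
    else:
        ph = PhantomConfig.three_parameter(
            nodes_per_axis=nodes_per_axis, noise_percent=noise_percent,
            noise_seed=seed, spatially_averaged=averaged)
    cfg = IFPIConfig(phantom=ph, mode=mode, max_global=max_global,
                     n_inner=n_inner, degree=degree, zone_edge=zone_edge,
                     overlap_fraction=overlap, tol=1e-3)
    res = run_ifpi(cfg)
    last = res.diagnostics.iloc[-1]
    return {"d_mu": float(last["d_mu"]), "d_lam": float(last["d_lam"]),
            "d_kappa": float(last["d_kappa"]), "d_p": float(last["d_p"]),
            "iterations": int(last["iteration"]) + 1,
            "converged": bool(res.converged), "n": nodes_per_axis,
            "result": res}
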
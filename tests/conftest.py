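"""Shared fixtures: small phantoms and forward solutions reused across
modules (session-scoped, built once)."""
import numpy as np
import pytest

from ifpi.phantom import PhantomConfig
from ifpi.gfp import run_forward, compute_beta


@pytest.fixture(scope="session")
def small_homogeneous():
    """Homogeneous 9^3 phantom with its coupled forward solution."""
    cfg = PhantomConfig.two_parameter(nodes_per_axis=9, inclusion_box=None)
    mesh = cfg.build_mesh("gfp")
    theta = cfg.build_properties(mesh)
    bcs = cfg.build_bcs(mesh, "gfp")
    u, p = run_forward(mesh, theta, bcs)
    return {"cfg": cfg, "mesh": mesh, "theta": theta, "bcs": bcs,
            "u": u, "p": p, "beta": compute_beta(cfg.globals, theta.kappa)}


@pytest.fixture(scope="session")
def small_inclusion():
    """Two-parameter single-inclusion phantom at 13^3 with forward fields
    on both boundary-tag layouts."""
    cfg = PhantomConfig.two_parameter(nodes_per_axis=13)
    mesh_g = cfg.build_mesh("gfp")
    mesh_i = cfg.build_mesh("ifpi")
    theta = cfg.build_properties(mesh_g)
    u, p = run_forward(mesh_g, theta, cfg.build_bcs(mesh_g, "gfp"))
    return {"cfg": cfg, "mesh": mesh_g, "mesh_ifpi": mesh_i, "theta": theta,
            "u": u, "p": p, "beta": compute_beta(cfg.globals, theta.kappa)}
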
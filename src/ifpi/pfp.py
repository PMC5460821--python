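"""Pressure forward problem (PFP).

Reduced scalar solve for the pore pressure given displacement data, the
coupling coefficient beta, one (or more) type-I pressure anchors, and
pre-assembled type-II flux loads on Gamma_q.  The linear system has one
unknown per node -- one fourth the size of the coupled problem -- with

    Kp(k,j) = (i/(rho_f omega)) <grad phi_k, beta grad phi_j>
    bp(k)   = -i omega <div u, phi_k> - i omega <beta u, grad phi_k>
              + (assembled r0 loads)_k.

Only the pressure gradient enters the physics, so shifting the anchor value
shifts the whole field by the same constant.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .fem import Mesh, basis_for, assemble_blocks, ConstrainedSolver, \
    nested_dissection_order
from .phantom import GlobalParams


@dataclass
class PressureSystem:
    Kp: sp.csr_matrix
    bp: np.ndarray
    mesh: Mesh


def _pressure_stiffness(mesh: Mesh, beta: np.ndarray,
                        globals_: GlobalParams, chunk: int = 4000):
    basis = basis_for(mesh.h)
    parts = []
    E = mesh.n_elements
    for s in range(0, E, chunk):
        conn = mesh.elements[s:s + chunk]
        beta_e = beta[conn]
        blocks = (1j / (globals_.rho_f * globals_.omega)) * \
            np.einsum("em,mkj->ekj", beta_e, basis.Sdiag)
        parts.append(assemble_blocks(conn, blocks, mesh.n_nodes))
    Kp = parts[0]
    for P in parts[1:]:
        Kp = Kp + P
    return Kp


def _displacement_source(mesh: Mesh, u: np.ndarray, beta: np.ndarray,
                         globals_: GlobalParams) -> np.ndarray:
    """-i omega <div u, phi_k> - i omega <beta u, grad phi_k> for nodal u."""
    basis = basis_for(mesh.h)
    w = globals_.omega
    conn = mesh.elements
    ue = np.asarray(u, dtype=complex)[conn]              # (E, 8, 3)
    beta_e = beta[conn]
    t1 = np.einsum("kji,eji->ek", basis.D2, ue)          # <div u, phi_k>
    t2 = np.einsum("mjki,em,eji->ek", basis.D3, beta_e, ue)  # <beta u, grad phi_k>
    out = np.zeros(mesh.n_nodes, dtype=complex)
    np.add.at(out, conn.ravel(), (-1j * w * (t1 + t2)).ravel())
    return out


def assemble_pfp(mesh: Mesh, u: np.ndarray, beta: np.ndarray,
                 r0_loads: np.ndarray | None,
                 globals_: GlobalParams) -> PressureSystem:
    """Assemble the reduced pressure system driven by the volumetric
    deformation of the solid; ``r0_loads`` are pre-assembled nodal values of
    the Gamma_q surface integral (zero elsewhere)."""
    if np.asarray(u).shape[0] != mesh.n_nodes:
        raise ValueError("displacement field does not match the mesh")
    Kp = _pressure_stiffness(mesh, beta, globals_)
    bp = _displacement_source(mesh, u, beta, globals_)
    if r0_loads is not None:
        bp = bp + np.asarray(r0_loads, dtype=complex)
    return PressureSystem(Kp=Kp, bp=bp, mesh=mesh)


def solve_pfp(system: PressureSystem, anchor_nodes, anchor_values) -> np.ndarray:
    """Solve for the nodal pressure with the anchor values exact."""
    anchor_nodes = np.atleast_1d(np.asarray(anchor_nodes, dtype=np.int64))
    anchor_values = np.atleast_1d(np.asarray(anchor_values, dtype=complex))
    key = nested_dissection_order(system.mesh.shape)
    solver = ConstrainedSolver(system.Kp, anchor_nodes, order_key=key)
    return solver.solve(system.bp, anchor_values)


def project_compatibility(system: PressureSystem, gamma_q_nodes: np.ndarray,
                          weights: np.ndarray | None = None) -> PressureSystem:
    """Distribute the global compatibility defect of the load vector over the
    Gamma_q nodes.

    With a single point anchor the discrete Neumann problem requires the
    total right-hand side to vanish (the columns of Kp sum to zero); any
    defect left by estimated loads would otherwise concentrate at the anchor
    like a point source.  The defect is removed with weights proportional to
    each node's share of the flux-boundary area (int phi_k over Gamma_q)
    unless explicit weights are given."""
    mesh = system.mesh
    if weights is None:
        from .fem import facet_load_vector, basis_for as _bf
        basis = _bf(mesh.h)
        weights = facet_load_vector(mesh, basis,
                                    mesh.facet_pres_tag == "flux",
                                    np.ones(mesh.n_nodes)).real
    w = np.zeros(mesh.n_nodes)
    w[gamma_q_nodes] = weights[gamma_q_nodes]
    if w.sum() == 0:                      # no flux-tagged facets: uniform
        w[gamma_q_nodes] = 1.0
    w /= w.sum()
    defect = system.bp.sum()
    return PressureSystem(Kp=system.Kp, bp=system.bp - defect * w,
                          mesh=mesh)


def solve_pressure_from_model(mesh: Mesh, model, theta, u_data=None,
                              anchor_nodes=None, anchor_values=None,
                              pull_elements: float = 1.0,
                              calibration_modes: int = 2) -> np.ndarray:
    """Global pressure estimate from a fitted displacement model.

    The reduced system is driven by the substituted form of the estimated
    type-II loads (every right-hand-side term a volume integral of the
    polynomial-reconstructed fields against test-function gradients, which
    is exactly compatible for the point-anchored solve and fully smoothed
    against data noise; see :func:`ifpi.pbc.momentum_source`).

    Because that right-hand side scales with the current property estimate
    (the elastic operator enters it linearly), the raw solution would carry
    any overall bias of mu, lambda into the pressure.  When the measured
    nodal displacements ``u_data`` are supplied, a single complex scale
    factor is therefore calibrated against the data-driven mass-balance
    rows (whose coefficients involve only the known beta), tested on the
    smooth low sine modes of the box: this re-anchors the absolute pressure
    scale to the data and removes the property-scale feedback from the
    outer inversion loop.
    """
    from .pbc import momentum_source
    from .gfp import compute_beta as _cb
    beta = _cb(theta.globals, theta.kappa)
    Kp = _pressure_stiffness(mesh, beta, theta.globals)
    if anchor_nodes is None:
        anchor_nodes = np.array([mesh.node_index(0, 0, 0)])
        anchor_values = np.zeros(1, dtype=complex)
    bp = momentum_source(mesh, model, theta, pull_elements=pull_elements)
    system = PressureSystem(Kp=Kp, bp=bp, mesh=mesh)
    p = solve_pfp(system, anchor_nodes, anchor_values)
    if u_data is None:
        return p
    b_data = _displacement_source(mesh, u_data, beta, theta.globals)
    L = mesh.edge_length
    x, y, z = mesh.coords.T
    Kp_p = Kp @ p
    num = 0.0 + 0j
    den = 0.0 + 0j
    for kx in range(1, calibration_modes + 1):
        for ky in range(1, calibration_modes + 1):
            for kz in range(1, calibration_modes + 1):
                w = (np.sin(kx * np.pi * x / L) * np.sin(ky * np.pi * y / L)
                     * np.sin(kz * np.pi * z / L))
                yw = w @ Kp_p
                num += np.conj(yw) * (w @ b_data)
                den += np.conj(yw) * yw
    c = num / den
    return c * p


def exact_r0_loads(mesh: Mesh, u: np.ndarray, p: np.ndarray,
                   beta: np.ndarray, globals_: GlobalParams) -> np.ndarray:
    """Exact discrete flux loads of a known (u, p) pair:

        L_k = (i/(rho_f omega)) <beta grad p, grad phi_k>
              + i omega <beta u, grad phi_k> + i omega <div u, phi_k>,

    which equals the surface integral of r0 phi_k on Gamma_q for the
    converged coupled solution (and vanishes at interior nodes).  Used as
    the oracle for the estimated loads and for the global flux balance."""
    Kp = _pressure_stiffness(mesh, beta, globals_)
    return Kp @ np.asarray(p, dtype=complex) \
        - _displacement_source(mesh, u, beta, globals_)
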
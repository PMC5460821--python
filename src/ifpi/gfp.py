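"""Global poroelastic forward problem (GFP).

Assembles and solves the coupled frequency-domain Biot system for the
time-harmonic displacement u and pore pressure p, with 4 complex unknowns
per node (u, v, w, p).  The momentum equation is

    div(mu grad u) + grad((lam + mu) div u) - (1 - beta) grad p
        = -omega^2 (rho - beta rho_f) u,

and the pressure equation is the compact mass-balance form
i omega div u = div q with the Darcy-type flux

    q = i omega beta u + (i beta / (rho_f omega)) grad p,

whose weak statement reads, for every pressure test function psi,

    (i/(rho_f omega)) <beta grad p, grad psi> + i omega <beta u, grad psi>
        + i omega <div u, psi> = surface integral of r0 psi over Gamma_q.

(The two printed forms of the displacement source term in the literature
differ by an overall sign; this pairing is the one under which the flux
balance and the reduced pressure problem are exactly self-consistent, which
the test suite verifies.)
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .fem import (Mesh, HexBasis, basis_for, assemble_blocks,
                  facet_load_vector, ConstrainedSolver,
                  nested_dissection_order, node_order_to_dof_key)
from .phantom import GlobalParams, PropertyMap, BoundaryConditionSet


def compute_beta(globals_: GlobalParams, kappa: np.ndarray) -> np.ndarray:
    """Complex coupling coefficient

    beta = omega phi^2 rho_f kappa / (i phi^2 + omega kappa (rho_a + phi rho_f))

    evaluated nodewise; beta -> 0 as kappa -> 0 or phi -> 0."""
    w = globals_.omega
    phi = globals_.phi
    kappa = np.asarray(kappa, dtype=float)
    num = w * phi ** 2 * globals_.rho_f * kappa
    den = 1j * phi ** 2 + w * kappa * (globals_.rho_a + phi * globals_.rho_f)
    if np.any(den == 0):
        raise ZeroDivisionError("degenerate parameters: beta denominator is zero")
    return num / den


def dbeta_dkappa(globals_: GlobalParams, kappa: np.ndarray) -> np.ndarray:
    """Analytic derivative of beta with respect to kappa (used by the
    inversion chain rule)."""
    w = globals_.omega
    phi = globals_.phi
    a = w * phi ** 2 * globals_.rho_f
    c = w * (globals_.rho_a + phi * globals_.rho_f)
    d0 = 1j * phi ** 2
    return a * d0 / (d0 + c * np.asarray(kappa, dtype=float)) ** 2


@dataclass
class CoupledSystem:
    K: sp.csr_matrix
    b: np.ndarray
    mesh: Mesh
    basis: HexBasis


def _dof(nodes, comp):
    return 4 * np.asarray(nodes) + comp


def assemble_coupled(conn: np.ndarray, n_nodes: int, basis: HexBasis,
                     mu: np.ndarray, lam: np.ndarray, beta: np.ndarray,
                     globals_: GlobalParams, chunk: int = 2000) -> sp.csr_matrix:
    """Assemble the coupled 4-dof/node matrix for arbitrary connectivity
    (global mesh or a subzone), with nodal mu, lam and beta interpolated by
    the same trilinear basis as the unknowns."""
    w = globals_.omega
    rho, rho_f = globals_.rho, globals_.rho_f
    n_dofs = 4 * n_nodes
    parts = []
    E = conn.shape[0]
    for s in range(0, E, chunk):
        c = conn[s:s + chunk]
        ne = c.shape[0]
        mu_e = mu[c]
        lamu_e = (lam + mu)[c]
        beta_e = beta[c]
        rb_e = rho - beta_e * rho_f
        omb_e = 1.0 - beta_e
        L = np.zeros((ne, 32, 32), dtype=complex)
        A_mu = np.einsum("em,mkj->ekj", mu_e, basis.Sdiag)
        A_div = np.einsum("em,mkjab->ekjab", lamu_e, basis.S)
        A_mass = np.einsum("em,mkj->ekj", rb_e, basis.M3)
        A_up = np.einsum("em,mkja->ekja", omb_e, basis.D3)
        A_pu2 = np.einsum("em,mjki->ekji", beta_e, basis.D3)
        A_pp = (1j / (rho_f * w)) * np.einsum("em,mkj->ekj", beta_e, basis.Sdiag)
        for i in range(3):
            L[:, i::4, i::4] += A_mu - w ** 2 * A_mass
            for ip in range(3):
                L[:, i::4, ip::4] += A_div[..., i, ip]
            L[:, i::4, 3::4] += A_up[..., i]
            L[:, 3::4, i::4] += 1j * w * (basis.D2[None, :, :, i]
                                          + A_pu2[..., i])
        L[:, 3::4, 3::4] += A_pp
        dofs = (4 * c[:, :, None] + np.arange(4)[None, None, :]).reshape(ne, 32)
        parts.append(assemble_blocks(dofs, L, n_dofs))
    K = parts[0]
    for P in parts[1:]:
        K = K + P
    return K


def assemble_gfp(mesh: Mesh, theta: PropertyMap,
                 bcs: BoundaryConditionSet) -> CoupledSystem:
    """Assemble the coupled system with natural boundary terms (tractions f0
    on Gamma_sigma and pre-assembled r0 flux loads on Gamma_q) in b; type-I
    values are eliminated at solve time."""
    basis = basis_for(mesh.h)
    beta = compute_beta(theta.globals, theta.kappa)
    K = assemble_coupled(mesh.elements, mesh.n_nodes, basis,
                         theta.mu, theta.lam, beta, theta.globals)
    b = np.zeros(4 * mesh.n_nodes, dtype=complex)
    if bcs.traction is not None:
        mask = mesh.facet_disp_tag == "traction"
        for i in range(3):
            b[i::4] += facet_load_vector(mesh, basis, mask, bcs.traction[:, i])
    if bcs.r0_loads is not None:
        b[3::4] += bcs.r0_loads
    return CoupledSystem(K=K, b=b, mesh=mesh, basis=basis)


def _constraints(bcs: BoundaryConditionSet):
    idx, vals = [], []
    for c in range(3):
        m = bcs.disp_mask[:, c]
        idx.append(_dof(bcs.disp_nodes[m], c))
        vals.append(bcs.disp_values[m, c])
    idx.append(_dof(bcs.pres_nodes, 3))
    vals.append(bcs.pres_values)
    return np.concatenate(idx), np.concatenate(vals).astype(complex)


def solve_gfp(system: CoupledSystem, bcs: BoundaryConditionSet):
    """Solve the coupled system; returns (u, p) with u of shape (N, 3)."""
    idx, vals = _constraints(bcs)
    key = node_order_to_dof_key(nested_dissection_order(system.mesh.shape), 4)
    solver = ConstrainedSolver(system.K, idx, order_key=key)
    x = solver.solve(system.b, vals)
    u = np.stack([x[0::4], x[1::4], x[2::4]], axis=1)
    return u, x[3::4]


def run_forward(mesh: Mesh, theta: PropertyMap, bcs: BoundaryConditionSet):
    return solve_gfp(assemble_gfp(mesh, theta, bcs), bcs)


# ---------------------------------------------------------------------------
# Derived quantities at quadrature points
# ---------------------------------------------------------------------------

def _qp_fields(mesh: Mesh, basis: HexBasis, nodal: np.ndarray, elems=None):
    """Values and gradients of a nodal field at every quadrature point.
    Returns value (E, 8gp, ...) and gradient (E, 8gp, ..., 3)."""
    conn = mesh.elements if elems is None else mesh.elements[elems]
    v = nodal[conn]                                     # (E, 8, ...)
    val = np.einsum("gj,ej...->eg...", basis.N, v)
    grad = np.einsum("gja,ej...->eg...a", basis.dNdx, v)
    return val, grad


@dataclass
class StressStrain:
    strain: np.ndarray   # (E, 8gp, 3, 3) complex
    stress: np.ndarray   # (E, 8gp, 3, 3) complex, Cauchy sigma_E


def compute_stress_strain(mesh: Mesh, u: np.ndarray,
                          theta: PropertyMap) -> StressStrain:
    """Small strain eps = (grad u + grad u^T)/2 and the isotropic Cauchy
    stress sigma_E = lam tr(eps) I + 2 mu eps, per quadrature point."""
    basis = basis_for(mesh.h)
    _, gu = _qp_fields(mesh, basis, np.asarray(u, dtype=complex))  # (E,g,3,3)
    eps = 0.5 * (gu + np.swapaxes(gu, -1, -2))
    mu_q, _ = _qp_fields(mesh, basis, theta.mu)
    lam_q, _ = _qp_fields(mesh, basis, theta.lam)
    tr = np.einsum("egaa->eg", eps)
    I = np.eye(3)
    sigma = lam_q[..., None, None] * tr[..., None, None] * I + \
        2.0 * mu_q[..., None, None] * eps
    return StressStrain(strain=eps, stress=sigma)


def compute_flux(mesh: Mesh, u: np.ndarray, p: np.ndarray, beta: np.ndarray,
                 globals_: GlobalParams) -> np.ndarray:
    """Fluid flux q = i omega beta u + (i beta/(rho_f omega)) grad p at every
    quadrature point, shape (E, 8gp, 3)."""
    basis = basis_for(mesh.h)
    w = globals_.omega
    u_q, _ = _qp_fields(mesh, basis, np.asarray(u, dtype=complex))
    _, gp = _qp_fields(mesh, basis, np.asarray(p, dtype=complex))
    beta_q, _ = _qp_fields(mesh, basis, np.asarray(beta, dtype=complex))
    return 1j * w * beta_q[..., None] * u_q \
        + (1j / (globals_.rho_f * w)) * beta_q[..., None] * gp


def flux_balance(mesh: Mesh, u: np.ndarray, p: np.ndarray, beta: np.ndarray,
                 globals_: GlobalParams):
    """Global mass balance of the compact pressure equation: the total
    discrete boundary flux (sum of the exact nodal flux loads) against
    i omega int div u.  Returns (boundary_flux, volume_source)."""
    from .pfp import exact_r0_loads
    loads = exact_r0_loads(mesh, u, p, beta, globals_)
    basis = basis_for(mesh.h)
    _, gu = _qp_fields(mesh, basis, np.asarray(u, dtype=complex))
    div = np.einsum("egaa->eg", gu)
    vol = 1j * globals_.omega * np.sum(div * basis.wq[None, :])
    return loads.sum(), vol
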
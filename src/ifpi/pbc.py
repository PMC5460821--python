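"""Type-II pressure boundary condition estimation from displacement data.

The measured complex displacement field is represented by global
least-squares polynomials in (x, y, z) -- one model per real scalar
component, degree 10 by default -- which provide the smooth analytic first
and second derivatives (grad u, div u, the component Laplacians and
grad(div u)) that the momentum-equation substitution needs.  The estimated
Gamma_q loads are the volume integrals

    L_k = <c_u(beta) u, grad phi_k> + i omega <div u, phi_k>
          + <c_L(beta) (div(mu grad u) + grad((lam+mu) div u)), grad phi_k>

with c_u = i beta omega (rho + rho_f - 2 beta rho_f)/(rho_f (1 - beta)) and
c_L = i beta/(rho_f omega (1 - beta)), all displacement derivatives taken
from the polynomial model and the nodal-property gradients from the
trilinear basis.  (These coefficients follow from substituting the momentum
equation into the flux definition; the test suite checks them against exact
discrete flux loads of a converged forward solution.)
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .fem import Mesh, basis_for
from .phantom import PropertyMap
from .gfp import compute_beta


@lru_cache(maxsize=16)
def monomial_exponents(degree: int) -> np.ndarray:
    """All (a, b, c) with a + b + c <= degree; C(degree+3, 3) rows."""
    return np.array([(a, b, c)
                     for a in range(degree + 1)
                     for b in range(degree + 1 - a)
                     for c in range(degree + 1 - a - b)], dtype=np.int64)


def _design_matrix(exponents: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Monomial design matrix at scaled points t in [-1, 1]^3."""
    # powers per axis computed once up to the max exponent
    cols = np.ones((t.shape[0], exponents.shape[0]))
    for a in range(3):
        maxe = exponents[:, a].max()
        pows = np.ones((t.shape[0], maxe + 1))
        for e in range(1, maxe + 1):
            pows[:, e] = pows[:, e - 1] * t[:, a]
        cols *= pows[:, exponents[:, a]]
    return cols


def _derivative_operator(exponents: np.ndarray, axis: int,
                         scale: float) -> np.ndarray:
    """Dense (P, P) matrix mapping monomial coefficients to the coefficients
    of the physical derivative along ``axis`` (chain-rule factor ``scale``)."""
    P = exponents.shape[0]
    index = {tuple(e): i for i, e in enumerate(exponents)}
    D = np.zeros((P, P))
    for i, e in enumerate(exponents):
        if e[axis] == 0:
            continue
        tgt = list(e)
        tgt[axis] -= 1
        D[index[tuple(tgt)], i] = e[axis] * scale
    return D


@dataclass
class PolynomialModel:
    """Global polynomial representation of the displacement field.

    ``coeffs`` is (P, 3) complex -- the real and imaginary parts are the six
    independently fitted real models; coordinates are affinely scaled to
    [-1, 1]^3 before fitting and evaluation."""

    degree: int
    exponents: np.ndarray
    coeffs: np.ndarray
    origin: np.ndarray        # (3,) domain lower corner
    extent: np.ndarray        # (3,) domain edge lengths
    residual_rms: np.ndarray  # (6,) per real component

    def scale_points(self, points: np.ndarray) -> np.ndarray:
        return 2.0 * (points - self.origin) / self.extent - 1.0

    def _dops(self):
        return [_derivative_operator(self.exponents, a, 2.0 / self.extent[a])
                for a in range(3)]

    def derivative_coeffs(self):
        """Coefficient matrices of every derived field: value, the nine
        first derivatives, the component Laplacians and grad(div u)."""
        D = self._dops()
        c = self.coeffs
        grad = np.stack([[D[a] @ c[:, i] for a in range(3)]
                         for i in range(3)])               # (i, a, P)
        lap = np.stack([sum(D[a] @ (D[a] @ c[:, i]) for a in range(3))
                        for i in range(3)])                # (i, P)
        divc = sum(D[i] @ c[:, i] for i in range(3))       # (P,)
        graddiv = np.stack([D[i] @ divc for i in range(3)])
        return {"value": c.T, "grad": grad, "laplacian": lap,
                "div": divc, "grad_div": graddiv}


@dataclass
class DerivativeBundle:
    """Analytic derivatives of the fitted polynomials at a set of points."""

    value: np.ndarray      # (n, 3)
    grad: np.ndarray       # (n, 3, 3)  grad[i][a] = d u_i / d x_a
    laplacian: np.ndarray  # (n, 3)     component Laplacians
    div: np.ndarray        # (n,)
    grad_div: np.ndarray   # (n, 3)


def fit_polynomials(u: np.ndarray, mesh: Mesh, degree: int = 10,
                    nodes: np.ndarray | None = None) -> PolynomialModel:
    """Least-squares fit of the six real displacement components by total-
    degree ``degree`` polynomials on coordinates scaled to [-1, 1]^3, with
    column norm-scaling for conditioning."""
    if not (1 <= degree <= 12):
        raise ValueError("polynomial degree must be between 1 and 12")
    exps = monomial_exponents(degree)
    pts = mesh.coords if nodes is None else mesh.coords[nodes]
    data = np.asarray(u, dtype=complex)
    if nodes is not None:
        data = data[nodes]
    if pts.shape[0] < exps.shape[0]:
        raise ValueError(
            f"underdetermined fit: {pts.shape[0]} nodes < {exps.shape[0]} "
            f"coefficients at degree {degree}")
    origin = np.zeros(3)
    extent = np.full(3, mesh.edge_length)
    t = 2.0 * (pts - origin) / extent - 1.0
    A = _design_matrix(exps, t)
    coln = np.linalg.norm(A, axis=0)
    coln[coln == 0] = 1.0
    sol, *_ = np.linalg.lstsq(A / coln, data, rcond=None)
    coeffs = sol / coln[:, None]
    fit = A @ coeffs
    res = fit - data
    rms = np.empty(6)
    rms[0::2] = np.sqrt(np.mean(res.real ** 2, axis=0))
    rms[1::2] = np.sqrt(np.mean(res.imag ** 2, axis=0))
    return PolynomialModel(degree=degree, exponents=exps, coeffs=coeffs,
                           origin=origin, extent=extent, residual_rms=rms)


def eval_derivatives(model: PolynomialModel, points: np.ndarray,
                     chunk: int = 20000) -> DerivativeBundle:
    """Evaluate the fitted field and its analytic derivatives at arbitrary
    points inside (or on the hull of) the fitted domain."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dc = model.derivative_coeffs()
    n = points.shape[0]
    value = np.empty((n, 3), dtype=complex)
    grad = np.empty((n, 3, 3), dtype=complex)
    lap = np.empty((n, 3), dtype=complex)
    div = np.empty(n, dtype=complex)
    graddiv = np.empty((n, 3), dtype=complex)
    for s in range(0, n, chunk):
        t = model.scale_points(points[s:s + chunk])
        A = _design_matrix(model.exponents, t)
        value[s:s + chunk] = A @ dc["value"].T
        for i in range(3):
            for a in range(3):
                grad[s:s + chunk, i, a] = A @ dc["grad"][i, a]
            lap[s:s + chunk, i] = A @ dc["laplacian"][i]
            graddiv[s:s + chunk, i] = A @ dc["grad_div"][i]
        div[s:s + chunk] = A @ dc["div"]
    return DerivativeBundle(value=value, grad=grad, laplacian=lap,
                            div=div, grad_div=graddiv)


def peak_slice_laplacian(mesh: Mesh, model: PolynomialModel, axis: int,
                         coordinate: float, component: int = 0,
                         part=np.real, pull_elements: float = 1.0) -> float:
    """Peak |div grad u_c| of the fitted displacement component over a grid
    slice, evaluated with the package's endpoint rule (points within
    ``pull_elements`` elements of the hull are pulled inward, where the
    least-squares polynomial derivatives are trustworthy).  Units 1/m for
    displacement in m."""
    nodes = mesh.interior_slice_nodes(axis, coordinate)
    pull = pull_elements * mesh.h
    pts = np.clip(mesh.coords[nodes], pull, mesh.edge_length - pull)
    bundle = eval_derivatives(model, pts)
    return float(np.abs(part(bundle.laplacian[:, component])).max())


def _boundary_elements(mesh: Mesh) -> np.ndarray:
    bmask = mesh.boundary_node_mask()
    return np.nonzero(bmask[mesh.elements].any(axis=1))[0]


def _theta_at_qp(basis, conn, theta: PropertyMap, beta_nodal):
    """Trilinear interpolation of mu, lam+mu, beta and the property
    gradients at the element quadrature points."""
    lamu_nodal = theta.lam + theta.mu
    mu_e = theta.mu[conn]
    lamu_e = lamu_nodal[conn]
    beta_e = beta_nodal[conn]
    return {
        "mu": np.einsum("gj,ej->eg", basis.N, mu_e),
        "gmu": np.einsum("gja,ej->ega", basis.dNdx, mu_e),
        "lamu": np.einsum("gj,ej->eg", basis.N, lamu_e),
        "glamu": np.einsum("gja,ej->ega", basis.dNdx, lamu_e),
        "beta": np.einsum("gj,ej->eg", basis.N, beta_e),
    }


def _elastic_operator(bundle_fields, props):
    """div(mu grad u) + grad((lam+mu) div u) expanded with nodal-theta
    gradients, at quadrature points."""
    uq, gradq, lapq, divq, gdivq = bundle_fields
    return (props["mu"][..., None] * lapq
            + np.einsum("ega,egia->egi", props["gmu"], gradq)
            + props["lamu"][..., None] * gdivq
            + divq[..., None] * props["glamu"])


def displacement_pressure_source(mesh: Mesh, model: PolynomialModel,
                                 theta: PropertyMap,
                                 chunk: int = 1500) -> np.ndarray:
    """Volumetric-deformation source of the reduced pressure problem,
    evaluated from the fitted polynomial (the smoothed stand-in for the
    measured displacement):

        b(k) = -i omega <div u, phi_k> - i omega <beta u, grad phi_k>.

    Because beta is known nodally, these rows anchor the absolute pressure
    scale to the displacement data -- the current property estimate does
    not enter them."""
    g = theta.globals
    w = g.omega
    basis = basis_for(mesh.h)
    beta_nodal = compute_beta(g, theta.kappa)
    b = np.zeros(mesh.n_nodes, dtype=complex)
    conn_all = mesh.elements
    for s in range(0, conn_all.shape[0], chunk):
        conn = conn_all[s:s + chunk]
        E = conn.shape[0]
        qp = basis.element_qp_coords(mesh, np.arange(s, s + E))
        bb = eval_derivatives(model, qp.reshape(-1, 3))
        uq = bb.value.reshape(E, 8, 3)
        divq = bb.div.reshape(E, 8)
        beta_q = np.einsum("gj,ej->eg", basis.N, beta_nodal[conn])
        F = -1j * w * beta_q[..., None] * uq
        G = -1j * w * divq
        contrib = np.einsum("g,egi,gki->ek", basis.wq, F, basis.dNdx) \
            + np.einsum("g,eg,gk->ek", basis.wq, G, basis.N)
        np.add.at(b, conn.ravel(), contrib.ravel())
    return b


def momentum_source(mesh: Mesh, model: PolynomialModel, theta: PropertyMap,
                    pull_elements: float = 1.0, chunk: int = 1500
                    ) -> np.ndarray:
    """Substituted form of the pressure right-hand side at a node: the
    estimated type-II load combined with the volumetric source,

        b(k) = <i omega beta (rho - beta rho_f)/((1-beta) rho_f) u, grad phi_k>
               + <(i beta/((1-beta) rho_f omega))
                  (div(mu grad u) + grad((lam+mu) div u)), grad phi_k>.

    Used for the Gamma_q (flux-boundary) rows of the pressure solve, where
    the surface integral of the unknown normal flux must be estimated from
    the displacement model through the momentum equation.  Evaluation
    points closer than ``pull_elements`` elements to the hull are pulled
    inward, where the least-squares polynomial derivatives are reliable
    (endpoint derivatives of a global fit are not).
    """
    g = theta.globals
    w, rho, rho_f = g.omega, g.rho, g.rho_f
    basis = basis_for(mesh.h)
    beta_nodal = compute_beta(g, theta.kappa)
    if np.any(np.abs(1.0 - beta_nodal) < 1e-12):
        raise ZeroDivisionError("beta = 1 encountered")
    pull = pull_elements * mesh.h
    b = np.zeros(mesh.n_nodes, dtype=complex)
    conn_all = mesh.elements
    for s in range(0, conn_all.shape[0], chunk):
        conn = conn_all[s:s + chunk]
        E = conn.shape[0]
        qp = basis.element_qp_coords(mesh, np.arange(s, s + E))
        pts = np.clip(qp.reshape(-1, 3), pull, mesh.edge_length - pull)
        bb = eval_derivatives(model, pts)
        fields = (bb.value.reshape(E, 8, 3), bb.grad.reshape(E, 8, 3, 3),
                  bb.laplacian.reshape(E, 8, 3), bb.div.reshape(E, 8),
                  bb.grad_div.reshape(E, 8, 3))
        props = _theta_at_qp(basis, conn, theta, beta_nodal)
        Lu = _elastic_operator(fields, props)
        bq = props["beta"]
        c_u = 1j * w * bq * (rho - bq * rho_f) / ((1.0 - bq) * rho_f)
        c_L = 1j * bq / ((1.0 - bq) * rho_f * w)
        F = c_u[..., None] * fields[0] + c_L[..., None] * Lu
        contrib = np.einsum("g,egi,gki->ek", basis.wq, F, basis.dNdx)
        np.add.at(b, conn.ravel(), contrib.ravel())
    return b


def estimate_r0_loads(mesh: Mesh, model: PolynomialModel,
                      theta: PropertyMap,
                      gamma_q_nodes: np.ndarray | None = None) -> np.ndarray:
    """Estimated nodal Gamma_q loads (the surface integral of r0 against each
    boundary basis function), from the polynomial displacement model and the
    current property estimate.  Returns a full-length nodal vector that is
    zero away from ``gamma_q_nodes`` (default: every node on a flux-tagged
    facet)."""
    g = theta.globals
    w, rho, rho_f = g.omega, g.rho, g.rho_f
    basis = basis_for(mesh.h)
    beta_nodal = compute_beta(g, theta.kappa)
    if np.any(np.abs(1.0 - beta_nodal) < 1e-12):
        raise ZeroDivisionError("beta = 1 encountered; the momentum "
                                "substitution is singular")
    elems = _boundary_elements(mesh)
    loads = np.zeros(mesh.n_nodes, dtype=complex)
    chunk = 1000
    for s in range(0, elems.size, chunk):
        sel = elems[s:s + chunk]
        conn = mesh.elements[sel]
        qp = basis.element_qp_coords(mesh, sel)            # (E, 8g, 3)
        E = conn.shape[0]
        bundle = eval_derivatives(model, qp.reshape(-1, 3))
        fields = (bundle.value.reshape(E, 8, 3),
                  bundle.grad.reshape(E, 8, 3, 3),
                  bundle.laplacian.reshape(E, 8, 3),
                  bundle.div.reshape(E, 8),
                  bundle.grad_div.reshape(E, 8, 3))
        props = _theta_at_qp(basis, conn, theta, beta_nodal)
        beta_q = props["beta"]
        c_u = 1j * beta_q * w * (rho + rho_f - 2.0 * beta_q * rho_f) \
            / (rho_f * (1.0 - beta_q))
        c_L = 1j * beta_q / (rho_f * w * (1.0 - beta_q))
        Lu = _elastic_operator(fields, props)
        F = c_u[..., None] * fields[0] + c_L[..., None] * Lu   # (E, 8g, 3)
        G = 1j * w * fields[3]                                 # (E, 8g)
        contrib = np.einsum("g,egi,gki->ek", basis.wq, F, basis.dNdx) \
            + np.einsum("g,eg,gk->ek", basis.wq, G, basis.N)
        np.add.at(loads, conn.ravel(), contrib.ravel())
    if gamma_q_nodes is None:
        gamma_q_nodes = mesh.nodes_with_pres_tag("flux")
    mask = np.zeros(mesh.n_nodes, dtype=bool)
    mask[gamma_q_nodes] = True
    loads[~mask] = 0.0
    return loads
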
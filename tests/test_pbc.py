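"""Polynomial displacement models, analytic derivatives, and estimated
pressure boundary loads."""
import numpy as np
import pytest

from ifpi.fem import build_structured_mesh
from ifpi.phantom import GlobalParams, PropertyMap, PhantomConfig, add_noise
from ifpi.gfp import compute_beta
from ifpi.pbc import (monomial_exponents, fit_polynomials, eval_derivatives,
                      estimate_r0_loads, momentum_source)
from ifpi.pfp import (_pressure_stiffness, _displacement_source,
                      exact_r0_loads)


def test_coefficient_count():
    # C(degree + 3, 3) monomials of total degree <= degree
    assert monomial_exponents(2).shape[0] == 10
    assert monomial_exponents(10).shape[0] == 286


def test_degree2_polynomial_recovered_exactly():
    mesh = build_structured_mesh(0.06, 7)
    x, y, z = mesh.coords.T
    u = np.stack([1 + 2 * x - y ** 2 + 0.5 * x * z,
                  3 * z ** 2 - x * y,
                  x + y + z + x ** 2], axis=1).astype(complex)
    model = fit_polynomials(u, mesh, degree=2)
    b = eval_derivatives(model, mesh.coords)
    assert np.allclose(b.value, u, rtol=1e-8, atol=1e-10)
    assert model.residual_rms.max() < 1e-10


def test_constant_field_single_coefficient():
    mesh = build_structured_mesh(0.06, 5)
    u = np.full((mesh.n_nodes, 3), 2.5 + 0.5j)
    model = fit_polynomials(u, mesh, degree=3)
    const_row = np.all(model.exponents == 0, axis=1)
    assert np.allclose(model.coeffs[const_row], 2.5 + 0.5j)
    assert np.abs(model.coeffs[~const_row]).max() < 1e-12


def test_linear_field_second_derivatives_vanish():
    mesh = build_structured_mesh(0.06, 5)
    u = (mesh.coords @ np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]]).T
         ).astype(complex)
    model = fit_polynomials(u, mesh, degree=4)
    b = eval_derivatives(model, mesh.coords)
    assert np.abs(b.laplacian).max() < 1e-8
    assert np.abs(b.grad_div).max() < 1e-8


def test_trig_field_derivatives_interior_accuracy():
    """Degree-10 fit of a smooth trigonometric field on the 21^3 grid gets
    values and first/second derivatives to <=1% interior relative error."""
    mesh = build_structured_mesh(0.06, 21)
    x, y, z = mesh.coords.T
    k = 2 * np.pi / 0.06
    u = np.stack([np.sin(k * x) * np.cos(0.5 * k * y),
                  np.cos(k * z),
                  np.sin(0.5 * k * (x + z))], axis=1).astype(complex)
    model = fit_polynomials(u, mesh, degree=10)
    interior = ((mesh.coords > 0.009) & (mesh.coords < 0.051)).all(axis=1)
    pts = mesh.coords[interior]
    b = eval_derivatives(model, pts)
    lap_true = np.stack([
        -(k ** 2 + 0.25 * k ** 2) * np.sin(k * pts[:, 0])
        * np.cos(0.5 * k * pts[:, 1]),
        -k ** 2 * np.cos(k * pts[:, 2]),
        -0.5 * k ** 2 * np.sin(0.5 * k * (pts[:, 0] + pts[:, 2]))], axis=1)
    val_true = np.stack([np.sin(k * pts[:, 0]) * np.cos(0.5 * k * pts[:, 1]),
                         np.cos(k * pts[:, 2]),
                         np.sin(0.5 * k * (pts[:, 0] + pts[:, 2]))], axis=1)
    assert np.linalg.norm(b.value - val_true) / np.linalg.norm(val_true) < 0.01
    assert np.linalg.norm(b.laplacian - lap_true) / np.linalg.norm(lap_true) < 0.01


def test_derivatives_match_symbolic_oracle():
    """Random degree-6 polynomial data: fitted derivatives equal symbolic
    differentiation."""
    import sympy as sp
    mesh = build_structured_mesh(0.06, 9)
    x, y, z = sp.symbols("x y z")
    rng = np.random.default_rng(4)
    exps = monomial_exponents(6)
    keep = rng.choice(exps.shape[0], size=25, replace=False)
    coefs = rng.normal(size=25)
    expr = sum(c * x ** int(a) * y ** int(b) * z ** int(cc)
               for c, (a, b, cc) in zip(coefs, exps[keep] * 1.0))
    f = sp.lambdify((x, y, z), expr, "numpy")
    vals = f(*mesh.coords.T) * np.ones(mesh.n_nodes)
    u = np.stack([vals, 2 * vals, -vals], axis=1).astype(complex)
    model = fit_polynomials(u, mesh, degree=6)
    pts = mesh.coords[::7]
    b = eval_derivatives(model, pts)
    lap_expr = sp.diff(expr, x, 2) + sp.diff(expr, y, 2) + sp.diff(expr, z, 2)
    lap = sp.lambdify((x, y, z), lap_expr, "numpy")(*pts.T) * np.ones(len(pts))
    assert np.allclose(b.laplacian[:, 0], lap, rtol=1e-6, atol=1e-6 * np.abs(lap).max())
    gx = sp.lambdify((x, y, z), sp.diff(expr, x), "numpy")(*pts.T) * np.ones(len(pts))
    assert np.allclose(b.grad[:, 0, 0], gx, rtol=1e-7, atol=1e-9 * np.abs(gx).max())


def test_underdetermined_fit_raises():
    mesh = build_structured_mesh(0.06, 5)   # 125 nodes < 286 coefficients
    u = np.zeros((mesh.n_nodes, 3), dtype=complex)
    with pytest.raises(ValueError, match="underdetermined"):
        fit_polynomials(u, mesh, degree=10)


def test_zero_displacement_zero_loads():
    cfg = PhantomConfig.two_parameter(nodes_per_axis=7)
    mesh = cfg.build_mesh("ifpi")
    theta = cfg.build_properties(mesh)
    u = np.zeros((mesh.n_nodes, 3), dtype=complex)
    model = fit_polynomials(u, mesh, degree=4)
    loads = estimate_r0_loads(mesh, model, theta)
    assert np.abs(loads).max() < 1e-20


def _manufactured(mesh, g, mu0, lam0, kap0):
    """Potential-flow displacement with the pressure defined exactly by the
    momentum equation (constant properties)."""
    b0 = compute_beta(g, np.array([kap0]))[0]
    x, y, z = mesh.coords.T
    psi = x ** 2 * y + 0.5 * z ** 4 + x * y * z + 0.3 * x ** 3 - y ** 2 * z
    lap_psi = 2 * y + 6 * z ** 2 + 1.8 * x - 2 * z
    u = np.stack([2 * x * y + y * z + 0.9 * x ** 2,
                  x ** 2 + x * z - 2 * y * z,
                  2 * z ** 3 + x * y - y ** 2], axis=1).astype(complex)
    p = ((lam0 + 2 * mu0) * lap_psi
         + g.omega ** 2 * (g.rho - b0 * g.rho_f) * psi) / (1 - b0)
    return u, p.astype(complex)


def test_estimated_loads_match_exact_loads_on_smooth_field():
    """The momentum-substitution load formula against the exact discrete
    flux loads of a manufactured smooth solution."""
    g = GlobalParams()
    cfg = PhantomConfig.two_parameter(nodes_per_axis=11, inclusion_box=None)
    mesh = cfg.build_mesh("ifpi")
    theta = cfg.build_properties(mesh)
    mu0, lam0, kap0 = theta.mu[0], theta.lam[0], theta.kappa[0]
    u, p = _manufactured(mesh, g, mu0, lam0, kap0)
    beta = compute_beta(g, theta.kappa)
    exact = exact_r0_loads(mesh, u, p, beta, g)
    model = fit_polynomials(u, mesh, degree=6)   # fits the cubic field exactly
    allb = np.nonzero(mesh.boundary_node_mask())[0]
    est = estimate_r0_loads(mesh, model, theta, allb)
    m = np.zeros(mesh.n_nodes, dtype=bool)
    m[allb] = True
    rel = np.linalg.norm((est - exact)[m]) / np.linalg.norm(exact[m])
    assert rel < 0.02


def test_constant_coefficient_reduction_identity():
    """With homogeneous mu, lambda the property-gradient terms vanish, so
    the general evaluation equals the reduced constant-coefficient form."""
    g = GlobalParams()
    cfg = PhantomConfig.two_parameter(nodes_per_axis=9, inclusion_box=None)
    mesh = cfg.build_mesh("ifpi")
    theta = cfg.build_properties(mesh)
    u, _ = _manufactured(mesh, g, theta.mu[0], theta.lam[0], theta.kappa[0])
    model = fit_polynomials(u, mesh, degree=5)
    allb = np.nonzero(mesh.boundary_node_mask())[0]
    general = estimate_r0_loads(mesh, model, theta, allb)

    # reduced form: mu lap(u) + (lam+mu) grad(div u) only
    from ifpi.fem import basis_for
    basis = basis_for(mesh.h)
    beta = compute_beta(g, theta.kappa)
    loads = np.zeros(mesh.n_nodes, dtype=complex)
    conn = mesh.elements
    qp = basis.element_qp_coords(mesh)
    b = eval_derivatives(model, qp.reshape(-1, 3))
    E = conn.shape[0]
    uq = b.value.reshape(E, 8, 3)
    lapq = b.laplacian.reshape(E, 8, 3)
    divq = b.div.reshape(E, 8)
    gdivq = b.grad_div.reshape(E, 8, 3)
    b0 = beta[0]
    w = g.omega
    cu = 1j * b0 * w * (g.rho + g.rho_f - 2 * b0 * g.rho_f) \
        / (g.rho_f * (1 - b0))
    cL = 1j * b0 / (g.rho_f * w * (1 - b0))
    Lu = theta.mu[0] * lapq + (theta.lam[0] + theta.mu[0]) * gdivq
    F = cu * uq + cL * Lu
    contrib = np.einsum("g,egi,gki->ek", basis.wq, F, basis.dNdx) \
        + np.einsum("g,eg,gk->ek", basis.wq, 1j * w * divq, basis.N)
    np.add.at(loads, conn.ravel(), contrib.ravel())
    m = np.zeros(mesh.n_nodes, dtype=bool)
    m[allb] = True
    loads[~m] = 0.0
    assert np.linalg.norm(loads[m] - general[m]) \
        <= 1e-10 * np.linalg.norm(general[m])


def test_momentum_source_is_exactly_compatible(small_inclusion):
    """The substituted right-hand side integrates basis gradients only, so
    its total sum vanishes identically (point-anchored solvability)."""
    s = small_inclusion
    mesh = s["mesh_ifpi"]
    model = fit_polynomials(s["u"], mesh, degree=8)
    b = momentum_source(mesh, model, s["theta"])
    assert abs(b.sum()) <= 1e-10 * np.abs(b).max()


def test_fit_residual_decreases_with_degree(small_inclusion):
    """Noiseless data: higher polynomial order fits the displacement field
    better; noisy data: the derivative fields roughen with order."""
    s = small_inclusion
    mesh = s["mesh_ifpi"]
    res = [fit_polynomials(s["u"], mesh, d).residual_rms.mean()
           for d in (4, 8, 10)]
    assert res[0] > res[1] > res[2]

    noisy = add_noise(s["u"], 10.0, 3)
    rough = []
    for d in (4, 10, 12):
        model = fit_polynomials(noisy, mesh, d)
        b = eval_derivatives(model, mesh.coords)
        rough.append(np.linalg.norm(b.laplacian))
    assert rough[0] < rough[1] < rough[2]


def test_noise_robustness_of_fitted_derivatives(small_inclusion):
    """Fitted second-derivative fields from noisy data stay bounded and
    retain a positive share of the noiseless spatial pattern, degrading
    monotonically as the noise grows."""
    s = small_inclusion
    mesh = s["mesh_ifpi"]
    clean = fit_polynomials(s["u"], mesh, degree=8)
    pts = mesh.coords[~mesh.boundary_node_mask()]
    b0 = eval_derivatives(clean, pts).laplacian[:, 0].real
    corrs = []
    for pct in (5.0, 10.0, 15.0):
        noisy = fit_polynomials(add_noise(s["u"], pct, 6), mesh, degree=8)
        b1 = eval_derivatives(noisy, pts).laplacian[:, 0].real
        assert np.isfinite(b1).all()
        # bounded: noise does not blow the derivative scale up by orders
        assert np.linalg.norm(b1) < 20 * np.linalg.norm(b0)
        corrs.append(np.corrcoef(b0, b1)[0, 1])
    assert corrs[0] > corrs[1] > corrs[2] > 0.1
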
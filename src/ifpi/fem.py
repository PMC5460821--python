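"""Trilinear hexahedral finite-element core on structured grids.

Provides the mesh, the 8-node trilinear basis with 2x2x2 Gauss quadrature,
precomputed reference integral tensors used by every assembly routine in the
package, and a constrained sparse linear solver.  All geometry is SI (meters);
the structured grid has identical axis-aligned cube elements of edge ``h``,
so every element shares one set of reference tensors.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu


class ConfigurationError(ValueError):
    """Invalid mesh / boundary-condition configuration."""


class SingularSystemError(RuntimeError):
    """Constrained linear system is singular (e.g. no pressure anchor)."""


# Local node numbering of the hexahedron (VTK order): offsets in (ix, iy, iz).
HEX_OFFSETS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=np.int64)
REF_SIGNS = 2.0 * HEX_OFFSETS - 1.0  # reference coordinates of local nodes

#: face name -> (axis, side); side 0 is the min face, 1 the max face
FACES = {"x-": (0, 0), "x+": (0, 1), "y-": (1, 0), "y+": (1, 1),
         "z-": (2, 0), "z+": (2, 1)}

DISP_TAGS = ("dirichlet", "traction")   # Gamma_u / Gamma_sigma
PRES_TAGS = ("dirichlet", "flux")       # Gamma_p / Gamma_q


@dataclass
class Mesh:
    """Structured grid of 8-node hexahedra on a cube.

    ``coords`` is (N, 3) node positions, ``elements`` (E, 8) connectivity in
    VTK node order, and boundary facets are quadrilaterals tagged with both a
    displacement role (Gamma_u or Gamma_sigma) and a pressure role (Gamma_p
    or Gamma_q), so the two decompositions each cover the whole surface.
    """

    coords: np.ndarray
    elements: np.ndarray
    shape: tuple
    h: float
    edge_length: float
    facet_nodes: np.ndarray       # (F, 4) corner nodes, counterclockwise
    facet_normals: np.ndarray     # (F, 3) outward unit normals
    facet_face: np.ndarray        # (F,) face name of each facet
    facet_disp_tag: np.ndarray    # (F,) 'dirichlet' | 'traction'
    facet_pres_tag: np.ndarray    # (F,) 'dirichlet' | 'flux'

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def node_index(self, ix, iy, iz):
        nx, ny, _ = self.shape
        return ix + nx * (iy + ny * iz)

    def node_grid(self):
        """Grid indices (ix, iy, iz) of every node, each (N,)."""
        nx, ny, nz = self.shape
        idx = np.arange(self.n_nodes)
        ix = idx % nx
        iy = (idx // nx) % ny
        iz = idx // (nx * ny)
        return ix, iy, iz

    def boundary_node_mask(self) -> np.ndarray:
        ix, iy, iz = self.node_grid()
        nx, ny, nz = self.shape
        return ((ix == 0) | (ix == nx - 1) | (iy == 0) | (iy == ny - 1)
                | (iz == 0) | (iz == nz - 1))

    def face_node_mask(self, face: str) -> np.ndarray:
        axis, side = FACES[face]
        ix, iy, iz = self.node_grid()
        g = (ix, iy, iz)[axis]
        return g == (0 if side == 0 else self.shape[axis] - 1)

    def nodes_with_pres_tag(self, tag: str) -> np.ndarray:
        """Nodes lying on any facet carrying pressure tag ``tag``."""
        sel = self.facet_pres_tag == tag
        return np.unique(self.facet_nodes[sel])

    def nodes_with_disp_tag(self, tag: str) -> np.ndarray:
        sel = self.facet_disp_tag == tag
        return np.unique(self.facet_nodes[sel])

    def interior_slice_nodes(self, axis: int, coordinate: float) -> np.ndarray:
        """Node indices of the grid plane closest to ``coordinate`` on ``axis``."""
        i = int(round(coordinate / self.h))
        ix, iy, iz = self.node_grid()
        g = (ix, iy, iz)[axis]
        return np.nonzero(g == i)[0]


def default_bc_layout() -> dict:
    return {f: ("dirichlet", "dirichlet") for f in FACES}


def build_structured_mesh(edge_length: float, nodes_per_axis: int,
                          bc_layout: dict | None = None) -> Mesh:
    """Build an ``n^3``-node structured hex mesh of a cube with tagged facets.

    ``bc_layout`` maps each face name ('x-', ..., 'z+') to a pair
    ``(disp_tag, pres_tag)``; untagged faces default to ('dirichlet',
    'dirichlet').
    """
    if edge_length <= 0:
        raise ConfigurationError("edge_length must be positive")
    n = int(nodes_per_axis)
    if n < 3 or n != nodes_per_axis:
        raise ConfigurationError("nodes_per_axis must be an integer >= 3")
    layout = default_bc_layout()
    if bc_layout:
        for face, tags in bc_layout.items():
            if face not in FACES:
                raise ConfigurationError(f"unknown face {face!r}")
            dt, pt = tags
            if dt not in DISP_TAGS or pt not in PRES_TAGS:
                raise ConfigurationError(f"bad tags {tags!r} for face {face!r}")
            layout[face] = (dt, pt)

    h = edge_length / (n - 1)
    ax = np.arange(n) * h
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    # node id = ix + n*(iy + n*iz): x fastest
    coords = np.stack([X.transpose(2, 1, 0).ravel(),
                       Y.transpose(2, 1, 0).ravel(),
                       Z.transpose(2, 1, 0).ravel()], axis=1)

    def nid(ix, iy, iz):
        return ix + n * (iy + n * iz)

    # element id = ex + (n-1)*(ey + (n-1)*ez): x fastest, like the nodes
    idxe = np.arange((n - 1) ** 3, dtype=np.int64)
    ex = idxe % (n - 1)
    ey = (idxe // (n - 1)) % (n - 1)
    ez = idxe // ((n - 1) ** 2)
    elements = np.stack([nid(ex + o[0], ey + o[1], ez + o[2])
                         for o in HEX_OFFSETS], axis=1)

    facet_nodes, facet_normals, facet_face = [], [], []
    facet_dt, facet_pt = [], []
    rng = np.arange(n - 1)
    A, B = np.meshgrid(rng, rng, indexing="ij")
    A, B = A.ravel(), B.ravel()
    for face, (axis, side) in FACES.items():
        fixed = 0 if side == 0 else n - 1
        normal = np.zeros(3)
        normal[axis] = -1.0 if side == 0 else 1.0
        # counterclockwise corner order seen from outside is irrelevant for
        # the integrals used here; a consistent bilinear order suffices
        quads = []
        for da, db in ((0, 0), (1, 0), (1, 1), (0, 1)):
            a, b = A + da, B + db
            if axis == 0:
                quads.append(nid(fixed, a, b))
            elif axis == 1:
                quads.append(nid(a, fixed, b))
            else:
                quads.append(nid(a, b, fixed))
        quads = np.stack(quads, axis=1)
        facet_nodes.append(quads)
        facet_normals.append(np.tile(normal, (quads.shape[0], 1)))
        facet_face.extend([face] * quads.shape[0])
        dt, pt = layout[face]
        facet_dt.extend([dt] * quads.shape[0])
        facet_pt.extend([pt] * quads.shape[0])

    return Mesh(coords=coords, elements=elements, shape=(n, n, n), h=h,
                edge_length=edge_length,
                facet_nodes=np.concatenate(facet_nodes, axis=0),
                facet_normals=np.concatenate(facet_normals, axis=0),
                facet_face=np.array(facet_face),
                facet_disp_tag=np.array(facet_dt),
                facet_pres_tag=np.array(facet_pt))


# ---------------------------------------------------------------------------
# Basis and reference tensors
# ---------------------------------------------------------------------------

def _gauss1d():
    g = 1.0 / np.sqrt(3.0)
    return np.array([-g, g]), np.array([1.0, 1.0])


class HexBasis:
    """Trilinear basis with 2x2x2 Gauss quadrature on cube elements of edge h.

    Precomputes the reference integral tensors used in every bilinear form:

    - ``S[m,k,j,a,b]``  = int N_m dN_k/dx_a dN_j/dx_b
    - ``M3[m,k,j]``     = int N_m N_k N_j
    - ``D3[m,k,j,a]``   = int N_m N_k dN_j/dx_a
    - ``M2``, ``D2``, ``S2`` the constant-coefficient counterparts

    ``Sdiag`` contracts S over a == b (grad-grad forms).  All integrals are
    exact for trilinear coefficient fields (integrands are at most cubic per
    axis and 2-point Gauss is exact through cubic).
    """

    def __init__(self, h: float):
        self.h = float(h)
        pts, wts = _gauss1d()
        gp = np.array([[x, y, z] for z in pts for y in pts for x in pts])
        w = np.array([1.0 for _ in range(8)]) * (h / 2.0) ** 3
        # N[g, j], dNdx[g, j, a]
        N = np.ones((8, 8))
        dNdxi = np.zeros((8, 8, 3))
        for j in range(8):
            s = REF_SIGNS[j]
            terms = (1 + s[None, :] * gp) / 2.0          # (8 gp, 3)
            N[:, j] = terms.prod(axis=1)
            for a in range(3):
                d = s[a] / 2.0
                others = [b for b in range(3) if b != a]
                dNdxi[:, j, a] = d * terms[:, others].prod(axis=1)
        self.gp_ref = gp
        self.N = N
        self.dNdx = dNdxi * (2.0 / h)
        self.wq = w
        self.S = np.einsum("g,gm,gka,gjb->mkjab", w, N, self.dNdx, self.dNdx)
        self.Sdiag = np.einsum("mkjaa->mkj", self.S)
        self.M3 = np.einsum("g,gm,gk,gj->mkj", w, N, N, N)
        self.D3 = np.einsum("g,gm,gk,gja->mkja", w, N, N, self.dNdx)
        self.M2 = np.einsum("g,gk,gj->kj", w, N, N)
        self.D2 = np.einsum("g,gk,gja->kja", w, N, self.dNdx)
        self.S2 = np.einsum("g,gka,gjb->kjab", w, self.dNdx, self.dNdx)
        self.S2diag = np.einsum("kjaa->kj", self.S2)
        # facet (bilinear quad) quadrature, area element (h/2)^2
        fgp = np.array([[x, y] for y in pts for x in pts])
        signs2 = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
        N2 = np.ones((4, 4))
        for j in range(4):
            t = (1 + signs2[j][None, :] * fgp) / 2.0
            N2[:, j] = t.prod(axis=1)
        self.facet_N = N2
        self.facet_wq = np.full(4, (h / 2.0) ** 2)
        self.facet_mass = np.einsum("g,gk,gj->kj", self.facet_wq, N2, N2)

    def element_qp_coords(self, mesh: Mesh, elems=None) -> np.ndarray:
        """Physical quadrature-point coordinates, shape (E, 8 gp, 3)."""
        conn = mesh.elements if elems is None else mesh.elements[elems]
        corner = mesh.coords[conn]                       # (E, 8, 3)
        return np.einsum("gj,ejc->egc", self.N, corner)


@lru_cache(maxsize=8)
def basis_for(h: float) -> HexBasis:
    return HexBasis(h)


def element_matrices(mesh: Mesh, basis: HexBasis, element: int,
                     coefficient: np.ndarray) -> dict:
    """Local matrices for one element with a trilinearly interpolated
    coefficient: stiffness int c grad.grad, mass int c N N, and the mixed
    int c N dN forms."""
    conn = mesh.elements[element]
    c = np.asarray(coefficient)[conn]
    return {
        "stiffness": np.einsum("m,mkj->kj", c, basis.Sdiag),
        "mass": np.einsum("m,mkj->kj", c, basis.M3),
        "mixed": np.einsum("m,mkja->kja", c, basis.D3),
        "stiffness_full": np.einsum("m,mkjab->kjab", c, basis.S),
    }


# ---------------------------------------------------------------------------
# Assembly / solve helpers
# ---------------------------------------------------------------------------

def assemble_blocks(conn_dofs: np.ndarray, blocks: np.ndarray,
                    n_dofs: int) -> sp.csr_matrix:
    """Scatter dense per-element blocks (E, L, L) into a global sparse matrix
    using the per-element dof lists ``conn_dofs`` (E, L)."""
    E, L = conn_dofs.shape
    rows = np.repeat(conn_dofs, L, axis=1).ravel()
    cols = np.tile(conn_dofs, (1, L)).ravel()
    K = sp.coo_matrix((blocks.ravel(), (rows, cols)),
                      shape=(n_dofs, n_dofs))
    return K.tocsr()


def facet_load_vector(mesh: Mesh, basis: HexBasis, facet_mask: np.ndarray,
                      nodal_values: np.ndarray) -> np.ndarray:
    """Assemble surface loads int_F g phi_k over the selected facets, with g
    given nodally (trilinear on each facet).  Returns a per-node vector."""
    out = np.zeros(mesh.n_nodes, dtype=complex)
    quads = mesh.facet_nodes[facet_mask]
    if quads.size == 0:
        return out
    vals = np.asarray(nodal_values, dtype=complex)[quads]     # (F, 4)
    loads = np.einsum("kj,fj->fk", basis.facet_mass, vals)
    np.add.at(out, quads.ravel(), loads.ravel())
    return out


@lru_cache(maxsize=32)
def nested_dissection_order(shape: tuple) -> np.ndarray:
    """Fill-reducing node ordering for a structured grid by recursive plane
    bisection (classic nested dissection).  Returns ``rank`` such that node
    ``i`` should be eliminated at position ``rank[i]``; separator planes are
    ordered last at every level, which bounds LU fill far better than
    generic orderings on these meshes."""
    nx, ny, nz = shape
    idx = np.arange(nx * ny * nz, dtype=np.int64)
    grid = np.stack([idx % nx, (idx // nx) % ny, idx // (nx * ny)], axis=1)

    order = np.empty(nx * ny * nz, dtype=np.int64)
    pos = [0]

    def emit(sel):
        k = sel.size
        order[pos[0]:pos[0] + k] = sel
        pos[0] += k

    def recurse(sel, lo, hi):
        span = hi - lo
        if span.max() <= 2 or sel.size <= 32:
            emit(sel)
            return
        axis = int(np.argmax(span))
        mid = (lo[axis] + hi[axis]) // 2
        g = grid[sel, axis]
        left = sel[g < mid]
        right = sel[g > mid]
        sep = sel[g == mid]
        lo_r = lo.copy(); lo_r[axis] = mid + 1
        hi_l = hi.copy(); hi_l[axis] = mid - 1
        recurse(left, lo, hi_l)
        recurse(right, lo_r, hi)
        emit(sep)

    recurse(np.arange(nx * ny * nz, dtype=np.int64),
            np.zeros(3, dtype=np.int64),
            np.array([nx - 1, ny - 1, nz - 1], dtype=np.int64))
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return rank


def node_order_to_dof_key(rank: np.ndarray, dofs_per_node: int) -> np.ndarray:
    """Expand a node elimination rank to a per-dof sort key (dofs of one
    node stay adjacent)."""
    n = rank.size
    return (dofs_per_node * rank[:, None]
            + np.arange(dofs_per_node)[None, :]).ravel()


def _equilibrate(K: sp.csc_matrix):
    """Symmetric-style diagonal scaling D1 K D2 to tame the ~1e11 spread
    between displacement and pressure rows."""
    a = abs(K)
    r = np.asarray(a.max(axis=1).todense()).ravel()
    r[r == 0] = 1.0
    Dr = sp.diags(1.0 / np.sqrt(r))
    a2 = abs(Dr @ K)
    c = np.asarray(a2.max(axis=0).todense()).ravel()
    c[c == 0] = 1.0
    Dc = sp.diags(1.0 / np.sqrt(c * r))  # combine to keep scaling balanced
    Dr2 = sp.diags(1.0 / np.sqrt(r * c))
    return Dr2 @ K @ Dc, Dr2, Dc


class ConstrainedSolver:
    """LU factorization of a sparse system with type-I (Dirichlet) dofs
    eliminated.  Keeps the factorization for reuse (adjoint solves use
    ``solve_adjoint``, which applies the transposed factors)."""

    def __init__(self, K: sp.spmatrix, fixed_idx: np.ndarray,
                 equilibrate: bool = True, order_key: np.ndarray | None = None):
        n = K.shape[0]
        self.n = n
        self.fixed_idx = np.asarray(fixed_idx, dtype=np.int64)
        free = np.ones(n, dtype=bool)
        free[self.fixed_idx] = False
        self.free_mask = free
        free_idx = np.nonzero(free)[0]
        if order_key is not None:
            free_idx = free_idx[np.argsort(order_key[free_idx],
                                           kind="stable")]
        self.free_idx = free_idx
        K = K.tocsr()
        self.K_free_cols_fixed = K[self.free_idx][:, self.fixed_idx]
        Kff = K[self.free_idx][:, self.free_idx].tocsc()
        if equilibrate:
            Ks, self._Dr, self._Dc = _equilibrate(Kff)
        else:
            Ks, self._Dr, self._Dc = Kff, None, None
        if order_key is not None:
            kw = dict(permc_spec="NATURAL",
                      options=dict(SymmetricMode=True, DiagPivotThresh=0.01))
        else:
            kw = {}
        try:
            self._lu = splu(Ks.tocsc(), **kw)
        except RuntimeError as err:  # pragma: no cover - exact msg varies
            raise SingularSystemError(
                "constrained system is singular; check that at least one "
                f"type-I (Dirichlet) value anchors every field ({err})")
        self._Kff = Kff

    def _apply(self, rhs, trans):
        if self._Dr is not None:
            if trans == "N":
                y = self._Dr @ rhs
                x = self._lu.solve(y)
                return self._Dc @ x
            # transposed system: (Dr K Dc)^T = Dc^T K^T Dr^T
            y = self._Dc @ rhs
            x = self._lu.solve(y, trans="T")
            return self._Dr @ x
        return self._lu.solve(rhs, trans=trans)

    def solve(self, b: np.ndarray, fixed_vals: np.ndarray,
              check_residual: bool = True) -> np.ndarray:
        b = np.asarray(b, dtype=complex)
        rhs = b[self.free_idx] - self.K_free_cols_fixed @ fixed_vals
        xf = self._apply(rhs, "N")
        if check_residual:
            r = self._Kff @ xf - rhs
            scale = max(np.linalg.norm(rhs), 1e-300)
            if np.linalg.norm(r) > 1e-8 * scale + 1e-250:
                raise SingularSystemError(
                    f"solver residual {np.linalg.norm(r)/scale:.2e} exceeds "
                    "1e-8; system is ill-conditioned or singular")
        x = np.empty(self.n, dtype=complex)
        x[self.free_idx] = xf
        x[self.fixed_idx] = fixed_vals
        return x

    def solve_adjoint(self, rhs_free: np.ndarray) -> np.ndarray:
        """Solve K_ff^T w = rhs on the free dofs; returns a full-length vector
        with zeros on the constrained dofs."""
        wf = self._apply(np.asarray(rhs_free, dtype=complex), "T")
        w = np.zeros(self.n, dtype=complex)
        w[self.free_idx] = wf
        return w


def solve_linear(K: sp.spmatrix, b: np.ndarray, fixed_idx: np.ndarray,
                 fixed_vals: np.ndarray) -> np.ndarray:
    """One-shot constrained solve: eliminate type-I dofs, factorize, verify
    the relative residual (<= 1e-8), and return the full solution with the
    prescribed entries exact."""
    solver = ConstrainedSolver(K, fixed_idx)
    return solver.solve(b, np.asarray(fixed_vals, dtype=complex))
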
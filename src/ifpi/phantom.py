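"""Synthetic single-inclusion poroelastic phantom.

Builds the 6 cm cube with a 3 x 2 x 2 cm stiff inclusion centred at
(3, 3, 4.8) cm, the compression-drive boundary conditions, the material
constants, and the noisy / spatially averaged displacement data consumed by
the estimation pipeline.  Everything is deterministic given the
configuration (and the noise seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json

import numpy as np
import scipy.ndimage as ndi
import yaml

from .fem import Mesh, build_structured_mesh, ConfigurationError


@dataclass
class GlobalParams:
    """Global poroelastic constants.

    rho, rho_f, rho_a are bulk, pore-fluid and apparent densities (kg/m^3);
    phi the porosity; frequency_hz the actuation frequency.  ``omega`` is the
    angular frequency used throughout the equations; by default 1 Hz cyclic
    actuation gives omega = 2*pi rad/s (set ``omega_is_angular`` to read the
    frequency literally as rad/s).
    """

    rho: float = 1000.0
    rho_f: float = 1000.0
    rho_a: float = 150.0
    phi: float = 0.2
    frequency_hz: float = 1.0
    omega_is_angular: bool = False

    def __post_init__(self):
        if not (0.0 < self.phi < 1.0):
            raise ConfigurationError("porosity must satisfy 0 < phi < 1")
        if min(self.rho, self.rho_f, self.rho_a) <= 0:
            raise ConfigurationError("densities must be positive")

    @property
    def omega(self) -> float:
        return self.frequency_hz if self.omega_is_angular \
            else 2.0 * np.pi * self.frequency_hz


@dataclass
class PropertyMap:
    """Nodal material parameters: shear modulus mu (Pa), Lame's first
    parameter lam (Pa), hydraulic conductivity kappa (m^3 s/kg)."""

    mu: np.ndarray
    lam: np.ndarray
    kappa: np.ndarray
    globals: GlobalParams

    def copy(self) -> "PropertyMap":
        return PropertyMap(self.mu.copy(), self.lam.copy(),
                           self.kappa.copy(), self.globals)

    def restrict(self, nodes: np.ndarray) -> "PropertyMap":
        return PropertyMap(self.mu[nodes], self.lam[nodes],
                           self.kappa[nodes], self.globals)


@dataclass
class BoundaryConditionSet:
    """Type-I / type-II data for displacement and pressure.

    disp_nodes carry prescribed complex displacement triplets (disp_mask
    selects which of u, v, w is constrained at those nodes); traction and
    flux data enter as natural boundary terms.  pres_nodes carry type-I
    pressures; ``r0_loads``, when set, are pre-assembled nodal values of the
    surface integral of r0 against each basis function on Gamma_q.
    """

    disp_nodes: np.ndarray
    disp_values: np.ndarray          # (n, 3) complex
    disp_mask: np.ndarray            # (n, 3) bool, True = constrained
    pres_nodes: np.ndarray
    pres_values: np.ndarray          # (n,) complex
    traction: np.ndarray | None = None   # (N, 3) nodal f0 on Gamma_sigma
    r0_loads: np.ndarray | None = None   # (N,) assembled flux loads

    def __post_init__(self):
        if self.r0_loads is not None and np.any(
                np.abs(self.r0_loads[self.pres_nodes]) > 0):
            raise ConfigurationError(
                "a node carries both a type-I pressure and a type-II load")


# Table 1 (two-parameter case) and Table 3 (three-parameter case) values.
MATRIX_PROPS = (3000.0, 4500.0, 1e-7)
INCLUSION_PROPS_TWO = (6000.0, 9000.0, 1e-7)
INCLUSION_PROPS_THREE = (6000.0, 9000.0, 1e-5)
#: inclusion box (meters): 3x2x2 cm centred at (3, 3, 4.8) cm
INCLUSION_BOX = ((0.015, 0.045), (0.02, 0.04), (0.038, 0.058))
PHANTOM_EDGE = 0.06
DRIVE_AMPLITUDE = 1e-4   # 1e-2 cm axial drive on the bottom face


def phantom_bc_layout(mode: str) -> dict:
    """Facet tag layout: top and bottom faces displacement-Dirichlet, side
    faces traction-free; pressure Dirichlet everywhere in 'gfp' mode, flux
    everywhere in 'ifpi' mode (the single-node anchor is node-level)."""
    pres = "dirichlet" if mode == "gfp" else "flux"
    layout = {f: ("traction", pres) for f in ("x-", "x+", "y-", "y+")}
    layout["z-"] = ("dirichlet", pres)
    layout["z+"] = ("dirichlet", pres)
    return layout


def assign_properties(mesh: Mesh, matrix_props, inclusion_box,
                      inclusion_props, globals_: GlobalParams | None = None
                      ) -> PropertyMap:
    """Piecewise-constant nodal property map: nodes whose coordinates fall in
    the closed axis-aligned ``inclusion_box`` get the inclusion values."""
    g = globals_ or GlobalParams()
    mu = np.full(mesh.n_nodes, float(matrix_props[0]))
    lam = np.full(mesh.n_nodes, float(matrix_props[1]))
    kappa = np.full(mesh.n_nodes, float(matrix_props[2]))
    if inclusion_box is not None:
        box = np.asarray(inclusion_box, dtype=float)
        if box.shape != (3, 2):
            raise ConfigurationError("inclusion_box must be ((x0,x1),(y0,y1),(z0,z1))")
        if np.any(box[:, 0] < -1e-12) or np.any(box[:, 1] > mesh.edge_length + 1e-12):
            raise ConfigurationError("inclusion box extends outside the domain")
        tol = 1e-9 * mesh.edge_length
        inside = np.ones(mesh.n_nodes, dtype=bool)
        for a in range(3):
            c = mesh.coords[:, a]
            inside &= (c >= box[a, 0] - tol) & (c <= box[a, 1] + tol)
        mu[inside], lam[inside], kappa[inside] = (float(inclusion_props[0]),
                                                  float(inclusion_props[1]),
                                                  float(inclusion_props[2]))
    return PropertyMap(mu, lam, kappa, g)


def make_boundary_conditions(mesh: Mesh, drive_amplitude: float = DRIVE_AMPLITUDE,
                             mode: str = "gfp") -> BoundaryConditionSet:
    """Compression-drive boundary conditions of the cube phantom.

    Both modes clamp the top face (u = v = w = 0) and drive the bottom face
    axially (u = v = 0, w = drive amplitude); the four side faces are
    traction-free.  In 'gfp' mode p = 0 is prescribed on the entire boundary;
    in 'ifpi' mode only the corner node at the origin is anchored to p = 0
    and every other boundary node awaits estimated type-II flux loads.
    """
    if mode not in ("gfp", "ifpi"):
        raise ConfigurationError(f"unknown boundary-condition mode {mode!r}")
    top = np.nonzero(mesh.face_node_mask("z+"))[0]
    bot = np.nonzero(mesh.face_node_mask("z-"))[0]
    disp_nodes = np.concatenate([top, bot])
    disp_values = np.zeros((disp_nodes.size, 3), dtype=complex)
    disp_values[top.size:, 2] = drive_amplitude
    disp_mask = np.ones((disp_nodes.size, 3), dtype=bool)
    if mode == "gfp":
        pres_nodes = np.nonzero(mesh.boundary_node_mask())[0]
    else:
        pres_nodes = np.array([mesh.node_index(0, 0, 0)])
    pres_values = np.zeros(pres_nodes.size, dtype=complex)
    return BoundaryConditionSet(disp_nodes=disp_nodes, disp_values=disp_values,
                                disp_mask=disp_mask, pres_nodes=pres_nodes,
                                pres_values=pres_values)


def add_noise(u: np.ndarray, percent: float, seed: int) -> np.ndarray:
    """Additive Gaussian displacement noise.

    Independent zero-mean Gaussian noise is added to each of the six real
    scalar components (Re/Im of u, v, w) at every node, with standard
    deviation sigma = (percent/100) x RMS over nodes of the complex
    displacement vector magnitude.  Deterministic given ``seed``.
    """
    if percent < 0:
        raise ValueError("noise percent must be non-negative")
    u = np.asarray(u, dtype=complex)
    if percent == 0:
        return u.copy()
    rms = np.sqrt(np.mean(np.sum(np.abs(u) ** 2, axis=1)))
    sigma = (percent / 100.0) * rms
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=u.shape) \
        + 1j * rng.normal(0.0, sigma, size=u.shape)
    return u + noise


def spatial_average(u: np.ndarray, mesh: Mesh) -> np.ndarray:
    """3x3x3 boxcar mean of each displacement component, truncated at the
    boundary (boundary nodes average over their existing neighbours)."""
    nx, ny, nz = mesh.shape
    out = np.empty_like(np.asarray(u, dtype=complex))
    ones = np.ones((nx, ny, nz))
    norm = ndi.uniform_filter(ones, size=3, mode="constant", cval=0.0)
    for c in range(u.shape[1]):
        # grid order: index = ix + nx*(iy + ny*iz) -> reshape as (iz, iy, ix)
        grid = u[:, c].reshape(nz, ny, nx)
        sm_r = ndi.uniform_filter(grid.real, size=3, mode="constant", cval=0.0)
        sm_i = ndi.uniform_filter(grid.imag, size=3, mode="constant", cval=0.0)
        normg = norm.reshape(nz, ny, nx) if norm.shape != (nz, ny, nx) else norm
        out[:, c] = ((sm_r + 1j * sm_i) / normg).ravel()
    return out


@dataclass
class PhantomConfig:
    """Full description of a synthetic experiment; the YAML schema of the
    command-line tools mirrors these fields."""

    edge_length: float = PHANTOM_EDGE
    nodes_per_axis: int = 21
    matrix_props: tuple = MATRIX_PROPS
    inclusion_props: tuple = INCLUSION_PROPS_TWO
    inclusion_box: tuple | None = INCLUSION_BOX
    drive_amplitude: float = DRIVE_AMPLITUDE
    noise_percent: float = 0.0
    noise_seed: int = 0
    spatially_averaged: bool = False
    globals: GlobalParams = field(default_factory=GlobalParams)

    @classmethod
    def two_parameter(cls, **kw) -> "PhantomConfig":
        return cls(inclusion_props=INCLUSION_PROPS_TWO, **kw)

    @classmethod
    def three_parameter(cls, **kw) -> "PhantomConfig":
        return cls(inclusion_props=INCLUSION_PROPS_THREE, **kw)

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        g = GlobalParams(**raw.pop("globals", {}))
        for key in ("matrix_props", "inclusion_props"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("inclusion_box") is not None and "inclusion_box" in raw:
            raw["inclusion_box"] = tuple(tuple(b) for b in raw["inclusion_box"])
        return cls(globals=g, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def build_mesh(self, mode: str = "gfp") -> Mesh:
        return build_structured_mesh(self.edge_length, self.nodes_per_axis,
                                     phantom_bc_layout(mode))

    def build_properties(self, mesh: Mesh) -> PropertyMap:
        return assign_properties(mesh, self.matrix_props, self.inclusion_box,
                                 self.inclusion_props, self.globals)

    def build_bcs(self, mesh: Mesh, mode: str = "gfp") -> BoundaryConditionSet:
        return make_boundary_conditions(mesh, self.drive_amplitude, mode)
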
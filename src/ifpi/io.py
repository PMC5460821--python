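"""HDF5 serialization and legacy-VTK export of meshes and complex fields.

HDF5 round-trips are lossless (complex fields stored as real/imag pairs).
The VTK writer emits legacy ASCII unstructured-grid files readable by
ParaView and friends, with one point array per real/imaginary field
component for slice visualization.
"""
from __future__ import annotations

import numpy as np
import h5py

from .fem import Mesh, build_structured_mesh


def save_mesh(group: h5py.Group, mesh: Mesh) -> None:
    group.attrs["edge_length"] = mesh.edge_length
    group.attrs["nodes_per_axis"] = mesh.shape[0]
    group.create_dataset("coordinates", data=mesh.coords)
    group.create_dataset("connectivity", data=mesh.elements)
    group.create_dataset("facet_nodes", data=mesh.facet_nodes)
    str_dt = h5py.string_dtype()
    group.create_dataset("facet_disp_tag", data=mesh.facet_disp_tag.astype(object), dtype=str_dt)
    group.create_dataset("facet_pres_tag", data=mesh.facet_pres_tag.astype(object), dtype=str_dt)
    group.create_dataset("facet_face", data=mesh.facet_face.astype(object), dtype=str_dt)


def load_mesh(group: h5py.Group) -> Mesh:
    n = int(group.attrs["nodes_per_axis"])
    edge = float(group.attrs["edge_length"])
    faces = [f.decode() if isinstance(f, bytes) else f
             for f in group["facet_face"][:]]
    dts = [f.decode() if isinstance(f, bytes) else f
           for f in group["facet_disp_tag"][:]]
    pts = [f.decode() if isinstance(f, bytes) else f
           for f in group["facet_pres_tag"][:]]
    layout = {}
    for f, d, p in zip(faces, dts, pts):
        layout[f] = (d, p)
    mesh = build_structured_mesh(edge, n, layout)
    return mesh


def save_field(group: h5py.Group, name: str, field: np.ndarray) -> None:
    field = np.asarray(field)
    if np.iscomplexobj(field):
        group.create_dataset(f"{name}_real", data=field.real)
        group.create_dataset(f"{name}_imag", data=field.imag)
    else:
        group.create_dataset(name, data=field)


def load_field(group: h5py.Group, name: str) -> np.ndarray:
    if f"{name}_real" in group:
        return group[f"{name}_real"][:] + 1j * group[f"{name}_imag"][:]
    return group[name][:]


def export_fields(path, mesh: Mesh, fields: dict, fmt: str = "h5") -> None:
    """Write a mesh plus named nodal fields. ``fmt`` is 'h5' or 'vtk'."""
    if fmt == "h5":
        with h5py.File(path, "w") as fh:
            save_mesh(fh.create_group("mesh"), mesh)
            fg = fh.create_group("fields")
            for name, field in fields.items():
                save_field(fg, name, field)
    elif fmt == "vtk":
        write_vtk(path, mesh, fields)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_fields(path):
    with h5py.File(path, "r") as fh:
        mesh = load_mesh(fh["mesh"])
        fg = fh["fields"]
        names = set()
        for key in fg:
            if key.endswith("_real") or key.endswith("_imag"):
                names.add(key[:-5])
            else:
                names.add(key)
        fields = {name: load_field(fg, name) for name in names}
    return mesh, fields


def _point_arrays(fields: dict) -> dict:
    """Flatten complex / vector fields into named real scalar point arrays."""
    out = {}
    for name, field in fields.items():
        field = np.asarray(field)
        comps = ("x", "y", "z")
        if field.ndim == 1:
            if np.iscomplexobj(field):
                out[f"Re_{name}"] = field.real
                out[f"Im_{name}"] = field.imag
            else:
                out[name] = field.astype(float)
        else:
            for c in range(field.shape[1]):
                base = f"{name}_{comps[c]}" if field.shape[1] <= 3 else f"{name}_{c}"
                if np.iscomplexobj(field):
                    out[f"Re_{base}"] = field[:, c].real
                    out[f"Im_{base}"] = field[:, c].imag
                else:
                    out[base] = field[:, c].astype(float)
    return out


def write_vtk(path, mesh: Mesh, fields: dict) -> None:
    """Legacy ASCII VTK unstructured grid (cell type 12 = hexahedron)."""
    arrays = _point_arrays(fields)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("poroelastic MRE fields\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.coords, fmt="%.9e")
        E = mesh.n_elements
        fh.write(f"CELLS {E} {E * 9}\n")
        cells = np.column_stack([np.full(E, 8), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {E}\n")
        np.savetxt(fh, np.full(E, 12), fmt="%d")
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, arr in arrays.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.9e")
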
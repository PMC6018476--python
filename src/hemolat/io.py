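"""Snapshot and geometry export: HDF5, legacy-VTK ASCII, plane tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import VesselGeometry

__all__ = [
    "write_field_h5",
    "write_geometry_h5",
    "write_vtk_image",
    "write_plane_table",
    "read_plane_table",
]


def write_field_h5(path, name: str, field: np.ndarray, unit, time: float = 0.0):
    """Write one voxel field to HDF5 with dx/dt/origin metadata."""
    import h5py

    with h5py.File(path, "a") as h5:
        ds = h5.create_dataset(name, data=field)
        ds.attrs["dx"] = unit.dx
        ds.attrs["dt"] = unit.dt
        ds.attrs["rho_ref"] = unit.rho_ref
        ds.attrs["time"] = time


def write_geometry_h5(path, geometry: VesselGeometry):
    """Write mask, wall links and the plane table to HDF5."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("fluid_mask", data=geometry.fluid_mask)
        h5.attrs["dx"] = geometry.unit.dx
        h5.attrs["dt"] = geometry.unit.dt
        h5.attrs["origin"] = geometry.origin
        g = h5.create_group("links")
        g.create_dataset("site", data=geometry.link_site)
        g.create_dataset("direction", data=geometry.link_dir)
        g.create_dataset("kind", data=geometry.link_kind)
        g.create_dataset("plane", data=geometry.link_plane)
        g.create_dataset("q", data=geometry.link_q)
        pt = h5.create_group("planes")
        for n, p in enumerate(geometry.planes):
            sub = pt.create_group(str(n))
            sub.attrs["label"] = p.label
            sub.attrs["role"] = p.role
            sub.create_dataset("location", data=p.location)
            sub.create_dataset("normal", data=p.normal)


def write_vtk_image(path, fields: dict, origin, spacing: float):
    """Write scalar/vector voxel fields as legacy-VTK ASCII STRUCTURED_POINTS.

    ``fields`` maps name -> array of shape (nx, ny, nz) or (3, nx, ny, nz).
    NaN (non-fluid) entries are written as 0 with a companion ``<name>_mask``
    scalar when present in the data.
    """
    shapes = {v.shape[-3:] for v in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share the same grid shape")
    nx, ny, nz = shapes.pop()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhemolat field snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            clean = np.nan_to_num(np.asarray(arr, dtype=np.float64))
            if clean.ndim == 3:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                flat = clean.transpose(2, 1, 0).ravel()  # VTK is x-fastest
                np.savetxt(fh, flat[:, None], fmt="%.9g")
            elif clean.ndim == 4 and clean.shape[0] == 3:
                fh.write(f"VECTORS {name} double\n")
                vec = clean.transpose(3, 2, 1, 0).reshape(-1, 3)
                np.savetxt(fh, vec, fmt="%.9g")
            else:
                raise ValueError(f"field {name!r} has unsupported shape {arr.shape}")


def write_plane_table(path, geometry: VesselGeometry):
    """Delimited plane table: label, role, location, normal."""
    rows = [
        {
            "label": p.label,
            "role": p.role,
            "x": p.location[0],
            "y": p.location[1],
            "z": p.location[2],
            "nx": p.normal[0],
            "ny": p.normal[1],
            "nz": p.normal[2],
        }
        for p in geometry.planes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_plane_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"label", "role", "x", "y", "z", "nx", "ny", "nz"}
    if not required.issubset(df.columns):
        raise ValueError(f"plane table must contain columns {sorted(required)}")
    return df
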
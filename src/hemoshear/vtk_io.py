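"""Deterministic legacy-VTK (ASCII) writers for masks and field snapshots.

Structured-points datasets: the cell mask as a scalar on the cell grid, and
velocity/pressure snapshots interpolated to cell centres.  Floats are
written at fixed precision so identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .meshing import Mesh, Region
from .solver import FlowField

__all__ = ["write_mask_vtk", "write_field_vtk", "write_wall_vtk"]

_FMT = "%.9e"


def _header(f, title: str, nx: int, ny: int, spacing: float) -> None:
    f.write("# vtk DataFile Version 3.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\n")
    f.write("DATASET STRUCTURED_POINTS\n")
    f.write(f"DIMENSIONS {nx} {ny} 1\n")
    f.write(f"ORIGIN {spacing / 2.0:.9e} {spacing / 2.0:.9e} 0.0\n")
    f.write(f"SPACING {spacing:.9e} {spacing:.9e} 1.0\n")


def write_mask_vtk(mesh: Mesh, path: str | Path) -> None:
    """Cell mask (0 solid, 1 parent fluid, 2 sac fluid) as point scalars."""
    code = np.zeros((mesh.nx, mesh.ny), dtype=int)
    code[mesh.fluid_mask] = 1
    code[:, mesh.ny_parent:][mesh.fluid_mask[:, mesh.ny_parent:]] = 2
    with open(path, "w") as f:
        _header(f, "hemoshear cell mask", mesh.nx, mesh.ny, mesh.cell_size)
        f.write(f"POINT_DATA {mesh.nx * mesh.ny}\n")
        f.write("SCALARS mask int 1\nLOOKUP_TABLE default\n")
        for j in range(mesh.ny):
            f.write(" ".join(str(int(code[i, j])) for i in range(mesh.nx)) + "\n")


def write_field_vtk(field: FlowField, snapshot: int, path: str | Path) -> None:
    """One snapshot: cell-centred velocity vectors and pressure scalars."""
    mesh = field.mesh
    nx, ny = mesh.nx, mesh.ny
    uc = 0.5 * (field.u[snapshot, :-1, :] + field.u[snapshot, 1:, :])
    vc = 0.5 * (field.v[snapshot, :, :-1] + field.v[snapshot, :, 1:])
    p = field.p[snapshot]
    with open(path, "w") as f:
        _header(f, f"hemoshear flow t={field.times[snapshot]:.6f}s", nx, ny, mesh.cell_size)
        f.write(f"POINT_DATA {nx * ny}\n")
        f.write("VECTORS velocity float\n")
        for j in range(ny):
            for i in range(nx):
                f.write(f"{uc[i, j]:.9e} {vc[i, j]:.9e} 0.0\n")
        f.write("SCALARS pressure float 1\nLOOKUP_TABLE default\n")
        for j in range(ny):
            f.write(" ".join(_FMT % p[i, j] for i in range(nx)) + "\n")


def write_wall_vtk(mesh: Mesh, values: np.ndarray, name: str, path: str | Path) -> None:
    """Wall-element scalars (e.g. time-averaged WSS) as a VTK polyline cloud."""
    centers = mesh.wall_face_centers()
    n = len(centers)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"hemoshear wall {name}\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {n} float\n")
        for x, y in centers:
            f.write(f"{x:.9e} {y:.9e} 0.0\n")
        f.write(f"POINT_DATA {n}\n")
        f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        for v in values:
            f.write(_FMT % v + "\n")
        f.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        for r in mesh.wall_region:
            f.write(str(int(r)) + "\n")
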
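"""Cartesian masked meshes for the channel + sac domain.

The flow domain is discretized on a uniform Cartesian grid with square cells
of side ``cell_size`` (mm).  Cells are either fluid or solid (masked); the
sac is represented by the staircase of cells whose centres fall inside the
sac polygon.  The parent walls are grid-aligned — ``build_mesh`` snaps the
cell size to an integer divisor of the parent caliber — so wall-shear
extraction on the parent is free of staircase error.

Wall elements are (fluid cell, outward face) pairs.  Each carries an
arc-length weight in mm: parent-wall faces weigh one cell side, while sac
faces receive the true sac-polyline arc length redistributed to the nearest
face, so the summed sac weight converges to the exact boundary length
rather than to the inflated Manhattan staircase length.

Regions partition the wall: ``sac`` (the aneurysm wall), ``parent_probe``
(the reference segment on the sac-bearing wall, nominally centred 10 mm
upstream of the neck) and ``other``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon
from scipy.spatial import cKDTree

from .geometry import AneurysmGeometry, GeometryError, ParameterError

__all__ = [
    "Face",
    "Region",
    "Mesh",
    "build_mesh",
    "build_channel_mesh",
    "locate_parent_probe",
]

#: resolution floor: at least this many cells across the parent caliber
MIN_CELLS_ACROSS = 8


class Face(IntEnum):
    """Outward face of a fluid cell (direction of the adjacent solid)."""

    N = 0
    S = 1
    E = 2
    W = 3


_FACE_DXY = {Face.N: (0, 1), Face.S: (0, -1), Face.E: (1, 0), Face.W: (-1, 0)}


class Region(IntEnum):
    OTHER = 0
    SAC = 1
    PARENT_PROBE = 2


@dataclass
class Mesh:
    """Masked Cartesian mesh with tagged wall elements.

    ``fluid_mask`` is indexed ``[i, j]`` (x-column, y-row).  The parent
    lumen occupies rows ``0 .. ny_parent-1``; the sac sits above row
    ``ny_parent - 1`` on the y = parent caliber wall.
    """

    cell_size: float  # mm
    nx: int
    ny: int
    ny_parent: int
    fluid_mask: np.ndarray  # bool (nx, ny)
    wall_cell: np.ndarray  # int (n_wall, 2) fluid-cell indices
    wall_face: np.ndarray  # int (n_wall,) Face codes
    wall_weight: np.ndarray  # float (n_wall,) arc-length weight, mm
    wall_region: np.ndarray  # int (n_wall,) Region codes
    inlet_rows: np.ndarray  # fluid rows j at i = 0
    outlet_rows: np.ndarray  # fluid rows j at i = nx - 1
    geometry: AneurysmGeometry | None = None

    @property
    def n_wall(self) -> int:
        return len(self.wall_face)

    def wall_face_centers(self) -> np.ndarray:
        """(n_wall, 2) wall face-centre coordinates in mm."""
        c = self.cell_size
        centers = (self.wall_cell + 0.5) * c
        for f, (dx, dy) in _FACE_DXY.items():
            sel = self.wall_face == int(f)
            centers[sel, 0] += dx * c / 2.0
            centers[sel, 1] += dy * c / 2.0
        return centers

    def region_weight(self, region: Region) -> float:
        return float(self.wall_weight[self.wall_region == int(region)].sum())


def _snap_cell_size(caliber: float, cell_size: float) -> tuple[float, int]:
    if cell_size > caliber / MIN_CELLS_ACROSS + 1e-12:
        raise ParameterError(
            f"cell_size {cell_size:g} mm too coarse: need <= parent_caliber/"
            f"{MIN_CELLS_ACROSS} = {caliber / MIN_CELLS_ACROSS:g} mm"
        )
    n_par = round(caliber / cell_size)
    return caliber / n_par, n_par


def build_channel_mesh(length: float, caliber: float, cell_size: float) -> Mesh:
    """Mesh a straight channel (no sac): used by the solver validation cases."""
    cell, n_par = _snap_cell_size(caliber, cell_size)
    nx = max(round(length / cell), 2)
    ny = n_par
    fluid = np.ones((nx, ny), dtype=bool)
    cells, faces = [], []
    for i in range(nx):
        cells += [(i, 0), (i, ny - 1)]
        faces += [int(Face.S), int(Face.N)]
    wall_cell = np.array(cells, dtype=int)
    wall_face = np.array(faces, dtype=int)
    rows = np.arange(ny)
    return Mesh(
        cell_size=cell,
        nx=nx,
        ny=ny,
        ny_parent=n_par,
        fluid_mask=fluid,
        wall_cell=wall_cell,
        wall_face=wall_face,
        wall_weight=np.full(len(faces), cell),
        wall_region=np.zeros(len(faces), dtype=int),
        inlet_rows=rows.copy(),
        outlet_rows=rows.copy(),
        geometry=None,
    )


def build_mesh(
    geom: AneurysmGeometry,
    cell_size: float,
    probe_distance: float = 10.0,
    probe_extent: float = 2.0,
    probe_side: str = "upstream",
) -> Mesh:
    """Discretize an aneurysm geometry onto the masked grid.

    Deterministic for fixed inputs.  The parent probe is tagged immediately
    (see :func:`locate_parent_probe` for the rules and options).
    """
    cell, n_par = _snap_cell_size(geom.parent_caliber, cell_size)
    nx = round(geom.parent_length / cell)
    sac_top = float(geom.sac_boundary[:, 1].max())
    ny = n_par + max(math.ceil((sac_top - geom.parent_caliber) / cell - 1e-12), 1)

    fluid = np.zeros((nx, ny), dtype=bool)
    fluid[:, :n_par] = True

    # sac polygon: boundary polyline closed along the wall
    poly = Polygon(geom.sac_boundary)
    ii, jj = np.meshgrid(np.arange(nx), np.arange(n_par, ny), indexing="ij")
    cx = (ii + 0.5) * cell
    cy = (jj + 0.5) * cell
    inside = shapely.contains_xy(poly, cx.ravel(), cy.ravel()).reshape(cx.shape)
    fluid[:, n_par:] = inside

    _check_connected(fluid)

    cells, faces = [], []
    solid = ~fluid
    for f, (dx, dy) in _FACE_DXY.items():
        fi, fj = np.nonzero(fluid)
        ni, nj = fi + dx, fj + dy
        out = (ni < 0) | (ni >= nx) | (nj < 0) | (nj >= ny)
        neigh_solid = out.copy()
        ok = ~out
        neigh_solid[ok] = solid[ni[ok], nj[ok]]
        # inlet/outlet faces are not walls
        if f is Face.W:
            neigh_solid &= ~((fi == 0) & (fj < n_par))
        if f is Face.E:
            neigh_solid &= ~((fi == nx - 1) & (fj < n_par))
        for a, b in zip(fi[neigh_solid], fj[neigh_solid]):
            cells.append((a, b))
            faces.append(int(f))
    wall_cell = np.array(cells, dtype=int)
    wall_face = np.array(faces, dtype=int)
    # canonical deterministic ordering
    order = np.lexsort((wall_face, wall_cell[:, 1], wall_cell[:, 0]))
    wall_cell, wall_face = wall_cell[order], wall_face[order]

    region = np.zeros(len(wall_face), dtype=int)
    x_lo, x_hi = geom.neck_center - geom.neck_width / 2, geom.neck_center + geom.neck_width / 2
    is_sac = wall_cell[:, 1] >= n_par
    # staircase corners: top-wall parent faces strictly under the neck opening
    face_x = (wall_cell[:, 0] + 0.5) * cell
    under_neck = (
        (wall_cell[:, 1] == n_par - 1)
        & (wall_face == int(Face.N))
        & (face_x > x_lo)
        & (face_x < x_hi)
    )
    region[is_sac | under_neck] = int(Region.SAC)

    weight = np.full(len(wall_face), cell, dtype=float)
    mesh = Mesh(
        cell_size=cell,
        nx=nx,
        ny=ny,
        ny_parent=n_par,
        fluid_mask=fluid,
        wall_cell=wall_cell,
        wall_face=wall_face,
        wall_weight=weight,
        wall_region=region,
        inlet_rows=np.arange(n_par),
        outlet_rows=np.arange(n_par),
        geometry=geom,
    )
    _assign_sac_weights(mesh, geom)
    return locate_parent_probe(mesh, geom, probe_distance, probe_extent, probe_side)


def _check_connected(fluid: np.ndarray) -> None:
    """4-connectivity flood fill from the inlet column; all fluid reachable."""
    from collections import deque

    nx, ny = fluid.shape
    seen = np.zeros_like(fluid)
    q = deque((0, j) for j in range(ny) if fluid[0, j])
    for i, j in q:
        seen[i, j] = True
    while q:
        i, j = q.popleft()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny and fluid[a, b] and not seen[a, b]:
                seen[a, b] = True
                q.append((a, b))
    if not np.array_equal(seen, fluid):
        raise GeometryError("fluid region is not 4-connected from the inlet")


def _assign_sac_weights(mesh: Mesh, geom: AneurysmGeometry) -> None:
    """Redistribute the exact sac arc length onto the sac wall faces."""
    sac_sel = mesh.wall_region == int(Region.SAC)
    if not sac_sel.any():
        raise GeometryError("no sac wall elements found (sac unresolved at this cell size)")
    centers = mesh.wall_face_centers()[sac_sel]
    tree = cKDTree(centers)
    line = LineString(geom.sac_boundary)
    n_samp = max(20 * len(centers), 2000)
    s = np.linspace(0.0, line.length, n_samp + 1)
    pts = np.array([line.interpolate(v).coords[0] for v in s])
    mids = 0.5 * (pts[:-1] + pts[1:])
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    _, nearest = tree.query(mids)
    w = np.bincount(nearest, weights=seg_len, minlength=len(centers))
    idx = np.nonzero(sac_sel)[0]
    mesh.wall_weight[idx] = w


def locate_parent_probe(
    mesh: Mesh,
    geom: AneurysmGeometry,
    probe_distance: float = 10.0,
    probe_extent: float = 2.0,
    side: str = "upstream",
) -> Mesh:
    """Tag the parent reference segment on the sac-bearing wall.

    The probe is centred ``probe_distance`` mm (default 10, i.e. 1.0 cm)
    from the nearer neck endpoint, on the upstream side by default;
    ``side`` may be ``"upstream"``, ``"downstream"`` or ``"both"``.
    """
    if side not in ("upstream", "downstream", "both"):
        raise ParameterError(f"unknown probe side {side!r}")
    cell = mesh.cell_size
    x_lo = geom.neck_center - geom.neck_width / 2.0
    x_hi = geom.neck_center + geom.neck_width / 2.0
    spans = []
    if side in ("upstream", "both"):
        c = x_lo - probe_distance
        if c - probe_extent / 2.0 < 0:
            raise ParameterError(
                f"parent too short upstream: probe centre at x={c:.3g} mm "
                f"needs {probe_extent / 2.0:g} mm clearance"
            )
        spans.append((c - probe_extent / 2.0, c + probe_extent / 2.0))
    if side in ("downstream", "both"):
        c = x_hi + probe_distance
        if c + probe_extent / 2.0 > geom.parent_length:
            raise ParameterError(
                f"parent too short downstream: probe centre at x={c:.3g} mm "
                f"exceeds parent_length {geom.parent_length:g} mm"
            )
        spans.append((c - probe_extent / 2.0, c + probe_extent / 2.0))

    region = mesh.wall_region.copy()
    region[region == int(Region.PARENT_PROBE)] = int(Region.OTHER)
    face_x = (mesh.wall_cell[:, 0] + 0.5) * cell
    top_wall = (
        (mesh.wall_cell[:, 1] == mesh.ny_parent - 1)
        & (mesh.wall_face == int(Face.N))
        & (region == int(Region.OTHER))
    )
    tagged = np.zeros(len(region), dtype=bool)
    for a, b in spans:
        tagged |= top_wall & (face_x >= a - 1e-12) & (face_x <= b + 1e-12)
    if not tagged.any():
        raise ParameterError("probe segment contains no wall faces at this cell size")
    region[tagged] = int(Region.PARENT_PROBE)
    return replace(mesh, wall_region=region)
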
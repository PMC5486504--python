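"""Parametric idealized sidewall-aneurysm geometries and 2-D morphometry.

An aneurysm is modelled as a planar sac attached to one wall of a straight
parent channel.  The parent lumen occupies ``y in [0, parent_caliber]`` with
the wall carrying the sac at ``y = parent_caliber``; the sac boundary is an
ordered polyline running from one neck endpoint to the other, strictly
outside the lumen except at the neck.  All lengths are millimetres.

Two shape families are provided:

* ``hemispherical-bump`` — a half-disc sitting on the wall.  The neck is the
  full sac diameter, so the aspect ratio is 0.5: the canonical shallow,
  wide-necked sac.
* ``circular-sac-with-neck`` — a circular sac whose centre is lifted off the
  wall, joined to a constricted neck by the two outer tangent lines
  (a "flask" profile).  Raising the offset or shrinking the neck drives the
  aspect ratio up, giving deep narrow-necked sacs.

Morphometry follows the clinical 2-D convention: height is the maximum
distance from the neck centre to the dome, neck width is measured parallel
to the parent artery, and the aspect ratio (AR) is height/neck.  Sacs are
classified narrow-necked when AR >= 1.4 and the neck is under 4 mm; a neck
of 4 mm or more forces the wide-necked class regardless of AR.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from shapely.geometry import LineString

__all__ = [
    "ShapeFamily",
    "NeckCategory",
    "AneurysmGeometry",
    "MorphologyMeasures",
    "GeometryError",
    "ParameterError",
    "make_geometry",
    "measure_morphology",
    "classify_neck",
    "geometry_to_json",
    "geometry_from_json",
    "boundary_to_csv",
    "boundary_from_csv",
]

#: aspect-ratio cutoff separating narrow- from wide-necked sacs
AR_NARROW_CUTOFF = 1.4
#: absolute neck-width cutoff (mm) above which a sac is wide-necked
NECK_WIDE_MM = 4.0

_ENDPOINT_TOL = 1e-9


class ParameterError(ValueError):
    """Infeasible geometry parameters; the message names the violated constraint."""


class GeometryError(ValueError):
    """A constructed or supplied geometry violates its invariants."""


class ShapeFamily(str, Enum):
    HEMISPHERICAL_BUMP = "hemispherical-bump"
    CIRCULAR_SAC_WITH_NECK = "circular-sac-with-neck"


class NeckCategory(str, Enum):
    NARROW = "narrow"
    WIDE = "wide"


@dataclass(frozen=True)
class AneurysmGeometry:
    """Planar sidewall-aneurysm geometry in mm.

    Attributes
    ----------
    parent_length, parent_caliber
        Length and height of the straight parent channel (mm).
    neck_center
        x-position of the neck midpoint on the sac-bearing wall (mm).
    neck_width
        Neck opening width along the wall (mm).
    sac_boundary
        ``(n, 2)`` array of (x, y) points from the upstream neck endpoint to
        the downstream one, outside the lumen except at its endpoints.
    shape_family
        Construction family tag.
    """

    parent_length: float
    parent_caliber: float
    neck_center: float
    neck_width: float
    sac_boundary: np.ndarray
    shape_family: ShapeFamily

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sac_boundary", np.asarray(self.sac_boundary, dtype=float)
        )
        self.validate()

    @property
    def neck_endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        h = self.parent_caliber
        return (
            (self.neck_center - self.neck_width / 2.0, h),
            (self.neck_center + self.neck_width / 2.0, h),
        )

    def validate(self) -> None:
        if self.neck_width <= 0:
            raise ParameterError("neck_width must be > 0")
        if self.parent_caliber <= 0:
            raise ParameterError("parent_caliber must be > 0")
        b = self.sac_boundary
        if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 3:
            raise GeometryError("sac_boundary must be an (n>=3, 2) polyline")
        (e1, e2) = self.neck_endpoints
        if not (
            math.dist(b[0], e1) <= _ENDPOINT_TOL and math.dist(b[-1], e2) <= _ENDPOINT_TOL
        ):
            raise GeometryError(
                "sac_boundary endpoints must coincide with the neck endpoints"
            )
        if np.any(b[1:-1, 1] < self.parent_caliber - _ENDPOINT_TOL):
            raise GeometryError("sac_boundary must lie outside the parent lumen")
        if not LineString(b).is_simple:
            raise GeometryError("sac_boundary is self-intersecting")
        # parent must leave room for the 10 mm upstream sampling site
        neck_hi = self.neck_center + self.neck_width / 2.0
        if self.parent_length < 10.0 + neck_hi:
            raise ParameterError(
                "parent_length must be >= 10 mm + neck extent "
                f"(need >= {10.0 + neck_hi:.3g} mm, got {self.parent_length:.3g})"
            )


@dataclass(frozen=True)
class MorphologyMeasures:
    """Clinical 2-D measurements of one sac (mm; aspect_ratio dimensionless)."""

    height: float
    neck_width: float
    aspect_ratio: float
    dome_measure: float
    neck_category: NeckCategory = field(init=False)

    def __post_init__(self) -> None:
        if self.height <= 0 or self.dome_measure <= 0:
            raise GeometryError("height and dome_measure must be > 0")
        if not math.isclose(self.aspect_ratio, self.height / self.neck_width):
            raise GeometryError("aspect_ratio must equal height / neck_width")
        object.__setattr__(self, "neck_category", classify_neck(self))


def classify_neck(m: "MorphologyMeasures | tuple[float, float]") -> NeckCategory:
    """Classify a sac as narrow- or wide-necked.

    Narrow iff aspect ratio >= 1.4 **and** neck width < 4 mm; a neck of
    4 mm or more overrides the aspect ratio and forces the wide class
    (the standard clinical wide-neck convention).

    Accepts either a :class:`MorphologyMeasures` or an ``(aspect_ratio,
    neck_width_mm)`` pair.
    """
    if isinstance(m, MorphologyMeasures):
        ar, neck = m.aspect_ratio, m.neck_width
    else:
        ar, neck = m
    if ar >= AR_NARROW_CUTOFF and neck < NECK_WIDE_MM:
        return NeckCategory.NARROW
    return NeckCategory.WIDE


def make_geometry(
    shape_family: ShapeFamily | str,
    parent_caliber: float,
    neck_width: float | None = None,
    sac_size: float = 2.0,
    sac_offset: float = 0.0,
    resolution: int = 200,
    parent_length: float | None = None,
    neck_center: float | None = None,
) -> AneurysmGeometry:
    """Construct a parametric sidewall-aneurysm geometry.

    Parameters
    ----------
    shape_family
        ``hemispherical-bump`` or ``circular-sac-with-neck``.
    parent_caliber
        Parent channel height (mm), the 2-D stand-in for vessel diameter.
    neck_width
        Neck opening (mm).  Ignored for the bump family, whose neck is the
        sac diameter ``2 * sac_size``.
    sac_size
        Sac radius (mm).
    sac_offset
        Height of the sac-circle centre above the wall (mm); flask family
        only.
    resolution
        Number of points in the sac boundary polyline.
    parent_length, neck_center
        Channel length and neck midpoint position (mm); defaults place the
        neck so that 13 mm of parent wall lie upstream of the neck.
    """
    family = ShapeFamily(shape_family)
    if parent_caliber <= 0 or sac_size <= 0:
        raise ParameterError("parent_caliber and sac_size must be > 0")
    if resolution < 8:
        raise ParameterError("resolution must be >= 8 boundary points")

    if family is ShapeFamily.HEMISPHERICAL_BUMP:
        neck_width = 2.0 * sac_size
    else:
        if neck_width is None or neck_width <= 0:
            raise ParameterError("neck_width must be > 0")
        if neck_width >= 2.0 * sac_size:
            raise ParameterError(
                f"neck_width ({neck_width} mm) must be smaller than the sac "
                f"diameter ({2.0 * sac_size} mm)"
            )
        if sac_offset < 0:
            raise ParameterError("sac_offset must be >= 0")

    if neck_center is None:
        neck_center = 13.0 + neck_width / 2.0
    if parent_length is None:
        parent_length = neck_center + neck_width / 2.0 + 13.0

    xm, h = neck_center, parent_caliber
    if xm - neck_width / 2.0 <= 0 or xm + neck_width / 2.0 >= parent_length:
        raise ParameterError("sac neck overlaps the inlet or outlet boundary")

    if family is ShapeFamily.HEMISPHERICAL_BUMP:
        theta = np.linspace(math.pi, 0.0, resolution)
        pts = np.column_stack(
            [xm + sac_size * np.cos(theta), h + sac_size * np.sin(theta)]
        )
    else:
        pts = _flask_boundary(xm, h, neck_width, sac_size, sac_offset, resolution)

    # snap endpoints exactly onto the neck
    pts[0] = (xm - neck_width / 2.0, h)
    pts[-1] = (xm + neck_width / 2.0, h)
    return AneurysmGeometry(
        parent_length=parent_length,
        parent_caliber=parent_caliber,
        neck_center=xm,
        neck_width=neck_width,
        sac_boundary=pts,
        shape_family=family,
    )


def _flask_boundary(
    xm: float, h: float, neck: float, r: float, d: float, resolution: int
) -> np.ndarray:
    """Flask profile: neck endpoints joined by outer tangents to a lifted circle."""
    cx, cy = xm, h + d
    e1 = np.array([xm - neck / 2.0, h])
    ec = math.dist(e1, (cx, cy))
    if ec <= r:
        raise ParameterError(
            "neck endpoints lie inside the sac circle; increase sac_offset or "
            "neck_width (need sqrt((neck/2)^2 + offset^2) > sac radius)"
        )
    # angle of the left tangent point, measured at the circle centre
    beta = math.atan2(e1[1] - cy, e1[0] - cx)  # direction centre -> endpoint
    gamma = math.acos(r / ec)
    # outer tangent: rotate clockwise from the endpoint direction so the
    # boundary bulges outward; normalized angle lands in (pi/2, 3*pi/2)
    t_left = (beta - gamma) % (2.0 * math.pi)
    t_right = math.pi - t_left  # mirror symmetry about x = xm
    # arc sweeps from the left tangent point over the dome top to the right one
    n_arc = max(resolution - 4, 8)
    ang = np.linspace(t_left, t_right, n_arc)
    arc = np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])
    p_left = arc[0]
    p_right = arc[-1]
    left_seg = np.linspace(e1, p_left, 3)[:-1]
    right_seg = np.linspace(p_right, [xm + neck / 2.0, h], 3)[1:]
    return np.vstack([left_seg, arc, right_seg])


def measure_morphology(geom: AneurysmGeometry) -> MorphologyMeasures:
    """Measure height, neck width, aspect ratio and dome arc length.

    Height is the maximum distance from the neck centre to any dome point
    (the clinical 2-D definition); the dome measure is the sac boundary arc
    length, the planar stand-in for dome area.
    """
    b = geom.sac_boundary
    if b.shape[0] < 3:
        raise GeometryError("degenerate sac boundary (<3 points)")
    neck_mid = np.array([geom.neck_center, geom.parent_caliber])
    height = float(np.max(np.linalg.norm(b - neck_mid, axis=1)))
    arc = float(np.sum(np.linalg.norm(np.diff(b, axis=0), axis=1)))
    return MorphologyMeasures(
        height=height,
        neck_width=geom.neck_width,
        aspect_ratio=height / geom.neck_width,
        dome_measure=arc,
    )


# ---------------------------------------------------------------------------
# serialization: JSON (parameter form) and CSV polyline, both lossless

def geometry_to_json(geom: AneurysmGeometry) -> str:
    return json.dumps(
        {
            "schema": "hemoshear-geometry-1",
            "parent_length": geom.parent_length,
            "parent_caliber": geom.parent_caliber,
            "neck_center": geom.neck_center,
            "neck_width": geom.neck_width,
            "shape_family": geom.shape_family.value,
            "sac_boundary": geom.sac_boundary.tolist(),
        },
        indent=2,
    )


def geometry_from_json(text: str) -> AneurysmGeometry:
    d = json.loads(text)
    if d.get("schema") != "hemoshear-geometry-1":
        raise ValueError(f"unsupported geometry schema: {d.get('schema')!r}")
    return AneurysmGeometry(
        parent_length=d["parent_length"],
        parent_caliber=d["parent_caliber"],
        neck_center=d["neck_center"],
        neck_width=d["neck_width"],
        sac_boundary=np.asarray(d["sac_boundary"], dtype=float),
        shape_family=ShapeFamily(d["shape_family"]),
    )


def boundary_to_csv(geom: AneurysmGeometry) -> str:
    """Sac boundary polyline as CSV with an ``x_mm,y_mm`` header."""
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["x_mm", "y_mm"])
    for x, y in geom.sac_boundary:
        w.writerow([repr(float(x)), repr(float(y))])
    return buf.getvalue()


def boundary_from_csv(text: str) -> np.ndarray:
    rows = list(csv.reader(io.StringIO(text)))
    if rows[0] != ["x_mm", "y_mm"]:
        raise ValueError("expected header 'x_mm,y_mm'")
    return np.array([[float(x), float(y)] for x, y in rows[1:]])
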
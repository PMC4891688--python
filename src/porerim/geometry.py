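"""Annotation geometry: polylines, ROI polygons and the quantities measured
on them — lengths, areas, point membership, point-to-edge distances,
projected (foreshortened) perimeters and pore circularity.

All coordinates are physical nanometres in a continuous frame.  Image pixel
(row, col) maps to the point ((col + 0.5) * pixel_size, (row + 0.5) *
pixel_size); y increases downward.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely.geometry as sgeom
from scipy.special import ellipe

from .errors import ValidationError

__all__ = [
    "Polyline",
    "RoiPolygon",
    "PoreAnnotation",
    "polyline_length",
    "polygon_area",
    "point_in_polygon",
    "pore_perimeter",
    "min_edge_distance",
    "projected_perimeter",
    "foreshortening_fraction",
    "perimeter_error_bound",
    "circularity",
    "classify_orientation",
]

EN_FACE_CUTOFF = 0.9
EDGE_ON_CUTOFF = 0.2


@dataclass
class Polyline:
    """An ordered sequence of 2D points in nm, optionally closed.

    The closing segment (last vertex back to the first) is implicit when
    ``closed`` is true; the first vertex is not repeated.
    """

    vertices: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError("vertices: expected an (n, 2) array")
        n_min = 3 if self.closed else 2
        if v.shape[0] < n_min:
            raise ValidationError(
                f"vertices: need at least {n_min} points for "
                f"{'closed' if self.closed else 'open'} polyline, got {v.shape[0]}"
            )
        seg = np.diff(v, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValidationError("vertices: consecutive vertices must be distinct")
        if self.closed and np.all(v[0] == v[-1]):
            raise ValidationError(
                "vertices: closed polyline must not repeat the first vertex"
            )
        self.vertices = v

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def as_shapely(self):
        if self.closed:
            return sgeom.LinearRing(self.vertices)
        return sgeom.LineString(self.vertices)


@dataclass
class RoiPolygon:
    """A simple (non-self-intersecting) region polygon with a label."""

    boundary: Polyline
    label: str = "pore"

    def __post_init__(self) -> None:
        if not self.boundary.closed:
            raise ValidationError("boundary: ROI polygon boundary must be closed")
        if self.label not in ("pore", "non_pore"):
            raise ValidationError(f"label: unknown region label {self.label!r}")
        poly = sgeom.Polygon(self.boundary.vertices)
        if not poly.is_valid or not poly.is_simple:
            raise ValidationError("boundary: polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ValidationError("boundary: polygon must have positive area")
        self._shapely = poly

    def as_shapely(self) -> sgeom.Polygon:
        return self._shapely


@dataclass
class PoreAnnotation:
    """Hand-drawn (or generated) pore annotation: the edge polyline plus the
    outer and inner boundaries flanking the rim band."""

    edge: Polyline
    outer: Polyline
    inner: Polyline
    orientation_class: str = "en_face"

    def __post_init__(self) -> None:
        if not self.outer.closed or not self.inner.closed:
            raise ValidationError("outer/inner: rim-band boundaries must be closed")
        if self.orientation_class not in ("en_face", "oblique", "edge_on"):
            raise ValidationError(
                f"orientation_class: unknown class {self.orientation_class!r}"
            )
        outer_poly = sgeom.Polygon(self.outer.vertices)
        for pt in self.inner.vertices:
            if not outer_poly.covers(sgeom.Point(pt)):
                raise ValidationError("inner: every inner vertex must lie within outer")


def polyline_length(p: Polyline) -> float:
    """Total length in nm, including the closing segment when closed."""
    v = p.vertices
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1).sum()
    if p.closed:
        seg += float(np.linalg.norm(v[0] - v[-1]))
    return float(seg)


def polygon_area(p: RoiPolygon | Polyline) -> float:
    """Absolute shoelace area in nm², independent of vertex orientation."""
    if isinstance(p, RoiPolygon):
        v = p.boundary.vertices
    else:
        if not p.closed:
            raise ValidationError("polygon_area requires a closed polyline")
        ring = sgeom.LinearRing(p.vertices)
        if not ring.is_simple:
            raise ValidationError("polygon_area: polygon must be simple")
        v = p.vertices
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def point_in_polygon(pt, p: RoiPolygon) -> bool:
    """Even-odd membership; points on the boundary count as inside."""
    return bool(p.as_shapely().covers(sgeom.Point(pt)))


def pore_perimeter(ann: PoreAnnotation) -> float:
    """Measured pore perimeter: the average of the outer and inner
    boundary lengths."""
    return 0.5 * (polyline_length(ann.outer) + polyline_length(ann.inner))


def min_edge_distance(pt, edge: Polyline) -> float:
    """Shortest Euclidean distance in nm from a point to the polyline.

    The closest point may lie in a segment interior or at a vertex.
    """
    return float(edge.as_shapely().distance(sgeom.Point(pt)))


def projected_perimeter(d: float, tilt: float) -> float:
    """Perimeter of a circular pore of diameter ``d`` viewed at ``tilt``.

    The projection is an ellipse with semiaxes d/2 and (d/2)·cos(tilt);
    the perimeter is evaluated via the complete elliptic integral of the
    second kind, so it equals πd at tilt 0 and 2d at tilt π/2 exactly.
    """
    if d <= 0:
        raise ValidationError("d: pore diameter must be positive")
    if not 0.0 <= tilt <= np.pi / 2:
        raise ValidationError("tilt: must lie in [0, π/2]")
    a = d / 2.0
    m = np.sin(tilt) ** 2  # eccentricity squared for b = a·cos(tilt)
    return float(4.0 * a * ellipe(m))


def foreshortening_fraction(d: float, tilt: float) -> float:
    """Fractional shortfall of the projected perimeter relative to πd."""
    true_perim = np.pi * d
    return float((true_perim - projected_perimeter(d, tilt)) / true_perim)


def perimeter_error_bound() -> float:
    """Supremum over tilt of the fractional perimeter foreshortening.

    The worst case is the edge-on view, where the measured perimeter is 2d,
    giving (πd − 2d)/πd = (π − 2)/π ≈ 0.3634 (about 36%).
    """
    return float((np.pi - 2.0) / np.pi)


def circularity(ann: PoreAnnotation | Polyline) -> float:
    """Minor/major axis ratio of the best-fit ellipse of the edge vertices.

    Computed from the principal second moments of the vertex cloud; for a
    polyline sampled uniformly in the ellipse parameter this equals b/a.
    """
    edge = ann.edge if isinstance(ann, PoreAnnotation) else ann
    v = edge.vertices
    if v.shape[0] < 5:
        raise ValidationError("edge: circularity needs at least 5 vertices")
    centered = v - v.mean(axis=0)
    cov = centered.T @ centered / v.shape[0]
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[1] <= 0:
        raise ValidationError("edge: degenerate vertex cloud")
    return float(np.sqrt(max(eigvals[0], 0.0) / eigvals[1]))


def classify_orientation(
    circ: float,
    en_face_cutoff: float = EN_FACE_CUTOFF,
    edge_on_cutoff: float = EDGE_ON_CUTOFF,
) -> str:
    """Map a circularity value to {en_face, oblique, edge_on}.

    The en-face cutoff (default 0.9) is a configurable choice; no numeric
    criterion is inherent to the measurement.
    """
    if circ >= en_face_cutoff:
        return "en_face"
    if circ <= edge_on_cutoff:
        return "edge_on"
    return "oblique"
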
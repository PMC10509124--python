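"""Planar geometry primitives for contour-based cardiac quantification.

Conventions
-----------
All coordinates are 2-D and in millimetres, origin at the image top-left
with *y* increasing downward.  Polygons are stored as ``(n, 2)`` vertex
arrays and are closed implicitly (the last vertex is not a repeat of the
first).  Areas returned by :func:`polygon_area` are magnitudes in mm^2;
signed quantities state their sign convention explicitly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import GeometryError

__all__ = [
    "as_points",
    "shoelace",
    "polygon_area",
    "polygon_centroid",
    "overlap_area",
    "polyline_length",
    "resample_polyline",
    "swept_area",
    "fit_line_tls",
    "point_line_distance",
    "nearest_vertex",
    "split_closed_polygon",
]


def as_points(obj) -> np.ndarray:
    """Coerce a vertex sequence to a float ``(n, 2)`` array."""
    pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError(f"expected an (n, 2) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise GeometryError("non-finite coordinates in point array")
    return pts


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the 2-D cross product, elementwise."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def shoelace(vertices) -> float:
    """Signed shoelace area of an implicitly closed polygon (mm^2).

    Positive for counter-clockwise traversal in a right-handed frame; the
    caller owns the sign convention.
    """
    pts = as_points(vertices)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(polygon) -> float:
    """Area of a simple polygon, independent of vertex orientation.

    Raises :class:`GeometryError` for fewer than three vertices or a
    self-intersecting boundary.
    """
    pts = as_points(polygon)
    if len(pts) < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    if not _ShapelyPolygon(pts).is_valid:
        raise GeometryError("polygon is self-intersecting or degenerate")
    return abs(shoelace(pts))


def polygon_centroid(polygon) -> np.ndarray:
    """Area centroid of a simple polygon."""
    pts = as_points(polygon)
    c = _ShapelyPolygon(pts).centroid
    return np.array([c.x, c.y])


def overlap_area(polygon_a, polygon_b) -> float:
    """Area of the intersection of two simple polygons (mm^2)."""
    a = _ShapelyPolygon(as_points(polygon_a)).buffer(0)
    b = _ShapelyPolygon(as_points(polygon_b)).buffer(0)
    return float(a.intersection(b).area)


def polyline_length(polyline) -> float:
    pts = as_points(polyline)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def resample_polyline(polyline, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` points uniformly spaced in arc
    length.  Endpoints are preserved exactly."""
    pts = as_points(polyline)
    if len(pts) < 2:
        raise GeometryError("polyline needs at least 2 points")
    if n < 2:
        raise GeometryError("resampling needs n >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0.0:
        raise GeometryError("degenerate polyline of zero length")
    t = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(t, s, pts[:, 0]), np.interp(t, s, pts[:, 1])])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def swept_area(ed_polyline, es_polyline, toward, n: int = 128) -> float:
    """Signed area swept between two open polylines (mm^2).

    The region is the closed polygon formed by the ED polyline, the reversed
    ES polyline and the two chords joining corresponding endpoints; both
    polylines are resampled to ``n`` points by arc length so unequal vertex
    counts are handled.  The sign is positive when the ES polyline is
    displaced from the ED polyline toward the reference point ``toward``
    (e.g. a cavity centroid for inward wall motion).  The orientation factor
    depends only on the ED polyline and the reference point, so mirroring
    the ES displacement flips the sign exactly.
    """
    ed = resample_polyline(ed_polyline, n)
    es = resample_polyline(es_polyline, n)
    ref = as_points(np.atleast_2d(toward))[0]

    closed = np.vstack([ed, es[::-1]])
    raw = shoelace(closed)

    tangents = np.diff(ed, axis=0)
    midpoints = 0.5 * (ed[:-1] + ed[1:])
    orientation = float(np.sum(_cross2(tangents, ref - midpoints)))
    if orientation == 0.0:
        raise GeometryError("reference point is collinear with the ED polyline")
    return raw * np.sign(orientation)


def fit_line_tls(points) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares (orthogonal regression) line through 2-D points.

    Returns ``(point, direction)`` with a unit direction vector.  For two
    points this is the exact line through them.  Raises
    :class:`GeometryError` if the points are (numerically) coincident.
    """
    pts = as_points(points)
    if len(pts) < 2:
        raise GeometryError("line fit needs at least 2 points")
    center = pts.mean(axis=0)
    centered = pts - center
    # principal direction of the scatter = TLS line direction
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise GeometryError("coincident points: AV line is undefined")
    return center, vt[0] / np.linalg.norm(vt[0])


def point_line_distance(point, line_point, line_direction) -> float:
    """Perpendicular distance from a point to an infinite 2-D line."""
    p = as_points(np.atleast_2d(point))[0]
    q = as_points(np.atleast_2d(line_point))[0]
    d = np.asarray(line_direction, dtype=float)
    d = d / np.linalg.norm(d)
    return abs(float(_cross2(d, p - q)))


def nearest_vertex(polygon, point) -> int:
    """Index of the polygon vertex nearest to ``point``."""
    pts = as_points(polygon)
    p = as_points(np.atleast_2d(point))[0]
    return int(np.argmin(np.linalg.norm(pts - p, axis=1)))


def split_closed_polygon(polygon, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a closed polygon boundary at vertex indices ``i`` and ``j``.

    Returns the two open boundary arcs, both inclusive of the split
    vertices, traversed in the polygon's stored orientation:
    ``arc_ij`` runs i -> j and ``arc_ji`` runs j -> i (wrapping).
    """
    pts = as_points(polygon)
    m = len(pts)
    if i == j:
        raise GeometryError("cannot split a polygon at a single vertex")
    idx_ij = [(i + k) % m for k in range(((j - i) % m) + 1)]
    idx_ji = [(j + k) % m for k in range(((i - j) % m) + 1)]
    return pts[idx_ij], pts[idx_ji]


def cross2(a: Sequence[float], b: Sequence[float]) -> float:
    """Scalar 2-D cross product."""
    return float(_cross2(np.asarray(a, dtype=float), np.asarray(b, dtype=float)))
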
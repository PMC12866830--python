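"""Alpha-shape construction and small polygon helpers.

The alpha-shape (concave hull) is the package's canonical boundary for a
segmented aggregate: the union of Delaunay triangles whose circumradius is
at most ``alpha_radius``.  Degenerate inputs (collinear points, or an alpha
radius smaller than the local point spacing) fall back to the convex hull so
that every cluster always has a well-defined area.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from .errors import DegenerateGeometryError

__all__ = ["alpha_shape", "convex_hull", "largest_polygon", "polygon_area"]


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of every Delaunay triangle (R = abc / 4K)."""
    p0 = points[simplices[:, 0]]
    p1 = points[simplices[:, 1]]
    p2 = points[simplices[:, 2]]
    a = np.linalg.norm(p1 - p0, axis=1)
    b = np.linalg.norm(p2 - p1, axis=1)
    c = np.linalg.norm(p0 - p2, axis=1)
    # twice the signed triangle area via the cross product
    cross = (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1]) - (
        p1[:, 1] - p0[:, 1]
    ) * (p2[:, 0] - p0[:, 0])
    area2 = np.abs(cross)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a * b * c) / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def convex_hull(points: np.ndarray):
    """Shapely convex hull of a point set (may be a Point/LineString)."""
    return MultiPoint([tuple(p) for p in np.asarray(points, float)]).convex_hull


def alpha_shape(points: np.ndarray, alpha_radius: float):
    """Concave hull of ``points``: union of Delaunay triangles with
    circumradius <= ``alpha_radius``.

    Parameters
    ----------
    points : (n, 2) array
        Point coordinates in µm.
    alpha_radius : float
        Circumradius cut-off in µm.  Larger values approach the convex hull.

    Returns
    -------
    shapely geometry (Polygon or MultiPolygon).  Falls back to the convex
    hull when the triangulation is degenerate or the filtered union has no
    area (e.g. alpha smaller than the point spacing).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        return convex_hull(pts)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return convex_hull(pts)
    radii = _circumradii(pts, tri.simplices)
    keep = tri.simplices[radii <= alpha_radius]
    if len(keep) == 0:
        return convex_hull(pts)
    triangles = shapely.polygons(pts[keep])
    try:
        # triangles from one triangulation form a valid coverage
        shape = shapely.coverage_union_all(triangles)
    except shapely.errors.GEOSException:
        shape = unary_union(list(triangles))
    if shape.is_empty or shape.area == 0:
        return convex_hull(pts)
    return shape


def largest_polygon(geom) -> Polygon:
    """The largest polygonal component of a shapely geometry."""
    if isinstance(geom, Polygon):
        return geom
    if geom.geom_type == "MultiPolygon":
        return max(geom.geoms, key=lambda g: g.area)
    if geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if isinstance(g, Polygon)]
        if polys:
            return max(polys, key=lambda g: g.area)
    raise DegenerateGeometryError(f"no polygonal component in {geom.geom_type}")


def polygon_area(geom) -> float:
    """Total area of a shapely geometry (0 for points/lines)."""
    return float(geom.area)
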
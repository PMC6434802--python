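"""Neck plane estimation and the six neck-size parameters.

The neck curve is the single boundary loop of the dome.  Its best-fit
plane (total least squares, arc-length weighted so the fit does not
depend on vertex sampling density) defines the reference frame for the
height parameters, and the loop's footprint in that plane yields the
neck diameters and areas:

* ``D_neck_min`` — minimal caliper width of the projected loop's convex
  hull ("minimum distance between two opposite points"),
* ``D_neck_max`` — maximal pairwise distance of projected loop points,
* ``P_neck``    — 3D polyline length of the neck curve,
* ``A_neck``    — planar (shoelace) area of the projected polygon,
* ``D_neck_equiv`` — hydraulic diameter 4 A / P,
* ``A_neck_elliptical`` — (pi/4) D_min D_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .mesh_core import AneurysmDome, MeshError, _loop_centroid

__all__ = ["NeckPlane", "NeckMetrics", "fit_neck_plane", "neck_metrics"]


@dataclass
class NeckPlane:
    """Best-fit neck plane with the dome on the positive side."""

    origin: np.ndarray  # arc-length-weighted centroid of the neck curve
    normal: np.ndarray  # unit normal, dome side positive

    def signed_height(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane directions."""
        n = self.normal
        seed = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, seed)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def project_2d(self, points: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        rel = np.atleast_2d(points) - self.origin
        return np.column_stack([rel @ u, rel @ v])


@dataclass
class NeckMetrics:
    D_neck_min: float
    D_neck_max: float
    P_neck: float
    D_neck_equiv: float
    A_neck: float
    A_neck_elliptical: float
    projected_polygon_convexified: bool = False

    def __post_init__(self):
        if not (0 < self.D_neck_min <= self.D_neck_max + 1e-12):
            raise ValueError("neck diameters must satisfy 0 < D_min <= D_max")


def fit_neck_plane(dome: AneurysmDome) -> NeckPlane:
    """Total-least-squares plane through the arc-length-weighted neck curve.

    The normal is oriented so the mean signed height of the dome vertices
    is positive (the dome lies above the plane).
    """
    pts = dome.neck_points
    nxt = np.roll(pts, -1, axis=0)
    seg_len = np.linalg.norm(nxt - pts, axis=1)
    # vertex weight = half the length of its two incident segments
    w = 0.5 * (seg_len + np.roll(seg_len, 1))
    if w.sum() <= 0:
        raise MeshError("degenerate neck loop (zero length)")
    origin = _loop_centroid(pts)
    rel = (pts - origin) * np.sqrt(w)[:, None]
    _, svals, vt = np.linalg.svd(rel, full_matrices=False)
    if svals[1] < 1e-12 * max(svals[0], 1e-300):
        raise MeshError("neck loop vertices are collinear; plane undefined")
    normal = vt[2]
    heights = (dome.surface.vertices - origin) @ normal
    if heights.mean() < 0:
        normal = -normal
    return NeckPlane(origin=origin, normal=normal / np.linalg.norm(normal))


def _min_caliper_width(hull_points_2d: np.ndarray) -> float:
    """Rotating-calipers minimal width of a 2D convex polygon.

    The minimal width is attained with one caliper flush against a hull
    edge, so it equals the minimum over edges of the farthest point
    distance to the edge's supporting line.
    """
    pts = hull_points_2d
    n = len(pts)
    if n == 2:
        return 0.0
    width = np.inf
    for i in range(n):
        a = pts[i]
        b = pts[(i + 1) % n]
        e = b - a
        norm = np.linalg.norm(e)
        if norm < 1e-15:
            continue
        # perpendicular distance of every vertex to line (a, b)
        rel = pts - a
        d = np.abs(e[0] * rel[:, 1] - e[1] * rel[:, 0]) / norm
        width = min(width, d.max())
    return float(width)


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _is_simple_polygon(poly: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return Polygon(poly).is_valid


def neck_metrics(dome: AneurysmDome, plane: NeckPlane) -> NeckMetrics:
    """The six neck parameters from the boundary loop and its plane."""
    pts3d = dome.neck_points
    nxt = np.roll(pts3d, -1, axis=0)
    perimeter = float(np.linalg.norm(nxt - pts3d, axis=1).sum())

    proj = plane.project_2d(pts3d)
    d_max = float(pdist(proj).max())

    hull = ConvexHull(proj)
    hull_pts = proj[hull.vertices]
    d_min = _min_caliper_width(hull_pts)

    convexified = False
    if _is_simple_polygon(proj):
        area = _polygon_area(proj)
    else:
        # self-intersecting footprint: fall back to its convex hull area
        area = float(hull.volume)  # 2D qhull: volume == area
        convexified = True

    d_equiv = 4.0 * area / perimeter
    a_ellip = np.pi / 4.0 * d_min * d_max
    return NeckMetrics(
        D_neck_min=d_min,
        D_neck_max=d_max,
        P_neck=perimeter,
        D_neck_equiv=d_equiv,
        A_neck=area,
        A_neck_elliptical=a_ellip,
        projected_polygon_convexified=convexified,
    )
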
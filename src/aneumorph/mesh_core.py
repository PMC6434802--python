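"""Triangle-mesh data model, I/O, validation and global integral quantities.

All lengths are millimetres; areas mm^2, volumes mm^3.  A
:class:`TriangleSurface` is an indexed triangle mesh whose topology is
checked on construction (manifold edges, consistent orientation,
non-degenerate triangles).  An :class:`AneurysmDome` is an open surface
with exactly one boundary loop — the neck curve where the sac was
separated from the parent vessel — oriented so that triangle normals
point away from the enclosed blood volume.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "TriangleSurface",
    "AneurysmDome",
    "ClosedAneurysm",
    "ValidationReport",
    "read_mesh",
    "validate_surface",
    "surface_area",
    "enclosed_volume",
    "cap_neck",
    "convex_hull_metrics",
    "minimal_bounding_sphere",
]

#: absolute tolerance for geometric predicates (mm)
GEOM_TOL = 1e-9


class MeshError(ValueError):
    """Raised for topological or geometric defects that block computation."""


# ---------------------------------------------------------------------------
# topology helpers


def _deduplicate_vertices(vertices: np.ndarray, triangles: np.ndarray, tol: float):
    """Merge vertices closer than ``tol`` and remap triangle indices."""
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[np.sort(first)]
    new_triangles = rank[inverse][triangles]
    return new_vertices, new_triangles


def _edge_face_map(triangles: np.ndarray):
    """Map undirected edge (i<j) -> list of (face index, directed-as-stored flag)."""
    emap: dict[tuple[int, int], list[tuple[int, bool]]] = defaultdict(list)
    for f, (a, b, c) in enumerate(triangles):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            emap[key].append((f, u < v))
    return emap


def _orient_consistently(triangles: np.ndarray, emap) -> np.ndarray:
    """Flip triangles via breadth-first propagation so that every interior
    edge is traversed in opposite directions by its two incident faces."""
    n_faces = len(triangles)
    tris = triangles.copy()
    flipped = np.zeros(n_faces, dtype=bool)
    visited = np.zeros(n_faces, dtype=bool)
    # adjacency through manifold edges only
    adj: list[list[tuple[int, bool]]] = [[] for _ in range(n_faces)]
    for faces in emap.values():
        if len(faces) == 2:
            (f1, d1), (f2, d2) = faces
            same = d1 == d2  # same traversal direction => inconsistent pair
            adj[f1].append((f2, same))
            adj[f2].append((f1, same))
    for seed in range(n_faces):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        while stack:
            f = stack.pop()
            for g, same in adj[f]:
                if not visited[g]:
                    visited[g] = True
                    flipped[g] = flipped[f] ^ same
                    stack.append(g)
    tris[flipped] = tris[flipped][:, ::-1]
    return tris


def _boundary_loops(triangles: np.ndarray, emap) -> list[np.ndarray]:
    """Ordered vertex cycles of edges used by exactly one triangle.

    Loops follow the orientation induced by the incident triangle, i.e.
    each directed boundary edge (a -> b) appears as a -> b in some
    triangle (a, b, *).
    """
    succ: dict[int, int] = {}
    tri_set = {tuple(t) for t in triangles}
    for (u, v), faces in emap.items():
        if len(faces) != 1:
            continue
        f, _ = faces[0]
        a, b, c = triangles[f]
        # find the directed occurrence within the face
        for s, t in ((a, b), (b, c), (c, a)):
            if {s, t} == {u, v}:
                if s in succ:
                    raise MeshError(
                        f"boundary is not a simple set of loops at vertex {s}"
                    )
                succ[s] = t
                break
    loops = []
    remaining = set(succ)
    while remaining:
        start = min(remaining)
        loop = [start]
        remaining.discard(start)
        v = succ[start]
        while v != start:
            loop.append(v)
            remaining.discard(v)
            v = succ[v]
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


# ---------------------------------------------------------------------------
# data model


class TriangleSurface:
    """Indexed triangle mesh in mm with validated topology.

    Parameters
    ----------
    vertices : (n, 3) array_like
        Vertex coordinates in mm.
    triangles : (m, 3) array_like
        0-based vertex index triples.
    deduplicate : bool
        Merge vertices closer than ``tol`` (default True).
    fix_orientation : bool
        Make triangle orientation globally consistent by breadth-first
        propagation (default True).  The *global* sign (inward vs
        outward) is not decided here; see :class:`AneurysmDome`.
    """

    def __init__(
        self,
        vertices,
        triangles,
        *,
        deduplicate: bool = True,
        fix_orientation: bool = True,
        tol: float = GEOM_TOL,
    ):
        vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        triangles = np.ascontiguousarray(triangles, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if triangles.ndim != 2 or triangles.shape[1] != 3:
            raise MeshError("triangles must be an (m, 3) array")
        if triangles.size and (triangles.min() < 0 or triangles.max() >= len(vertices)):
            raise MeshError("triangle references a missing vertex")
        if deduplicate:
            vertices, triangles = _deduplicate_vertices(vertices, triangles, tol)
        # drop exactly degenerate triangles (repeated indices after merging)
        keep = (
            (triangles[:, 0] != triangles[:, 1])
            & (triangles[:, 1] != triangles[:, 2])
            & (triangles[:, 2] != triangles[:, 0])
        )
        triangles = triangles[keep]
        emap = _edge_face_map(triangles)
        for (u, v), faces in emap.items():
            if len(faces) > 2:
                raise MeshError(
                    f"non-manifold edge ({u}, {v}) shared by {len(faces)} triangles"
                )
        if fix_orientation and len(triangles):
            triangles = _orient_consistently(triangles, emap)
            emap = _edge_face_map(triangles)
        self.vertices = vertices
        self.triangles = triangles
        self._emap = emap
        self._loops: Optional[list[np.ndarray]] = None

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def triangle_corners(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.triangles]

    @property
    def triangle_cross(self) -> np.ndarray:
        c = self.triangle_corners
        return np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])

    @property
    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_cross, axis=1)

    @property
    def triangle_normals(self) -> np.ndarray:
        cr = self.triangle_cross
        norms = np.linalg.norm(cr, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(norms > 0, cr / norms, 0.0)

    @property
    def boundary_loops(self) -> list[np.ndarray]:
        if self._loops is None:
            self._loops = _boundary_loops(self.triangles, self._emap)
        return self._loops

    @property
    def is_closed(self) -> bool:
        return len(self.boundary_loops) == 0

    # -- transforms ---------------------------------------------------------

    def flipped(self) -> "TriangleSurface":
        """Surface with all triangle orientations reversed."""
        s = self.copy()
        s.triangles = s.triangles[:, ::-1].copy()
        s._emap = _edge_face_map(s.triangles)
        s._loops = None
        return s

    def transformed(self, rotation=None, translation=None, scale: float = 1.0):
        v = self.vertices * float(scale)
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriangleSurface(
            v, self.triangles, deduplicate=False, fix_orientation=False
        )

    def copy(self) -> "TriangleSurface":
        return TriangleSurface(
            self.vertices.copy(),
            self.triangles.copy(),
            deduplicate=False,
            fix_orientation=False,
        )

    def __repr__(self):
        return (
            f"TriangleSurface({self.n_vertices} vertices, "
            f"{self.n_triangles} triangles, "
            f"{len(self.boundary_loops)} boundary loop(s))"
        )


@dataclass
class AneurysmDome:
    """Open aneurysm sac surface bounded by the neck curve.

    On construction the surface orientation is made outward: the neck is
    temporarily capped and all triangles are flipped if the resulting
    signed volume is negative.
    """

    surface: TriangleSurface
    parent_vessel_diameter: Optional[float] = None
    aneurysm_id: str = "aneurysm"
    group_id: str = "group"

    def __post_init__(self):
        loops = self.surface.boundary_loops
        if len(loops) != 1:
            raise MeshError(
                f"expected exactly one neck boundary loop, found {len(loops)}"
            )
        if len(loops[0]) < 3:
            raise MeshError("neck boundary loop must have at least 3 vertices")
        if self.parent_vessel_diameter is not None and self.parent_vessel_diameter <= 0:
            raise MeshError("parent vessel diameter must be positive")
        vol = _capped_signed_volume(self.surface)
        if vol < 0:
            self.surface = self.surface.flipped()

    @property
    def neck_loop(self) -> np.ndarray:
        return self.surface.boundary_loops[0]

    @property
    def neck_points(self) -> np.ndarray:
        return self.surface.vertices[self.neck_loop]


@dataclass
class ClosedAneurysm:
    """Watertight neck-closed aneurysm with flagged cap triangles."""

    surface: TriangleSurface
    cap_triangle_mask: np.ndarray
    source: AneurysmDome

    @property
    def dome_area(self) -> float:
        return surface_area(self.surface, ~self.cap_triangle_mask)

    @property
    def closed_area(self) -> float:
        return surface_area(self.surface)

    @property
    def volume(self) -> float:
        return enclosed_volume(self.surface)


# ---------------------------------------------------------------------------
# I/O


def read_mesh(path, format: Optional[str] = None) -> TriangleSurface:
    """Read an STL/PLY/OBJ mesh file into a :class:`TriangleSurface`.

    Vertices are deduplicated at 1e-9 mm and triangle orientation is made
    consistent.  Units are assumed to be millimetres; no unit metadata is
    read from the file.
    """
    import trimesh

    kwargs = {"process": False}
    if format is not None:
        kwargs["file_type"] = format.lower()
    mesh = trimesh.load(str(path), force="mesh", **kwargs)
    if not hasattr(mesh, "faces") or len(mesh.faces) == 0:
        raise MeshError(f"no triangles found in {path}")
    return TriangleSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces))


def write_mesh(surface: TriangleSurface, path) -> None:
    """Write a surface as STL/PLY/OBJ (format from the file extension)."""
    import trimesh

    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.triangles, process=False
    )
    mesh.export(str(path))


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Report-only surface quality check; serializable via ``as_dict``."""

    n_vertices: int
    n_triangles: int
    nonmanifold_edges: list
    inconsistent_edges: list
    degenerate_triangles: list
    boundary_loop_count: int
    self_intersecting_pairs: Optional[list]
    passed: bool = field(init=False)

    def __post_init__(self):
        self.passed = (
            not self.nonmanifold_edges
            and not self.inconsistent_edges
            and not self.degenerate_triangles
            and not self.self_intersecting_pairs
        )

    def as_dict(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "n_triangles": self.n_triangles,
            "nonmanifold_edges": [list(e) for e in self.nonmanifold_edges],
            "inconsistent_edges": [list(e) for e in self.inconsistent_edges],
            "degenerate_triangles": list(map(int, self.degenerate_triangles)),
            "boundary_loop_count": self.boundary_loop_count,
            "self_intersecting_pairs": (
                None
                if self.self_intersecting_pairs is None
                else [list(p) for p in self.self_intersecting_pairs]
            ),
            "passed": bool(self.passed),
        }


def _tri_tri_intersects(t1: np.ndarray, t2: np.ndarray, eps: float = 1e-12) -> bool:
    """Exact-ish triangle-triangle intersection test (interval method)."""

    def plane(t):
        n = np.cross(t[1] - t[0], t[2] - t[0])
        return n, -np.dot(n, t[0])

    n2, d2 = plane(t2)
    dist1 = t1 @ n2 + d2
    if np.all(dist1 > eps) or np.all(dist1 < -eps):
        return False
    n1, d1 = plane(t1)
    dist2 = t2 @ n1 + d1
    if np.all(dist2 > eps) or np.all(dist2 < -eps):
        return False

    if np.all(np.abs(dist1) <= eps):  # coplanar: 2D overlap via shapely
        from shapely.geometry import Polygon

        axis = np.argmax(np.abs(n2)) if np.linalg.norm(n2) > 0 else 2
        cols = [i for i in range(3) if i != axis]
        p1 = Polygon(t1[:, cols])
        p2 = Polygon(t2[:, cols])
        return bool(p1.intersects(p2) and p1.intersection(p2).area > eps)

    # interval of each triangle on the intersection line
    direction = np.cross(n1, n2)
    axis = int(np.argmax(np.abs(direction)))

    def interval(t, dist):
        proj = t[:, axis]
        pts = []
        for i in range(3):
            j = (i + 1) % 3
            di, dj = dist[i], dist[j]
            if di * dj < 0 or (abs(di) <= eps) != (abs(dj) <= eps):
                if abs(di - dj) > eps:
                    s = di / (di - dj)
                    pts.append(proj[i] + s * (proj[j] - proj[i]))
            if abs(di) <= eps:
                pts.append(proj[i])
        if not pts:
            return None
        return min(pts), max(pts)

    i1 = interval(t1, dist1)
    i2 = interval(t2, dist2)
    if i1 is None or i2 is None:
        return False
    return min(i1[1], i2[1]) - max(i1[0], i2[0]) > eps


def _self_intersections(surface: TriangleSurface) -> list[tuple[int, int]]:
    """All-pairs triangle intersection test with AABB prefilter.

    Pairs sharing a vertex are ignored (they touch by construction).
    """
    corners = surface.triangle_corners
    lo = corners.min(axis=1)
    hi = corners.max(axis=1)
    tris = surface.triangles
    pairs = []
    m = len(tris)
    for i in range(m):
        # AABB overlap, vectorized over j > i
        js = np.nonzero(
            np.all(lo[i + 1 :] <= hi[i] + GEOM_TOL, axis=1)
            & np.all(hi[i + 1 :] >= lo[i] - GEOM_TOL, axis=1)
        )[0]
        set_i = set(tris[i])
        for j in js + i + 1:
            if set_i & set(tris[j]):
                continue
            if _tri_tri_intersects(corners[i], corners[j]):
                pairs.append((i, int(j)))
    return pairs


def validate_surface(
    surface: TriangleSurface, check_self_intersections: bool = False
) -> ValidationReport:
    """Check manifoldness, orientation consistency, degenerate triangles,
    hole count and (optionally) self-intersections.  Report-only: the
    surface is never modified."""
    nonmanifold = [e for e, fs in surface._emap.items() if len(fs) > 2]
    inconsistent = []
    for e, fs in surface._emap.items():
        if len(fs) == 2 and fs[0][1] == fs[1][1]:
            inconsistent.append(e)
    degenerate = [int(i) for i in np.nonzero(surface.triangle_areas < 1e-14)[0]]
    intersections = (
        _self_intersections(surface) if check_self_intersections else None
    )
    return ValidationReport(
        n_vertices=surface.n_vertices,
        n_triangles=surface.n_triangles,
        nonmanifold_edges=nonmanifold,
        inconsistent_edges=inconsistent,
        degenerate_triangles=degenerate,
        boundary_loop_count=len(surface.boundary_loops),
        self_intersecting_pairs=intersections,
    )


# ---------------------------------------------------------------------------
# integral quantities


def surface_area(surface: TriangleSurface, triangle_subset=None) -> float:
    """Total (or masked) triangle area in mm^2."""
    areas = surface.triangle_areas
    if triangle_subset is not None:
        areas = areas[np.asarray(triangle_subset)]
        if areas.size == 0:
            warnings.warn("empty triangle subset; area is 0", stacklevel=2)
            return 0.0
    return float(areas.sum())


def enclosed_volume(surface: TriangleSurface) -> float:
    """Signed-volume (divergence theorem) of a watertight, outward-oriented
    surface: sum of det(v0, v1, v2)/6 over triangles."""
    if not surface.is_closed:
        raise MeshError("enclosed_volume requires a watertight surface")
    vol = _signed_volume(surface)
    if vol < 0:
        raise MeshError(
            "negative enclosed volume: triangle orientation is inward"
        )
    return vol


def _signed_volume(surface: TriangleSurface) -> float:
    c = surface.triangle_corners
    return float(np.einsum("ij,ij->i", c[:, 0], np.cross(c[:, 1], c[:, 2])).sum() / 6.0)


def _loop_centroid(points: np.ndarray) -> np.ndarray:
    """Arc-length-weighted centroid of a closed polyline (cycle)."""
    nxt = np.roll(points, -1, axis=0)
    seg_len = np.linalg.norm(nxt - points, axis=1)
    seg_mid = 0.5 * (points + nxt)
    total = seg_len.sum()
    if total <= 0:
        return points.mean(axis=0)
    return (seg_mid * seg_len[:, None]).sum(axis=0) / total


def _cap_triangles(surface: TriangleSurface):
    """Fan triangles closing the single boundary loop to its centroid.

    Returns (vertices incl. centroid, cap triangle index array).
    """
    loop = surface.boundary_loops[0]
    pts = surface.vertices[loop]
    centroid = _loop_centroid(pts)
    n = surface.n_vertices
    verts = np.vstack([surface.vertices, centroid[None, :]])
    # dome boundary edges run a -> b in dome winding; cap runs b -> a
    a = loop
    b = np.roll(loop, -1)
    cap = np.column_stack([b, a, np.full(len(loop), n, dtype=np.int64)])
    return verts, cap


def _capped_signed_volume(surface: TriangleSurface) -> float:
    if surface.is_closed:
        return _signed_volume(surface)
    verts, cap = _cap_triangles(surface)
    tris = np.vstack([surface.triangles, cap])
    closed = TriangleSurface(verts, tris, deduplicate=False, fix_orientation=False)
    return _signed_volume(closed)


def cap_neck(dome: AneurysmDome) -> ClosedAneurysm:
    """Close the neck by fan triangulation to the arc-length-weighted loop
    centroid; the resulting surface is watertight with positive volume and
    the cap triangles are flagged."""
    surface = dome.surface
    verts, cap = _cap_triangles(surface)
    tris = np.vstack([surface.triangles, cap])
    closed = TriangleSurface(verts, tris, deduplicate=False, fix_orientation=False)
    if not closed.is_closed:
        raise MeshError("capping failed to produce a watertight surface")
    vol = _signed_volume(closed)
    if vol <= 0:
        raise MeshError("capped surface has non-positive volume")
    mask = np.zeros(len(tris), dtype=bool)
    mask[len(surface.triangles):] = True
    # warn on strongly non-planar loops whose fan may fold
    cap_pts = surface.vertices[surface.boundary_loops[0]]
    centroid = _loop_centroid(cap_pts)
    spread = cap_pts - centroid
    normal = np.linalg.svd(spread, full_matrices=False)[2][2]
    planarity = np.abs(spread @ normal).max()
    extent = np.linalg.norm(spread, axis=1).max()
    if extent > 0 and planarity > 0.5 * extent:
        warnings.warn(
            "neck loop is strongly non-planar; cap fan may self-intersect",
            stacklevel=2,
        )
    return ClosedAneurysm(surface=closed, cap_triangle_mask=mask, source=dome)


def convex_hull_metrics(surface: TriangleSurface):
    """Exact convex hull of the vertex set.

    Returns ``(hull_surface, area_mm2, volume_mm3)``.  The hull surface is
    a closed :class:`TriangleSurface` with outward orientation.
    """
    pts = surface.vertices if isinstance(surface, TriangleSurface) else np.asarray(surface)
    if len(pts) < 4:
        raise MeshError("convex hull requires at least 4 points")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull degenerate input
        raise MeshError(f"degenerate point set for convex hull: {exc}") from exc
    simplices = hull.simplices.copy()
    # orient each simplex outward using qhull's facet equations
    corners = pts[simplices]
    normals = np.cross(
        corners[:, 1] - corners[:, 0], corners[:, 2] - corners[:, 0]
    )
    flip = np.einsum("ij,ij->i", normals, hull.equations[:, :3]) < 0
    simplices[flip] = simplices[flip][:, ::-1]
    hull_surface = TriangleSurface(
        pts, simplices, deduplicate=False, fix_orientation=False
    )
    return hull_surface, float(hull.area), float(hull.volume)


# ---------------------------------------------------------------------------
# minimal bounding sphere (Welzl with 2/3/4-point support)


def _circumsphere(support: tuple) -> tuple[np.ndarray, float]:
    """Smallest sphere having all support points (1-4) on its boundary."""
    k = len(support)
    if k == 0:
        return np.zeros(3), -1.0
    if k == 1:
        return np.asarray(support[0], dtype=float), 0.0
    if k == 2:
        a, b = support
        c = 0.5 * (a + b)
        return c, float(np.linalg.norm(a - c))
    if k == 3:
        a, b, c = support
        ab, ac = b - a, c - a
        n = np.cross(ab, ac)
        nn = np.dot(n, n)
        if nn <= 1e-30:  # collinear: fall back to the two farthest points
            return _farthest_pair_ball(support)
        m = (np.dot(ab, ab) * np.cross(ac, n) + np.dot(ac, ac) * np.cross(n, ab)) / (
            2.0 * nn
        )
        center = a + m
        return center, float(np.linalg.norm(m))
    # k == 4: solve 2 (p_i - a) . c = |p_i|^2 - |a|^2 for the center c
    a = np.asarray(support[0], dtype=float)
    rows = np.array([2.0 * (np.asarray(p) - a) for p in support[1:]])
    rhs = np.array([np.dot(p, p) - np.dot(a, a) for p in support[1:]])
    try:
        center = np.linalg.solve(rows, rhs)
    except np.linalg.LinAlgError:
        return _best_subset_ball(support)
    return center, float(np.linalg.norm(center - a))


def _farthest_pair_ball(points) -> tuple[np.ndarray, float]:
    pts = np.asarray(points, dtype=float)
    best = (pts[0], 0.0)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            r = 0.5 * np.linalg.norm(pts[i] - pts[j])
            if r > best[1]:
                best = (0.5 * (pts[i] + pts[j]), float(r))
    return best


def _best_subset_ball(support) -> tuple[np.ndarray, float]:
    """Degenerate support: smallest sub-support sphere enclosing all."""
    from itertools import combinations

    pts = [np.asarray(p, dtype=float) for p in support]
    best = None
    for k in (2, 3):
        for sub in combinations(pts, k):
            c, r = _circumsphere(sub)
            if r < 0:
                continue
            if all(np.linalg.norm(p - c) <= r + 1e-9 for p in pts):
                if best is None or r < best[1]:
                    best = (c, r)
    if best is None:
        best = _farthest_pair_ball(pts)
    return best


def _welzl(points: np.ndarray, seed: int = 0) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(seed)
    pts = points[rng.permutation(len(points))]

    def mb(n: int, support: tuple) -> tuple[np.ndarray, float]:
        center, radius = _circumsphere(support)
        if len(support) == 4:
            return center, radius
        for i in range(n):
            p = pts[i]
            if radius < 0 or np.linalg.norm(p - center) > radius * (1 + 1e-12) + 1e-12:
                center, radius = mb(i, support + (p,))
        return center, radius

    return mb(len(pts), ())


def minimal_bounding_sphere(surface) -> tuple[np.ndarray, float, float, float]:
    """Exact minimal enclosing sphere of the vertex set (Welzl-type).

    Returns ``(center, radius, A_MBS, V_MBS)`` with A = 4 pi r^2 and
    V = 4 pi r^3 / 3.  All vertices lie within radius + 1e-9.
    """
    pts = surface.vertices if isinstance(surface, TriangleSurface) else np.asarray(
        surface, dtype=float
    )
    if len(pts) == 0:
        raise MeshError("minimal bounding sphere requires at least one point")
    if len(pts) == 1:
        center, radius = pts[0].copy(), 0.0
    else:
        center, radius = _welzl(pts)
        # one corrective pass: enforce the containment contract exactly
        d = np.linalg.norm(pts - center, axis=1)
        radius = max(radius, float(d.max()) - 1e-12)
    area = 4.0 * np.pi * radius**2
    volume = 4.0 * np.pi * radius**3 / 3.0
    return center, float(radius), float(area), float(volume)
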
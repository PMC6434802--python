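"""The twelve dimensional size parameters of an aneurysm dome.

Heights are measured against the neck plane; ``D_max`` is the largest
cross-sectional diameter over planes parallel to the neck plane, found
by a slice sweep, and ``H_b`` (bulge height) is the height of the
maximizing slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .mesh_core import AneurysmDome, ClosedAneurysm, MeshError
from .neck_geometry import NeckPlane

__all__ = [
    "SizeMetrics",
    "height_metrics",
    "max_dimension",
    "plane_parallel_diameter",
    "assemble_size_metrics",
]


@dataclass
class SizeMetrics:
    """Parameters #1-#12: lengths in mm, areas mm^2, volumes mm^3."""

    H: float
    L_max: float
    H_max: float
    D_max: float
    H_b: float
    A: float
    A_CH: float
    A_MBS: float
    A_closed: float
    V: float
    V_CH: float
    V_MBS: float

    def check_invariants(self, rtol: float = 1e-9, mesh_slack: float = 1e-6):
        """Raise if a dimensional inequality among the metrics is violated.

        ``mesh_slack`` absorbs discretization error (e.g. slice spacing)."""
        checks = [
            ("0 <= H_b", -self.H_b, mesh_slack),
            ("H_b <= H", self.H_b - self.H, mesh_slack + rtol * self.H),
            ("H <= H_max", self.H - self.H_max, rtol * self.H_max + mesh_slack),
            ("H_max <= L_max", self.H_max - self.L_max, rtol * self.L_max + mesh_slack),
            ("D_max <= L_max", self.D_max - self.L_max, rtol * self.L_max + mesh_slack),
            ("A <= A_closed", self.A - self.A_closed, rtol * self.A_closed + mesh_slack),
            ("V <= V_CH", self.V - self.V_CH, rtol * self.V_CH + mesh_slack),
            ("V_CH <= V_MBS", self.V_CH - self.V_MBS, rtol * self.V_MBS + mesh_slack),
            ("A_CH <= A_MBS", self.A_CH - self.A_MBS, rtol * self.A_MBS + mesh_slack),
        ]
        for name, excess, slack in checks:
            if excess > slack:
                raise MeshError(f"size-metric invariant violated: {name} "
                                f"(excess {excess:.3g})")


def height_metrics(dome: AneurysmDome, plane: NeckPlane) -> tuple[float, float]:
    """``H``: max signed height of dome vertices above the neck plane;
    ``H_max``: max distance from the neck centroid to any dome vertex."""
    heights = plane.signed_height(dome.surface.vertices)
    h = float(heights.max())
    if h <= 0:
        raise MeshError("all dome vertices lie below the neck plane")
    h_max = float(np.linalg.norm(dome.surface.vertices - plane.origin, axis=1).max())
    return h, h_max


def max_dimension(dome: AneurysmDome) -> float:
    """Max pairwise vertex distance, computed on convex-hull vertices."""
    pts = dome.surface.vertices
    if len(pts) < 2:
        raise MeshError("max_dimension requires at least 2 vertices")
    if len(pts) > 16:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:
            pass  # degenerate (planar) input: brute force below
    return float(pdist(pts).max())


def _slice_points(surface, plane: NeckPlane, height: float) -> np.ndarray:
    """Intersection points of the mesh with the plane offset to ``height``."""
    d = plane.signed_height(surface.vertices) - height
    tris = surface.triangles
    td = d[tris]
    pts = []
    verts = surface.vertices
    # edges crossing the plane contribute one interpolated point each
    for i, j in ((0, 1), (1, 2), (2, 0)):
        di, dj = td[:, i], td[:, j]
        crossing = (di * dj) < 0
        if not crossing.any():
            continue
        t = di[crossing] / (di[crossing] - dj[crossing])
        a = verts[tris[crossing, i]]
        b = verts[tris[crossing, j]]
        pts.append(a + t[:, None] * (b - a))
    on_plane = np.abs(d) < 1e-12
    if on_plane.any():
        pts.append(verts[on_plane])
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)


def plane_parallel_diameter(
    dome: AneurysmDome, plane: NeckPlane, n_slices: int = 100
) -> tuple[float, float]:
    """Slice-sweep maximum cross-sectional diameter.

    Slices at heights (k + 1/2) H / n_slices, strictly above the neck
    plane.  Returns ``(D_max, H_b)`` with ties resolved to the lowest
    slice.
    """
    heights = plane.signed_height(dome.surface.vertices)
    h_top = float(heights.max())
    if h_top <= 0:
        raise MeshError("dome has no extent above the neck plane")
    d_max = 0.0
    h_b = 0.0
    found = False
    for k in range(n_slices):
        hk = (k + 0.5) * h_top / n_slices
        pts = _slice_points(dome.surface, plane, hk)
        if len(pts) < 2:
            continue
        found = True
        if len(pts) > 32:
            proj = plane.project_2d(pts)
            try:
                hull = ConvexHull(proj)
                pts = pts[hull.vertices]
            except Exception:
                pass
        dia = float(pdist(pts).max())
        if dia > d_max * (1 + 1e-12):
            d_max = dia
            h_b = hk
    if not found:
        raise MeshError("no plane-parallel slice intersected the dome")
    return d_max, h_b


def assemble_size_metrics(
    dome: AneurysmDome,
    closed: ClosedAneurysm,
    hull_area: float,
    hull_volume: float,
    mbs_radius: float,
    H: float,
    H_max: float,
    L_max: float,
    D_max: float,
    H_b: float,
    *,
    check: bool = True,
) -> SizeMetrics:
    """Populate the #1-#12 record and verify its dimensional inequalities."""
    metrics = SizeMetrics(
        H=H,
        L_max=L_max,
        H_max=H_max,
        D_max=D_max,
        H_b=H_b,
        A=closed.dome_area,
        A_CH=hull_area,
        A_MBS=4.0 * np.pi * mbs_radius**2,
        A_closed=closed.closed_area,
        V=closed.volume,
        V_CH=hull_volume,
        V_MBS=4.0 * np.pi * mbs_radius**3 / 3.0,
    )
    if check:
        metrics.check_invariants()
    return metrics
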
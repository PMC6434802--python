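"""Discrete per-vertex curvature and the ten curvature parameters.

Gaussian curvature is the angle deficit ``(2 pi - sum of incident
angles) / w`` and mean curvature comes from the cotangent-weighted
mean-curvature normal, both with mixed Voronoi vertex areas (the
obtuse-safe variant).  These are the standard discrete operators: the
angle deficit satisfies Gauss-Bonnet exactly on closed meshes, and both
converge to the smooth curvatures under refinement.

Statistics are computed over *interior* vertices only — vertices on, or
sharing an edge with, the neck boundary loop are masked out, since
curvature is undefined at the artificial neck crease.  Area-weighted
means over the interior are combined with the full dome area to
estimate the L2-norm integrals (MLN, GLN), which avoids the downward
bias of simply dropping the boundary ring from the integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import AneurysmDome, MeshError, TriangleSurface

__all__ = ["CurvatureField", "CurvatureMetrics", "curvature_field", "curvature_metrics"]


@dataclass
class CurvatureField:
    """Per-vertex curvature data of a dome (or closed) surface.

    ``M`` is signed mean curvature in 1/mm (positive = convex outward),
    ``K`` Gaussian curvature in 1/mm^2, ``w`` the mixed Voronoi vertex
    area in mm^2 (summing to the total surface area), ``interior`` the
    mask of vertices whose curvature enters the statistics.
    """

    M: np.ndarray
    K: np.ndarray
    w: np.ndarray
    interior: np.ndarray
    barycentric_fallback: bool = False

    @property
    def total_area(self) -> float:
        return float(self.w.sum())


@dataclass
class CurvatureMetrics:
    """Parameters #31-#40."""

    MAA: float      # area-weighted mean of M, 1/mm
    absMAA: float   # area-weighted mean of |M|, 1/mm
    MSD: float      # area-weighted SD of M, 1/mm
    HMC: float      # % excess of absMAA over 1/r_MBS
    MLN: float      # L2-norm of M / (4 pi), dimensionless
    GAA: float      # area-weighted mean of K, 1/mm^2
    absGAA: float   # area-weighted mean of |K|, 1/mm^2
    GSD: float      # area-weighted SD of K, 1/mm^2
    HGC: float      # % excess of absGAA over 1/r_MBS^2
    GLN: float      # sqrt(A * integral K^2 dA) / (4 pi), dimensionless


def _corner_angles_and_cotans(surface: TriangleSurface):
    c = surface.triangle_corners
    angles = np.empty((len(c), 3))
    cotans = np.empty((len(c), 3))
    for k in range(3):
        u = c[:, (k + 1) % 3] - c[:, k]
        v = c[:, (k + 2) % 3] - c[:, k]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        dot = np.einsum("ij,ij->i", u, v)
        angles[:, k] = np.arctan2(cross, dot)
        with np.errstate(divide="ignore", invalid="ignore"):
            cotans[:, k] = np.where(cross > 1e-300, dot / cross, 0.0)
    return angles, cotans


def _mixed_voronoi_areas(surface: TriangleSurface, angles, cotans):
    """Meyer-style mixed areas: Voronoi for non-obtuse triangles, area/2
    at the obtuse corner and area/4 elsewhere otherwise; exactly
    degenerate triangles fall back to barycentric thirds."""
    tris = surface.triangles
    tri_area = surface.triangle_areas
    c = surface.triangle_corners
    n_tri = len(tris)
    contrib = np.empty((n_tri, 3))

    edge_sq = np.empty((n_tri, 3))  # squared length of edge opposite corner k
    for k in range(3):
        e = c[:, (k + 1) % 3] - c[:, (k + 2) % 3]
        edge_sq[:, k] = np.einsum("ij,ij->i", e, e)

    obtuse_corner = np.argmax(angles, axis=1)
    is_obtuse = angles[np.arange(n_tri), obtuse_corner] > np.pi / 2
    degenerate = tri_area < 1e-14

    for k in range(3):
        # Voronoi area at corner k: (|e_j|^2 cot(theta_j) + |e_l|^2 cot(theta_l))/8
        j, l = (k + 1) % 3, (k + 2) % 3
        contrib[:, k] = (edge_sq[:, j] * cotans[:, j] + edge_sq[:, l] * cotans[:, l]) / 8.0
    for k in range(3):
        sel = is_obtuse & ~degenerate
        contrib[sel, k] = np.where(
            obtuse_corner[sel] == k, tri_area[sel] / 2.0, tri_area[sel] / 4.0
        )
        contrib[degenerate, k] = tri_area[degenerate] / 3.0

    w = np.zeros(surface.n_vertices)
    for k in range(3):
        np.add.at(w, tris[:, k], contrib[:, k])
    return w, bool(degenerate.any())


def _vertex_normals(surface: TriangleSurface) -> np.ndarray:
    normals = np.zeros((surface.n_vertices, 3))
    cr = surface.triangle_cross  # area-weighted face normals
    for k in range(3):
        np.add.at(normals, surface.triangles[:, k], cr)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(norm > 0, normals / norm, 0.0)


def _interior_mask(surface: TriangleSurface) -> np.ndarray:
    mask = np.ones(surface.n_vertices, dtype=bool)
    boundary = np.zeros(surface.n_vertices, dtype=bool)
    for loop in surface.boundary_loops:
        boundary[loop] = True
    mask[boundary] = False
    # also drop vertices sharing a triangle with a boundary vertex
    tris = surface.triangles
    touching = boundary[tris].any(axis=1)
    mask[np.unique(tris[touching])] = False
    return mask


def curvature_field(dome) -> CurvatureField:
    """Per-vertex mean and Gaussian curvature of a dome or closed surface."""
    surface = dome.surface if isinstance(dome, AneurysmDome) else dome
    angles, cotans = _corner_angles_and_cotans(surface)
    w, fallback = _mixed_voronoi_areas(surface, angles, cotans)
    tris = surface.triangles
    verts = surface.vertices
    n = surface.n_vertices

    angle_sum = np.zeros(n)
    for k in range(3):
        np.add.at(angle_sum, tris[:, k], angles[:, k])
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(w > 0, (2.0 * np.pi - angle_sum) / w, 0.0)

    # cotangent mean-curvature vector: L_i = sum_j (cot a + cot b)(x_i - x_j)
    L = np.zeros((n, 3))
    for k in range(3):
        i, j = tris[:, (k + 1) % 3], tris[:, (k + 2) % 3]
        ck = cotans[:, k][:, None]
        np.add.at(L, i, ck * (verts[i] - verts[j]))
        np.add.at(L, j, ck * (verts[j] - verts[i]))

    vnormals = _vertex_normals(surface)
    mag = np.linalg.norm(L, axis=1)
    sign = np.sign(np.einsum("ij,ij->i", L, vnormals))
    sign[sign == 0] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(w > 0, sign * mag / (4.0 * w), 0.0)

    return CurvatureField(
        M=M, K=K, w=w, interior=_interior_mask(surface),
        barycentric_fallback=fallback,
    )


def curvature_metrics(
    field: CurvatureField, dome_area: float, mbs_radius: float
) -> CurvatureMetrics:
    """Parameters #31-#40 from the per-vertex field.

    ``dome_area`` is the total (unmasked) dome surface area; the
    bounding-sphere radius sets the reference curvatures for HMC/HGC.
    """
    sel = field.interior
    w = field.w[sel]
    if w.sum() <= 0:
        raise MeshError("no interior vertices with positive area weight")
    M = field.M[sel]
    K = field.K[sel]
    wsum = w.sum()

    maa = float((w * M).sum() / wsum)
    abs_maa = float((w * np.abs(M)).sum() / wsum)
    msd = float(np.sqrt((w * (M - maa) ** 2).sum() / wsum))
    gaa = float((w * K).sum() / wsum)
    abs_gaa = float((w * np.abs(K)).sum() / wsum)
    gsd = float(np.sqrt((w * (K - gaa) ** 2).sum() / wsum))

    mean_m2 = float((w * M**2).sum() / wsum)
    mean_k2 = float((w * K**2).sum() / wsum)
    mln = np.sqrt(dome_area * mean_m2) / (4.0 * np.pi)
    gln = np.sqrt(dome_area * (dome_area * mean_k2)) / (4.0 * np.pi)

    return CurvatureMetrics(
        MAA=maa,
        absMAA=abs_maa,
        MSD=msd,
        HMC=100.0 * (abs_maa * mbs_radius - 1.0),
        MLN=float(mln),
        GAA=gaa,
        absGAA=abs_gaa,
        GSD=gsd,
        HGC=100.0 * (abs_gaa * mbs_radius**2 - 1.0),
        GLN=float(gln),
    )
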
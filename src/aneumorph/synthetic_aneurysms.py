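"""Synthetic aneurysm fixtures and cohorts with analytic ground truth.

Two roles: (i) single shapes with closed-form (spherical cap) or
high-resolution-quadrature (ellipsoid cap) truth records, for verifying
the parameter computations; (ii) cohorts of perturbed reconstructions
of base shapes, emulating the inter-group variability of segmentation
pipelines (global over/under-sizing, surface noise, smoothing, and
neck-placement shifts), for exercising the uncertainty statistics.

All randomness flows through one seeded generator per call; results are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import Delaunay

from .mesh_core import AneurysmDome, MeshError, TriangleSurface

__all__ = [
    "CapSpec",
    "PerturbationSpec",
    "make_spherical_cap",
    "make_ellipsoid_cap",
    "add_undulation",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CapSpec:
    """Spherical-cap dome: base diameter, height, target edge length (mm)."""

    diameter: float = 5.0
    height: float = 4.0
    edge_length: float = 0.2

    def __post_init__(self):
        if self.diameter <= 0 or self.height <= 0 or self.edge_length <= 0:
            raise ValueError("diameter, height and edge length must be positive")
        if self.edge_length > self.diameter / 4:
            raise ValueError("edge length too coarse (must be <= diameter/4)")

    @property
    def sphere_radius(self) -> float:
        a = self.diameter / 2.0
        return (a * a + self.height * self.height) / (2.0 * self.height)

    def truth(self) -> dict:
        """Closed-form values of the analytically known parameters."""
        d, h = self.diameter, self.height
        a = d / 2.0
        R = self.sphere_radius
        taller_than_hemisphere = h > R
        area = 2.0 * np.pi * R * h
        base_area = np.pi * a * a
        volume = np.pi * h * h * (R - h / 3.0)
        if taller_than_hemisphere:
            mbs_radius = R
            l_max = 2.0 * R
            d_max = 2.0 * R
            h_b = h - R
        else:
            mbs_radius = a
            l_max = d
            d_max = d
            h_b = 0.0
        return {
            "kind": "spherical_cap",
            "sphere_radius": R,
            "H": h,
            "L_max": l_max,
            "H_max": max(h, a),
            "D_max": d_max,
            "H_b": h_b,
            "A": area,
            "A_closed": area + base_area,
            "V": volume,
            "A_CH": area + base_area,  # a cap is convex
            "V_CH": volume,
            "mbs_radius": mbs_radius,
            "A_MBS": 4.0 * np.pi * mbs_radius**2,
            "V_MBS": 4.0 * np.pi * mbs_radius**3 / 3.0,
            "D_neck_min": d,
            "D_neck_max": d,
            "P_neck": np.pi * d,
            "A_neck": base_area,
            "mean_curvature": 1.0 / R,
            "gaussian_curvature": 1.0 / R**2,
        }


def _disk_triangulation(radii: np.ndarray, counts: np.ndarray):
    """2D points on concentric rings (apex at origin) plus their Delaunay
    triangulation with consistent counter-clockwise orientation."""
    pts = [np.zeros((1, 2))]
    for j, (rho, m) in enumerate(zip(radii, counts)):
        # stagger successive rings for better-shaped triangles
        phi = 2.0 * np.pi * (np.arange(m) + 0.5 * (j % 2)) / m
        pts.append(np.column_stack([rho * np.cos(phi), rho * np.sin(phi)]))
    pts2d = np.vstack(pts)
    tri = Delaunay(pts2d)
    simplices = tri.simplices.copy()
    c = pts2d[simplices]
    signed = (c[:, 1, 0] - c[:, 0, 0]) * (c[:, 2, 1] - c[:, 0, 1]) - (
        c[:, 1, 1] - c[:, 0, 1]
    ) * (c[:, 2, 0] - c[:, 0, 0])
    simplices[signed < 0] = simplices[signed < 0][:, ::-1]
    # drop exactly degenerate slivers (collinear points on the rim circle)
    simplices = simplices[np.abs(signed) > 1e-14]
    return pts2d, simplices


def _cap_rings(R: float, theta_rim: float, edge: float):
    n_rings = max(3, int(round(R * theta_rim / edge)))
    thetas = theta_rim * np.arange(1, n_rings + 1) / n_rings
    counts = np.maximum(
        6, np.round(2.0 * np.pi * R * np.sin(thetas) / edge).astype(int)
    )
    return thetas, counts


def make_spherical_cap(spec: CapSpec) -> tuple[AneurysmDome, dict]:
    """Isotropically triangulated spherical-cap dome.

    Every vertex lies exactly on the analytic sphere and the rim circle
    is evenly sampled; the boundary loop is the rim.  Returns the dome
    and its closed-form truth record.
    """
    R = spec.sphere_radius
    h = spec.height
    theta_rim = float(np.arccos(np.clip((R - h) / R, -1.0, 1.0)))
    thetas, counts = _cap_rings(R, theta_rim, spec.edge_length)
    # azimuthal-equidistant projection: ring radius rho = R * theta
    pts2d, simplices = _disk_triangulation(R * thetas, counts)
    rho = np.linalg.norm(pts2d, axis=1)
    theta = rho / R
    phi = np.arctan2(pts2d[:, 1], pts2d[:, 0])
    center_z = h - R
    verts = np.column_stack(
        [
            R * np.sin(theta) * np.cos(phi),
            R * np.sin(theta) * np.sin(phi),
            center_z + R * np.cos(theta),
        ]
    )
    # rim vertices: place exactly at z = 0
    on_rim = np.isclose(theta, theta_rim, atol=1e-12)
    verts[on_rim, 2] = 0.0
    surface = TriangleSurface(verts, simplices, deduplicate=True)
    dome = AneurysmDome(surface=surface)
    return dome, spec.truth()


def _spheroid_cap_area(a: float, c: float, z0: float, n: int = 4096) -> float:
    """Lateral area of x^2/a^2 + y^2/a^2 + z^2/c^2 = 1 above z = z0
    (axisymmetric case), by composite-trapezoid quadrature."""
    z = z0 + (np.arange(n) + 0.5) * (c - z0) / n  # midpoints, avoid pole
    rho = a * np.sqrt(np.clip(1.0 - z**2 / c**2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        drho = np.where(
            rho > 0,
            (-(a / c**2) * z) / np.sqrt(np.clip(1 - z**2 / c**2, 1e-300, None)),
            0.0,
        )
    integrand = 2.0 * np.pi * rho * np.sqrt(1.0 + drho**2)
    return float(integrand.sum() * (c - z0) / n)


def make_ellipsoid_cap(
    a: float,
    b: float,
    c: float,
    cut_height: float = 0.0,
    edge_length: float = 0.1,
) -> tuple[AneurysmDome, dict]:
    """Ellipsoid dome above the plane z = ``cut_height``.

    Built by anisotropically scaling a unit-sphere cap, so the cut is a
    planar ellipse; the truth record is numeric (quadrature) and tagged
    as such.
    """
    if not (-c < cut_height < c):
        raise ValueError("cut plane must intersect the ellipsoid interior")
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    z0 = cut_height / c  # cut height on the unit sphere
    scale = min(a, b, c)
    unit_edge = edge_length / scale
    theta_rim = float(np.arccos(z0))
    thetas, counts = _cap_rings(1.0, theta_rim, unit_edge)
    pts2d, simplices = _disk_triangulation(thetas, counts)
    rho = np.linalg.norm(pts2d, axis=1)
    phi = np.arctan2(pts2d[:, 1], pts2d[:, 0])
    verts = np.column_stack(
        [
            a * np.sin(rho) * np.cos(phi),
            b * np.sin(rho) * np.sin(phi),
            c * np.cos(rho),
        ]
    )
    on_rim = np.isclose(rho, theta_rim, atol=1e-12)
    verts[on_rim, 2] = cut_height
    surface = TriangleSurface(verts, simplices, deduplicate=True)
    dome = AneurysmDome(surface=surface)

    # volume above the cut: integral of pi a b (1 - z^2/c^2) dz
    zc = cut_height
    volume = np.pi * a * b * ((c - zc) - (c**3 - zc**3) / (3.0 * c**2))
    truth = {
        "kind": "ellipsoid_cap",
        "semi_axes": (a, b, c),
        "cut_height": cut_height,
        "H": c - cut_height,
        "V": float(volume),
    }
    if abs(a - b) < 1e-12:
        truth["A"] = _spheroid_cap_area(a, c, cut_height)
    return dome, truth


def add_undulation(
    dome: AneurysmDome,
    n_blebs: int = 3,
    amplitude: float = 0.2,
    seed: int = 0,
    support_radius: Optional[float] = None,
) -> AneurysmDome:
    """Add smooth radial bumps (compact-support cosine profile) at random
    interior locations; negative amplitude makes dents.  The boundary
    loop is never displaced."""
    if n_blebs == 0 or amplitude == 0:
        return AneurysmDome(
            surface=dome.surface.copy(),
            parent_vessel_diameter=dome.parent_vessel_diameter,
            aneurysm_id=dome.aneurysm_id,
            group_id=dome.group_id,
        )
    rng = np.random.default_rng(seed)
    surface = dome.surface
    verts = surface.vertices.copy()
    extent = np.ptp(verts, axis=0).max()
    if abs(amplitude) >= extent / 3:
        raise ValueError("bleb amplitude too large relative to dome size")
    if support_radius is None:
        support_radius = extent / 5.0
    boundary = dome.neck_points
    from .curvature_metrics import _vertex_normals

    normals = _vertex_normals(surface)
    candidates = np.nonzero(
        np.min(
            np.linalg.norm(verts[:, None, :] - boundary[None, ::4, :], axis=2), axis=1
        )
        > support_radius
    )[0]
    if len(candidates) == 0:
        raise MeshError("no interior vertex far enough from the boundary for a bleb")
    for _ in range(n_blebs):
        center = verts[rng.choice(candidates)]
        r = np.linalg.norm(verts - center, axis=1)
        inside = r < support_radius
        bump = 0.5 * amplitude * (1.0 + np.cos(np.pi * r[inside] / support_radius))
        verts[inside] += bump[:, None] * normals[inside]
    new_surface = TriangleSurface(verts, surface.triangles, deduplicate=False)
    return AneurysmDome(
        surface=new_surface,
        parent_vessel_diameter=dome.parent_vessel_diameter,
        aneurysm_id=dome.aneurysm_id,
        group_id=dome.group_id,
    )


def shape_gallery(
    n_shapes: int = 24, seed: int = 0, edge_factor: float = 1 / 12
) -> list[AneurysmDome]:
    """Diverse tie-free gallery of synthetic domes for index studies.

    Mixes spherical caps of varying height ratio and ellipsoid caps of
    varying elongation, each decorated with mild random undulations, so
    every parameter — including the convexity-sensitive ones — takes a
    distinct continuous value on every shape.
    """
    rng = np.random.default_rng(seed)
    domes = []
    for i in range(n_shapes):
        if i % 2 == 0:
            d = rng.uniform(2.5, 6.0)
            h = rng.uniform(0.45 * d, 1.3 * d)
            dome, _ = make_spherical_cap(CapSpec(d, h, edge_length=d * edge_factor))
            extent = d
        else:
            a, b = rng.uniform(0.9, 2.2, size=2)
            c = rng.uniform(1.0, 2.8)
            cut = rng.uniform(-0.4, 0.4) * c
            dome, _ = make_ellipsoid_cap(
                a, b, c, cut, edge_length=min(a, b, c) * 2 * edge_factor
            )
            extent = 2 * max(a, b)
        # mild dents keep UI/CR strictly off their convex-limit values
        dome = add_undulation(
            dome,
            n_blebs=int(rng.integers(1, 4)),
            amplitude=-rng.uniform(0.02, 0.1) * extent,
            seed=int(rng.integers(2**31)),
        )
        dome.aneurysm_id = f"shape{i:02d}"
        domes.append(dome)
    return domes


@dataclass(frozen=True)
class PerturbationSpec:
    """Inter-group variability model for a simulated cohort.

    ``scale_sd`` is the SD of a global scale factor Normal(1, sd)
    (over/under-segmentation); ``normal_noise_sd`` (mm) drives iid
    vertex displacement along normals; Taubin-style smoothing runs for
    a per-group iteration count drawn uniformly from
    ``smoothing_iterations``; the neck plane is tilted by
    Normal(0, neck_tilt_sd) degrees and offset by
    Normal(0, neck_offset_sd) mm with the boundary re-cut.
    """

    n_groups: int = 25
    scale_sd: float = 0.05
    normal_noise_sd: float = 0.05
    smoothing_iterations: tuple[int, int] = (0, 10)
    neck_tilt_sd: float = 3.0
    neck_offset_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        for name in ("scale_sd", "normal_noise_sd", "neck_tilt_sd", "neck_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["smoothing_iterations"] = list(self.smoothing_iterations)
        return d


def _taubin_smooth(
    verts: np.ndarray,
    triangles: np.ndarray,
    fixed: np.ndarray,
    iterations: int,
    lam: float = 0.5,
    mu: float = -0.53,
) -> np.ndarray:
    """Volume-preserving two-step (shrink/inflate) Laplacian smoothing
    with uniform weights; ``fixed`` vertices do not move."""
    if iterations <= 0:
        return verts
    n = len(verts)
    edges = np.vstack(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    deg = np.zeros(n)
    np.add.at(deg, edges[:, 0], 1.0)
    np.add.at(deg, edges[:, 1], 1.0)
    deg[deg == 0] = 1.0
    v = verts.copy()
    for _ in range(iterations):
        for factor in (lam, mu):
            acc = np.zeros_like(v)
            np.add.at(acc, edges[:, 0], v[edges[:, 1]])
            np.add.at(acc, edges[:, 1], v[edges[:, 0]])
            lap = acc / deg[:, None] - v
            lap[fixed] = 0.0
            v = v + factor * lap
    return v


def _recut_neck(
    surface: TriangleSurface,
    neck_points: np.ndarray,
    tilt_deg: float,
    tilt_azimuth: float,
    offset: float,
    base_normal: np.ndarray,
    clearance: float = 0.02,
) -> TriangleSurface:
    """Slice the dome with a tilted/offset plane and keep the upper part.

    The plane is raised until it clears the existing boundary loop, so
    the re-cut surface has exactly one (new) boundary loop.
    """
    import trimesh

    n = base_normal / np.linalg.norm(base_normal)
    # tilt the normal by tilt_deg about an in-plane axis at the given azimuth
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, seed_vec)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    axis = np.cos(tilt_azimuth) * u + np.sin(tilt_azimuth) * v
    ang = np.deg2rad(tilt_deg)
    n_new = (
        n * np.cos(ang)
        + np.cross(axis, n) * np.sin(ang)
        + axis * np.dot(axis, n) * (1.0 - np.cos(ang))
    )
    n_new /= np.linalg.norm(n_new)
    centroid = neck_points.mean(axis=0)
    # raise the plane above every old boundary point, plus the random offset
    rim_height = (neck_points - centroid) @ n_new
    origin = centroid + n_new * (rim_height.max() + clearance + max(offset, 0.0))
    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.triangles, process=False
    )
    cut = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=n_new, plane_origin=origin, cap=False
    )
    if cut is None or len(cut.faces) == 0:
        raise MeshError("neck re-cut removed the entire dome")
    return TriangleSurface(np.asarray(cut.vertices), np.asarray(cut.faces))


def simulate_cohort(
    base_domes: Sequence[AneurysmDome],
    spec: PerturbationSpec,
) -> list[AneurysmDome]:
    """Per-group perturbed reconstructions of each base dome.

    For every group: draw a global scale factor, displace vertices along
    their normals, smooth, and re-cut the neck with a tilted/offset
    plane.  Group order and draws are deterministic under the seed.
    Perturbations that break the dome topology are retried up to 5
    times, then raised.
    """
    from .curvature_metrics import _vertex_normals

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.smoothing_iterations
    out = []
    for dome in base_domes:
        for g in range(spec.n_groups):
            last_err = None
            for _attempt in range(5):
                try:
                    out.append(
                        _perturb_once(dome, spec, rng, lo, hi, g, _vertex_normals)
                    )
                    break
                except MeshError as exc:
                    last_err = exc
            else:
                raise MeshError(
                    f"perturbation failed 5 times for {dome.aneurysm_id} "
                    f"group {g}: {last_err}"
                )
    return out


def _perturb_once(dome, spec, rng, lo, hi, g, vertex_normals):
    surface = dome.surface
    scale = rng.normal(1.0, spec.scale_sd) if spec.scale_sd > 0 else 1.0
    if scale <= 0.1:
        raise MeshError("drew a non-physical scale factor")
    verts = surface.vertices * scale
    triangles = surface.triangles

    boundary_mask = np.zeros(len(verts), dtype=bool)
    boundary_mask[dome.neck_loop] = True

    if spec.normal_noise_sd > 0:
        normals = vertex_normals(surface)
        noise = rng.normal(0.0, spec.normal_noise_sd, size=len(verts))
        noise[boundary_mask] = 0.0
        verts = verts + noise[:, None] * normals

    iters = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    if iters > 0:
        verts = _taubin_smooth(verts, triangles, boundary_mask, iters)

    new_surface = TriangleSurface(verts, triangles, deduplicate=False)

    if spec.neck_tilt_sd > 0 or spec.neck_offset_sd > 0:
        tilt = abs(rng.normal(0.0, spec.neck_tilt_sd))
        azimuth = rng.uniform(0.0, 2.0 * np.pi)
        offset = rng.normal(0.0, spec.neck_offset_sd)
        new_surface = _recut_neck(
            new_surface,
            new_surface.vertices[dome.neck_loop],
            tilt,
            azimuth,
            offset,
            _base_plane_normal(dome),
        )

    return AneurysmDome(
        surface=new_surface,
        parent_vessel_diameter=dome.parent_vessel_diameter,
        aneurysm_id=dome.aneurysm_id,
        group_id=f"g{g:03d}",
    )


def _base_plane_normal(dome: AneurysmDome) -> np.ndarray:
    """Unit normal of the best-fit plane of the current neck loop."""
    pts = dome.neck_points
    rel = pts - pts.mean(axis=0)
    normal = np.linalg.svd(rel, full_matrices=False)[2][2]
    heights = (dome.surface.vertices - pts.mean(axis=0)) @ normal
    return normal if heights.mean() >= 0 else -normal


def write_cohort(
    domes: Sequence[AneurysmDome],
    outdir,
    spec: Optional[PerturbationSpec] = None,
    truths: Optional[dict] = None,
) -> dict:
    """Write cohort meshes as STL plus a manifest JSON; returns the manifest."""
    from pathlib import Path

    from .mesh_core import write_mesh

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for dome in domes:
        name = f"{dome.aneurysm_id}_{dome.group_id}.stl"
        write_mesh(dome.surface, outdir / name)
        entries.append(
            {
                "aneurysm": dome.aneurysm_id,
                "group": dome.group_id,
                "file": name,
                "parent_vessel_diameter": dome.parent_vessel_diameter,
            }
        )
    manifest = {
        "meshes": entries,
        "perturbation": spec.as_dict() if spec is not None else None,
        "truths": truths,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
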
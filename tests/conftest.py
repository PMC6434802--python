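"""Shared fixtures: analytic domes and precomputed parameter records."""

import numpy as np
import pytest

from aneumorph import (
    AneurysmDome,
    CapSpec,
    TriangleSurface,
    compute_parameters,
    make_spherical_cap,
)


@pytest.fixture(scope="session")
def hemisphere():
    """Refined unit-hemisphere dome (R=1, rim in z=0) with truth record."""
    dome, truth = make_spherical_cap(CapSpec(diameter=2.0, height=1.0, edge_length=0.05))
    return dome, truth


@pytest.fixture(scope="session")
def hemisphere_record(hemisphere):
    dome, truth = hemisphere
    dome = AneurysmDome(
        surface=dome.surface, parent_vessel_diameter=2.0, aneurysm_id="hemi"
    )
    return compute_parameters(dome), truth


@pytest.fixture(scope="session")
def cap54():
    """The 5 mm x 4 mm spherical-cap phantom at 0.2 mm resolution."""
    return make_spherical_cap(CapSpec(diameter=5.0, height=4.0, edge_length=0.2))


@pytest.fixture(scope="session")
def cap54_record(cap54):
    dome, truth = cap54
    return compute_parameters(dome), truth


def make_cube():
    """Closed unit cube (8 vertices, 12 outward-oriented triangles)."""
    v = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
    )
    f = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x = 0, normal -x
            [4, 6, 7], [4, 7, 5],  # x = 1, normal +x
            [0, 4, 5], [0, 5, 1],  # y = 0
            [2, 3, 7], [2, 7, 6],  # y = 1
            [0, 2, 6], [0, 6, 4],  # z = 0
            [1, 5, 7], [1, 7, 3],  # z = 1
        ]
    )
    return TriangleSurface(v, f)


def make_square_pyramid(apex_height=1.0):
    """Open pyramid dome over the unit square rim [0,1]^2 at z=0."""
    v = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0.5, 0.5, apex_height]],
        dtype=float,
    )
    f = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
    return AneurysmDome(surface=TriangleSurface(v, f))


@pytest.fixture(scope="session")
def cube():
    return make_cube()


def random_rotation(rng):
    """Haar-random rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
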
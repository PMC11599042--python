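"""Shared fixtures: analytic surfaces and their curvature maps.

Everything is generated in memory at collection time; no stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

import bscrmap as b


@pytest.fixture(scope="session")
def flat_map():
    """500x500 µm flat height map, 2 µm pixels."""
    return b.HeightMap(np.zeros((251, 251)), pixel_size=2.0)


@pytest.fixture(scope="session")
def bowl_surface():
    """Single spherical micro-bowl, sphere radius 32 µm (kappa 31.25 mm^-1),
    aperture 62 µm, grid-aligned centre at (100, 100) µm, 1 µm pixels."""
    hm, info = b.make_surface(
        b.SurfaceSpec(
            kind="microbowl_array",
            extent=(200.0, 200.0),
            pixel_size=1.0,
            radius=32.0,
            aperture=62.0,
            pitch=200.0,
        )
    )
    return hm, info


@pytest.fixture(scope="session")
def bowl_array_maps():
    """Bowl lattice (R=32, aperture 60, pitch 100) with its motif/BSCR maps."""
    hm, _ = b.make_surface(
        b.SurfaceSpec(
            kind="microbowl_array",
            extent=(400.0, 400.0),
            pixel_size=2.0,
            radius=32.0,
            aperture=60.0,
            pitch=100.0,
        )
    )
    motif, bscr, summary = b.map_surface(hm, b.CurvatureParams())
    return hm, motif, bscr, summary


def sphere_bowl_height(rho: np.ndarray, radius: float, half_aperture: float) -> np.ndarray:
    """Analytic spherical-cap pit profile used by make_surface: z <= 0 inside
    the aperture, following the sphere of the given radius."""
    rim = np.sqrt(radius**2 - half_aperture**2)
    return np.where(rho < half_aperture, rim - np.sqrt(radius**2 - np.minimum(rho, half_aperture) ** 2), 0.0)


def circumradius_3pt(p1, p2, p3) -> float:
    """Independent circumradius oracle: solve the circle equation
    x^2 + y^2 + D x + E y + F = 0 through three points by linear algebra."""
    pts = np.array([p1, p2, p3], dtype=float)
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(3)])
    rhs = -(pts[:, 0] ** 2 + pts[:, 1] ** 2)
    D, E, F = np.linalg.solve(A, rhs)
    cx, cy = -D / 2.0, -E / 2.0
    return float(np.sqrt(cx**2 + cy**2 - F))
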
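"""Shared fixtures: synthetic phantoms, polygon factories, processed bones.

Expensive artifacts (the 80k-face mesh and its decimation, fully processed
specimens) are session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from osteogeom.cli import RunConfig, process_specimen
from osteogeom.mesh_prep import TriangleMesh, decimate
from osteogeom.synthetic import circular_tube_spec, default_spec, generate_bone


def regular_polygon(n: int, radius: float = 1.0, center=(0.0, 0.0),
                    phase: float = 0.0) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


def ellipse_polygon(a: float, b: float, n: int = 4096, center=(0.0, 0.0),
                    rotation: float = 0.0) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n) / n
    x, y = a * np.cos(ang), b * np.sin(ang)
    c, s = np.cos(rotation), np.sin(rotation)
    return np.column_stack([center[0] + c * x - s * y,
                            center[1] + s * x + c * y])


def random_star_annulus(rng: np.random.Generator, n: int = 200):
    """A nested pair of star-shaped (about the origin) random polygons."""
    ang = 2.0 * np.pi * np.arange(n) / n
    r_out = 10.0 * np.ones(n)
    for k in range(2, 6):
        amp = rng.uniform(0.0, 0.8)
        phase = rng.uniform(0.0, 2 * np.pi)
        r_out += amp * np.cos(k * ang + phase)
    frac = rng.uniform(0.35, 0.6) + 0.1 * np.cos(
        rng.integers(2, 5) * ang + rng.uniform(0, 2 * np.pi))
    r_in = r_out * np.clip(frac, 0.2, 0.8)
    outer = np.column_stack([r_out * np.cos(ang), r_out * np.sin(ang)])
    inner = np.column_stack([r_in * np.cos(ang), r_in * np.sin(ang)])
    return outer, inner


def build_solid_cylinder(radius: float = 10.0, length: float = 400.0,
                         n_rings: int = 17, n_angular: int = 32) -> TriangleMesh:
    """Watertight solid cylinder (no cavity), fan-capped ends."""
    t = np.linspace(0.0, length, n_rings)
    phi = 2.0 * np.pi * np.arange(n_angular) / n_angular
    rings = [np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                              np.full(n_angular, z)]) for z in t]
    verts = np.vstack(rings + [np.array([[0.0, 0.0, 0.0]]),
                               np.array([[0.0, 0.0, length]])])
    bot, top = len(verts) - 2, len(verts) - 1
    faces = []
    for i in range(n_rings - 1):
        for j in range(n_angular):
            a, b = i * n_angular + j, i * n_angular + (j + 1) % n_angular
            c, d = a + n_angular, b + n_angular
            faces.append((a, b, d))
            faces.append((a, d, c))
    for j in range(n_angular):
        a, b = j, (j + 1) % n_angular
        faces.append((bot, b, a))
        m = (n_rings - 1) * n_angular
        faces.append((top, m + a, m + b))
    return TriangleMesh(verts, np.asarray(faces))


@pytest.fixture(scope="session")
def tube_spec():
    return circular_tube_spec(outer_radius=15.0, inner_radius=10.0,
                              biomechanical_length=400.0)


@pytest.fixture(scope="session")
def tube_bone(tube_spec):
    return generate_bone(tube_spec)


@pytest.fixture(scope="session")
def default_bone():
    return generate_bone(default_spec())


@pytest.fixture(scope="session")
def big_spec():
    return default_spec(n_rings=160, n_angular=128)


@pytest.fixture(scope="session")
def big_bone(big_spec):
    bone = generate_bone(big_spec)
    assert bone.mesh.n_faces >= 80000
    return bone


@pytest.fixture(scope="session")
def decimated_mesh(big_bone):
    return decimate(big_bone.mesh, 20000)


@pytest.fixture(scope="session")
def processed_tube(tube_spec, tube_bone):
    sections, props = process_specimen(tube_bone, RunConfig())
    return tube_spec, sections, props


@pytest.fixture(scope="session")
def processed_default(default_bone):
    sections, props = process_specimen(default_bone, RunConfig())
    return default_bone, sections, props
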
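"""Diaphyseal sampling: biomechanical length, cross-section extraction,
contour classification, and equiangular semilandmark placement.

Levels are fractions of the biomechanical length (BL) measured from the
distal end (0 = distal origin, defined as the condyle-landmark midpoint
projected onto the long axis).  The default configuration samples 60 evenly
spaced sections on [0.20, 0.80] BL and places 21 semilandmarks per contour
on equiangular rays from the medullary-cavity centroid, ray 0 along +x
(lateral), counterclockwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely

from .csg import polygon_area, polygon_centroid
from .errors import SamplingError, SlicingError, ValidationError
from .mesh_prep import AnatomicalLandmarks, BoneSpecimen, TriangleMesh

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingConfig",
    "Contour",
    "CrossSection",
    "biomechanical_length",
    "section_levels",
    "slice_mesh_plane",
    "slice_at_level",
    "medullary_centroid",
    "sample_semilandmarks",
    "radial_thickness",
    "extract_sections",
]

#: Fraction of the periosteal area below which a loop is treated as mesh noise.
SLIVER_AREA_FRACTION = 0.01


@dataclass(frozen=True)
class SamplingConfig:
    """Where and how densely the diaphysis is sampled."""

    n_sections: int = 60
    range_lo: float = 0.20
    range_hi: float = 0.80
    n_semilandmarks: int = 21

    def __post_init__(self):
        if not (0.0 < self.range_lo < self.range_hi < 1.0):
            raise ValidationError("need 0 < range_lo < range_hi < 1")
        if self.n_sections < 2:
            raise ValidationError("n_sections must be >= 2")
        if self.n_semilandmarks < 3:
            raise ValidationError("n_semilandmarks must be >= 3")


@dataclass(frozen=True)
class Contour:
    """A simple closed counterclockwise polyline in the section plane."""

    points: np.ndarray  # (k, 2), first point not repeated
    role: str  # "periosteal" | "endosteal"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValidationError("contour needs >= 3 planar points")
        if polygon_area(pts, signed=True) < 0:
            pts = pts[::-1].copy()
        object.__setattr__(self, "points", pts)
        if self.role not in ("periosteal", "endosteal"):
            raise ValidationError(f"unknown contour role {self.role!r}")

    @property
    def area(self) -> float:
        return polygon_area(self.points)


@dataclass(frozen=True)
class CrossSection:
    """One sampling level: contours plus (optionally) semilandmarks."""

    level: float
    z_height: float
    periosteal: Contour
    endosteal: Contour
    periosteal_slm: np.ndarray | None = None
    endosteal_slm: np.ndarray | None = None
    ray_angles: np.ndarray | None = None
    ray_origin: np.ndarray | None = None
    log: dict = field(default_factory=dict, compare=False)


def biomechanical_length(landmarks: AnatomicalLandmarks) -> float:
    """Mean of the neck-to-medial-condyle and neck-to-lateral-condyle distances."""
    d_med = float(np.linalg.norm(landmarks.neck_point - landmarks.medial_condyle_point))
    d_lat = float(np.linalg.norm(landmarks.neck_point - landmarks.lateral_condyle_point))
    if d_med <= 0 or d_lat <= 0:
        raise ValidationError("zero neck-to-condyle distance")
    return 0.5 * (d_med + d_lat)


def section_levels(config: SamplingConfig) -> np.ndarray:
    """Evenly spaced level fractions from range_lo to range_hi inclusive."""
    return np.linspace(config.range_lo, config.range_hi, config.n_sections)


def distal_origin_z(spec: BoneSpecimen) -> float:
    """z of the distal BL origin: condyle midpoint projected on the long axis.

    Assumes an oriented specimen (long axis = z)."""
    lm = spec.landmarks
    return float(0.5 * (lm.medial_condyle_point[2] + lm.lateral_condyle_point[2]))


# ---------------------------------------------------------------------------
# Mesh-plane intersection
# ---------------------------------------------------------------------------

def slice_mesh_plane(mesh: TriangleMesh, z0: float) -> list[np.ndarray]:
    """Intersect the mesh with the plane z = z0; return closed 2D loops.

    Intersection points are keyed by the mesh edge they lie on, so segments
    from adjacent triangles share endpoints exactly and chain into loops.
    If the plane passes through a vertex the plane is nudged by a tiny
    deterministic epsilon.
    """
    z = mesh.vertices[:, 2]
    span = float(z.max() - z.min())
    eps = 1e-9 * max(span, 1.0)
    zq = z0
    for _ in range(40):  # escape exact vertex hits
        if np.min(np.abs(z - zq)) > eps:
            break
        zq += 3.7 * eps

    side = z > zq
    fs = side[mesh.faces]
    crossing = (fs.any(axis=1)) & (~fs.all(axis=1))
    loops: list[np.ndarray] = []
    if not np.any(crossing):
        return loops

    points: dict[tuple[int, int], np.ndarray] = {}
    adjacency: dict[tuple[int, int], list[tuple[int, int]]] = {}
    verts = mesh.vertices
    for tri in mesh.faces[crossing]:
        cut = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if side[a] == side[b]:
                continue
            key = (int(a), int(b)) if a < b else (int(b), int(a))
            if key not in points:
                va, vb = verts[key[0]], verts[key[1]]
                t = (zq - va[2]) / (vb[2] - va[2])
                points[key] = va[:2] + t * (vb[:2] - va[:2])
            cut.append(key)
        if len(cut) != 2:  # pragma: no cover - guarded by the vertex nudge
            raise SlicingError(f"triangle cut in {len(cut)} edges at z={zq}")
        adjacency.setdefault(cut[0], []).append(cut[1])
        adjacency.setdefault(cut[1], []).append(cut[0])

    visited: set[tuple[int, int]] = set()
    for start in adjacency:
        if start in visited:
            continue
        loop_keys = [start]
        visited.add(start)
        prev, cur = None, start
        closed = False
        while True:
            nxt = [k for k in adjacency[cur] if k != prev]
            if not nxt:
                break
            step = nxt[0]
            if step == start:
                closed = True
                break
            if step in visited:
                break
            loop_keys.append(step)
            visited.add(step)
            prev, cur = cur, step
        if closed and len(loop_keys) >= 3:
            loops.append(np.asarray([points[k] for k in loop_keys]))
        elif not closed:
            logger.debug("open polyline of %d points discarded at z=%g",
                         len(loop_keys), zq)
    return loops


def slice_at_level(
    spec: BoneSpecimen, level: float, *, bl: float | None = None
) -> CrossSection:
    """Extract and classify the periosteal/endosteal contours at one level.

    The specimen must be oriented.  Loops smaller than
    ``SLIVER_AREA_FRACTION`` of the periosteal area are discarded as mesh
    noise (recorded in the section log); exactly two substantive nested loops
    must remain.
    """
    if bl is None:
        bl = biomechanical_length(spec.landmarks)
    z0 = distal_origin_z(spec) + level * bl
    loops = slice_mesh_plane(spec.mesh, z0)
    if not loops:
        raise SlicingError(f"no intersection at level {level:.3f} (z={z0:.2f})")

    areas = [polygon_area(lp) for lp in loops]
    order = np.argsort(areas)[::-1]
    peri_area = areas[order[0]]
    kept, slivers = [], 0
    for i in order:
        if areas[i] < SLIVER_AREA_FRACTION * peri_area:
            slivers += 1
            logger.info("level %.3f: filtered sliver loop (area %.4g)", level, areas[i])
        else:
            kept.append(int(i))
    if len(kept) < 2:
        raise SlicingError(f"no medullary cavity at level {level:.3f}")
    outer_poly = shapely.Polygon(loops[kept[0]])
    nested = [i for i in kept[1:] if outer_poly.contains(shapely.Polygon(loops[i]))]
    if len(kept) > 2 or len(nested) != 1:
        raise SlicingError(
            f"ambiguous section at level {level:.3f}: loop areas "
            f"{[round(areas[i], 3) for i in kept]}"
        )
    return CrossSection(
        level=float(level),
        z_height=z0,
        periosteal=Contour(loops[kept[0]], "periosteal"),
        endosteal=Contour(loops[nested[0]], "endosteal"),
        log={"n_loops": len(loops), "slivers_filtered": slivers},
    )


# ---------------------------------------------------------------------------
# Semilandmarks
# ---------------------------------------------------------------------------

def medullary_centroid(endosteal: Contour) -> np.ndarray:
    """Shoelace-weighted area centroid of the endosteal polygon."""
    return polygon_centroid(endosteal.points)


def _ray_crossings(points: np.ndarray, origin: np.ndarray, angle: float) -> np.ndarray:
    """Sorted positive distances at which the ray crosses the polygon boundary."""
    d = np.array([math.cos(angle), math.sin(angle)])
    p = points - origin
    e = np.roll(p, -1, axis=0) - p
    # perpendicular coordinate of each vertex w.r.t. the ray line; an edge
    # crosses where consecutive values straddle zero (half-open rule, so a
    # vertex exactly on the ray is counted once, never zero or twice)
    c = d[0] * p[:, 1] - d[1] * p[:, 0]
    c1 = np.roll(c, -1)
    crossing = ((c <= 0.0) & (c1 > 0.0)) | ((c1 <= 0.0) & (c > 0.0))
    denom = c1 - c
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (p[:, 0] * e[:, 1] - p[:, 1] * e[:, 0]) / denom  # distance along ray
    ok = crossing & (t > 1e-12)
    return np.sort(t[ok])


def sample_semilandmarks(section: CrossSection, config: SamplingConfig) -> CrossSection:
    """Place equiangular semilandmarks on both contours.

    n rays at angles 2*pi*k/n from +x originate at the medullary centroid;
    semilandmark k is the nearest ray crossing of the endosteal contour and
    the farthest crossing of the periosteal contour, so the pair spans the
    full cortical wall along that ray.
    """
    n = config.n_semilandmarks
    origin = medullary_centroid(section.endosteal)
    angles = 2.0 * np.pi * np.arange(n) / n
    peri = np.empty((n, 2))
    endo = np.empty((n, 2))
    multi = 0
    for k, ang in enumerate(angles):
        te = _ray_crossings(section.endosteal.points, origin, ang)
        tp = _ray_crossings(section.periosteal.points, origin, ang)
        if len(te) == 0 or len(tp) == 0:
            raise SamplingError(
                f"ray {k} (angle {ang:.3f} rad) misses a contour at level "
                f"{section.level:.3f}"
            )
        if len(te) > 1 or len(tp) > 1:
            multi += 1
        d = np.array([math.cos(ang), math.sin(ang)])
        endo[k] = origin + te[0] * d
        peri[k] = origin + tp[-1] * d
    if multi:
        logger.debug("level %.3f: %d rays with multiple crossings",
                     section.level, multi)
    return replace(
        section,
        periosteal_slm=peri,
        endosteal_slm=endo,
        ray_angles=angles,
        ray_origin=origin,
        log={**section.log, "rays_multiple_crossings": multi},
    )


def radial_thickness(section: CrossSection) -> np.ndarray:
    """Per-ray cortical thickness: |periosteal - endosteal| semilandmark."""
    if section.periosteal_slm is None or section.endosteal_slm is None:
        raise SamplingError("semilandmarks not sampled")
    return np.linalg.norm(section.periosteal_slm - section.endosteal_slm, axis=1)


def extract_sections(
    spec: BoneSpecimen, config: SamplingConfig = SamplingConfig()
) -> list[CrossSection]:
    """Slice and semilandmark every level of the sampling configuration."""
    bl = biomechanical_length(spec.landmarks)
    out = []
    for level in section_levels(config):
        section = slice_at_level(spec, float(level), bl=bl)
        out.append(sample_semilandmarks(section, config))
    return out
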
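"""Parametric femur-like phantom meshes with closed-form section properties.

A phantom is a tapered tube whose periosteal and endosteal boundaries are
concentric ellipses at every level, so every downstream quantity (areas,
moments, moduli, perimeters, ray thicknesses) has an exact counterpart.
Two disease modes perturb the healthy geometry:

* ``uniform_endosteal_expansion`` scales the endosteal semi-axes by a factor
  f >= 1 (medullary cavity grows, cortex thins isotropically); closed forms
  remain available.
* ``regional_thinning`` pushes the endosteal boundary outwards preferentially
  on the anterior (+y) and lateral (+x) quadrants within the 20-45% BL band;
  only the ray-thickness ground truth remains closed-form.

The mesh is a watertight wall: outer tube + inner tube + flat annular end
caps placed outside the sampled level range, so any mid-shaft plane section
yields exactly two closed loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ellipe

from .errors import NoClosedFormError, ValidationError
from .mesh_prep import AnatomicalLandmarks, BoneSpecimen, TriangleMesh

__all__ = [
    "SyntheticBoneSpec",
    "AnalyticSectionTruth",
    "default_spec",
    "circular_tube_spec",
    "expansion_for_area_ratio",
    "generate_bone",
    "analytic_truth",
    "analytic_thickness",
    "generate_cohort",
    "ellipse_perimeter",
]

Profile = Callable[[np.ndarray], np.ndarray]

#: Axial extent of the tube in level fractions; caps sit outside [0.05, 0.95]
#: so they never contaminate sampled sections.
TUBE_T_RANGE = (0.02, 0.98)

#: Level band over which regional thinning is concentrated.
THINNING_BAND = (0.20, 0.45)

OSTEO_MODES = ("none", "uniform_endosteal_expansion", "regional_thinning")


def _as_profile(p) -> Profile:
    if callable(p):
        return p
    value = float(p)
    return lambda t: np.full_like(np.asarray(t, dtype=float), value)


@dataclass(frozen=True)
class SyntheticBoneSpec:
    """Parametric description of one phantom bone.

    Semi-axis profiles are functions of the normalized level t in [0, 1]
    (floats are accepted and treated as constant profiles): ``periosteal_a``
    along x (mediolateral), ``periosteal_b`` along y (anteroposterior), and
    the endosteal pair for the inner ellipse.  The disease parameters are
    ``expansion_factor`` (f >= 1, uniform mode) and ``thinning_strength``
    (in [0, 1), regional mode: maximum fraction of the local cortical wall
    removed).
    """

    biomechanical_length: float = 400.0
    n_rings: int = 48
    n_angular: int = 64
    periosteal_a: Profile | float = field(default=15.0)
    periosteal_b: Profile | float = field(default=12.0)
    endosteal_a: Profile | float = field(default=9.3)
    endosteal_b: Profile | float = field(default=7.44)
    osteo_mode: str = "none"
    expansion_factor: float = 1.0
    thinning_strength: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.osteo_mode not in OSTEO_MODES:
            raise ValidationError(f"osteo_mode must be one of {OSTEO_MODES}")
        if self.n_rings < 16 or self.n_angular < 32:
            raise ValidationError("need n_rings >= 16 and n_angular >= 32")
        if self.expansion_factor < 1.0:
            raise ValidationError("expansion_factor must be >= 1")
        if not (0.0 <= self.thinning_strength < 1.0):
            raise ValidationError("thinning_strength must be in [0, 1)")
        if self.biomechanical_length <= 0:
            raise ValidationError("biomechanical_length must be positive")
        for name in ("periosteal_a", "periosteal_b", "endosteal_a", "endosteal_b"):
            object.__setattr__(self, "_" + name, _as_profile(getattr(self, name)))
        # positive cortical thickness everywhere (checked on a fine grid)
        t = np.linspace(0.0, 1.0, 257)
        ap, bp, ae, be = self.semi_axes(t)
        if np.any(ae <= 0) or np.any(be <= 0):
            raise ValidationError("endosteal semi-axes must be positive")
        if np.any(ae >= ap) or np.any(be >= bp):
            raise ValidationError(
                "endosteal ellipse must lie strictly inside the periosteal one"
            )

    def semi_axes(self, t):
        """(a_p, b_p, a_e, b_e) at level(s) t, disease expansion applied."""
        t = np.asarray(t, dtype=float)
        ap = self._periosteal_a(t)
        bp = self._periosteal_b(t)
        f = self.expansion_factor if self.osteo_mode == "uniform_endosteal_expansion" else 1.0
        return ap, bp, f * self._endosteal_a(t), f * self._endosteal_b(t)

    @property
    def group(self) -> str:
        return "healthy" if self.osteo_mode == "none" else "osteoporosis"


@dataclass(frozen=True)
class AnalyticSectionTruth:
    """Exact elliptical-annulus values at one level."""

    level: float
    total_area: float
    medullary_area: float
    cortical_area: float
    Ix: float
    Iy: float
    Imin: float
    Imax: float
    J: float
    Zx: float
    Zy: float
    Zpol: float
    periosteal_perimeter: float
    endosteal_perimeter: float
    thickness: np.ndarray  # per sampling ray, mm


def default_spec(**overrides) -> SyntheticBoneSpec:
    """A gently tapering elliptical phantom with a constant-shape cavity.

    The endosteal ellipse is a fixed scale (0.62) of the periosteal one at
    every level, so MA/TA is constant along the shaft — convenient for
    cohorts constructed to hit a prescribed cortical-area ratio.
    """
    k = 0.62
    ap = lambda t: 15.0 + 6.0 * (t - 0.45) ** 2
    bp = lambda t: 12.0 + 4.0 * (t - 0.45) ** 2
    params = dict(
        periosteal_a=ap,
        periosteal_b=bp,
        endosteal_a=lambda t: k * ap(t),
        endosteal_b=lambda t: k * bp(t),
    )
    params.update(overrides)
    return SyntheticBoneSpec(**params)


def circular_tube_spec(
    outer_radius: float = 15.0,
    inner_radius: float = 10.0,
    biomechanical_length: float = 400.0,
    **overrides,
) -> SyntheticBoneSpec:
    """A straight circular tube (the simplest fully analytic phantom)."""
    return SyntheticBoneSpec(
        biomechanical_length=biomechanical_length,
        periosteal_a=outer_radius,
        periosteal_b=outer_radius,
        endosteal_a=inner_radius,
        endosteal_b=inner_radius,
        **overrides,
    )


def expansion_for_area_ratio(spec: SyntheticBoneSpec, ratio: float) -> float:
    """Endosteal expansion factor f giving CA(osteo)/CA(healthy) = ratio.

    Requires MA/TA to be constant along the shaft (otherwise no single f
    achieves the ratio at every level).
    """
    if not (0.0 < ratio < 1.0):
        raise ValidationError("ratio must be in (0, 1)")
    t = np.linspace(0.0, 1.0, 101)
    ap, bp, ae, be = spec.semi_axes(t)
    q = (ae * be) / (ap * bp)  # MA/TA per level
    if np.ptp(q) > 1e-9:
        raise ValidationError(
            "MA/TA varies along the shaft; no single expansion factor "
            "achieves the requested cortical-area ratio at every level"
        )
    k2 = float(q[0])
    f2 = (1.0 - ratio * (1.0 - k2)) / k2
    f = math.sqrt(f2)
    ape, bpe, aee, bee = spec.semi_axes(t)
    if np.any(f * aee >= ape) or np.any(f * bee >= bpe):
        raise ValidationError("requested ratio would eliminate the cortex")
    return f


# ---------------------------------------------------------------------------
# Regional thinning weights
# ---------------------------------------------------------------------------

def angular_thinning_weight(phi) -> np.ndarray:
    """Weight in [0, 1], concentrated on the anterior (+y) and lateral (+x)
    quadrants, zero on the posterior-medial quadrant, smooth everywhere."""
    phi = np.asarray(phi, dtype=float)
    return np.clip(np.cos(phi), 0.0, None) ** 2 + np.clip(np.sin(phi), 0.0, None) ** 2


def level_thinning_weight(t) -> np.ndarray:
    """Hann bump over the 20-45% BL band, zero outside."""
    t = np.asarray(t, dtype=float)
    lo, hi = THINNING_BAND
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    w = np.cos(0.5 * np.pi * (t - mid) / half) ** 2
    return np.where(np.abs(t - mid) <= half, w, 0.0)


def _ellipse_polar_radius(a, b, phi):
    """Radius of an origin-centred axis-aligned ellipse at polar angle phi."""
    return a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)


def _boundary_radii(spec: SyntheticBoneSpec, t, phi):
    """Polar radii (periosteal, endosteal) at level t and polar angle(s) phi.

    For regional thinning the endosteal boundary moves outwards along the
    ray by the local weight fraction of the cortical wall.
    """
    ap, bp, ae, be = spec.semi_axes(t)
    rp = _ellipse_polar_radius(ap, bp, phi)
    re = _ellipse_polar_radius(ae, be, phi)
    if spec.osteo_mode == "regional_thinning" and spec.thinning_strength > 0:
        s = spec.thinning_strength * angular_thinning_weight(phi) * level_thinning_weight(t)
        re = re + s * (rp - re)
    return rp, re


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------

def generate_bone(spec: SyntheticBoneSpec, specimen_id: str | None = None) -> BoneSpecimen:
    """Build the watertight phantom mesh plus landmarks and group label.

    Construction is deterministic given the spec.  Landmarks are synthetic:
    two condyle points symmetric about the long axis at the distal origin
    (lateral at +x) and a neck point placed so the measured biomechanical
    length equals ``spec.biomechanical_length`` exactly.
    """
    bl = spec.biomechanical_length
    nr, na = spec.n_rings, spec.n_angular
    t = np.linspace(TUBE_T_RANGE[0], TUBE_T_RANGE[1], nr)
    phi = 2.0 * np.pi * np.arange(na) / na

    tt, pp = np.meshgrid(t, phi, indexing="ij")
    rp, re = _boundary_radii(spec, tt, pp)
    cos_p, sin_p = np.cos(pp), np.sin(pp)
    z = (tt * bl)[..., None]
    outer = np.concatenate([(rp * cos_p)[..., None], (rp * sin_p)[..., None], z], axis=2)
    inner = np.concatenate([(re * cos_p)[..., None], (re * sin_p)[..., None], z], axis=2)
    vertices = np.concatenate([outer.reshape(-1, 3), inner.reshape(-1, 3)])

    def O(i, j):
        return i * na + (j % na)

    def I(i, j):
        return nr * na + i * na + (j % na)

    faces = []
    for i in range(nr - 1):
        for j in range(na):
            # outer wall, outward normals
            faces.append((O(i, j), O(i, j + 1), O(i + 1, j + 1)))
            faces.append((O(i, j), O(i + 1, j + 1), O(i + 1, j)))
            # inner wall, normals towards the cavity
            faces.append((I(i, j), I(i + 1, j + 1), I(i, j + 1)))
            faces.append((I(i, j), I(i + 1, j), I(i + 1, j + 1)))
    m = nr - 1
    for j in range(na):
        # bottom cap (-z) and top cap (+z)
        faces.append((O(0, j), I(0, j), I(0, j + 1)))
        faces.append((O(0, j), I(0, j + 1), O(0, j + 1)))
        faces.append((O(m, j), I(m, j + 1), I(m, j)))
        faces.append((O(m, j), O(m, j + 1), I(m, j + 1)))

    mesh = TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))
    if not mesh.is_watertight():  # pragma: no cover - construction invariant
        raise RuntimeError("internal error: generated mesh is not watertight")

    c = 0.05 * bl
    h = math.sqrt(bl * bl - c * c)
    landmarks = AnatomicalLandmarks(
        neck_point=np.array([0.0, 0.0, h]),
        medial_condyle_point=np.array([-c, 0.0, 0.0]),
        lateral_condyle_point=np.array([c, 0.0, 0.0]),
    )
    if specimen_id is None:
        specimen_id = f"synthetic-{spec.osteo_mode}-{spec.seed}"
    return BoneSpecimen(specimen_id, mesh, landmarks, spec.group,
                        meta={"seed": spec.seed, "osteo_mode": spec.osteo_mode})


# ---------------------------------------------------------------------------
# Closed-form ground truth
# ---------------------------------------------------------------------------

def ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter via the complete elliptic integral E.

    P = 4 a E(m), m = 1 - (b/a)^2 with a >= b; machine precision (the
    circular case reduces to 2 pi R).
    """
    a, b = max(a, b), min(a, b)
    if a <= 0:
        raise ValidationError("semi-axes must be positive")
    return float(4.0 * a * ellipe(1.0 - (b / a) ** 2))


def analytic_thickness(spec: SyntheticBoneSpec, level: float, angles) -> np.ndarray:
    """Exact cortical thickness along rays from the section centre.

    Valid in every mode (thinning is defined radially).  Note: rays originate
    at the geometric centre; for regional thinning the measured medullary
    centroid shifts slightly, so mesh-derived thickness matches this only
    approximately there.
    """
    rp, re = _boundary_radii(spec, float(level), np.asarray(angles, dtype=float))
    return rp - re


def analytic_truth(
    spec: SyntheticBoneSpec, level: float, n_rays: int = 21
) -> AnalyticSectionTruth:
    """Closed-form section properties of the elliptical annulus at ``level``.

    Raises :class:`NoClosedFormError` under active regional thinning, whose
    cross-sections are no longer elliptical (thickness truth stays available
    through :func:`analytic_thickness`).
    """
    if spec.osteo_mode == "regional_thinning" and spec.thinning_strength > 0 \
            and level_thinning_weight(level) > 0:
        raise NoClosedFormError(
            "no closed form for moments under regional thinning; "
            "use analytic_thickness for the thickness ground truth"
        )
    ap, bp, ae, be = (float(v) for v in spec.semi_axes(float(level)))
    ta = math.pi * ap * bp
    ma = math.pi * ae * be
    ix = math.pi / 4.0 * (ap * bp**3 - ae * be**3)
    iy = math.pi / 4.0 * (ap**3 * bp - ae**3 * be)
    j = ix + iy
    angles = 2.0 * np.pi * np.arange(n_rays) / n_rays
    return AnalyticSectionTruth(
        level=float(level),
        total_area=ta,
        medullary_area=ma,
        cortical_area=ta - ma,
        Ix=ix,
        Iy=iy,
        Imin=min(ix, iy),
        Imax=max(ix, iy),
        J=j,
        Zx=ix / bp,
        Zy=iy / ap,
        Zpol=j / max(ap, bp),
        periosteal_perimeter=ellipse_perimeter(ap, bp),
        endosteal_perimeter=ellipse_perimeter(ae, be),
        thickness=analytic_thickness(spec, level, angles),
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _scaled_spec(base: SyntheticBoneSpec, scale: float, **overrides) -> SyntheticBoneSpec:
    """Uniformly scale all radius profiles (and BL) of a spec."""
    ap, bp = base._periosteal_a, base._periosteal_b  # normalized callables
    ae, be = base._endosteal_a, base._endosteal_b
    return replace(
        base,
        biomechanical_length=base.biomechanical_length * scale,
        periosteal_a=lambda t, _f=ap: scale * _f(t),
        periosteal_b=lambda t, _f=bp: scale * _f(t),
        endosteal_a=lambda t, _f=ae: scale * _f(t),
        endosteal_b=lambda t, _f=be: scale * _f(t),
        **overrides,
    )


def generate_cohort(
    n_healthy: int,
    n_osteo: int,
    variation: float,
    seed: int,
    base_spec: SyntheticBoneSpec | None = None,
    osteo_mode: str = "uniform_endosteal_expansion",
    expansion_factor: float | None = None,
    thinning_strength: float = 0.5,
    cortical_area_ratio: float = 0.70,
    truth_levels: Sequence[float] | None = None,
) -> tuple[list[BoneSpecimen], pd.DataFrame]:
    """Simulate a two-group cohort with per-specimen lognormal size jitter.

    ``variation`` is the approximate coefficient of variation of
    cross-sectional areas: each specimen is the base phantom uniformly scaled
    by exp(N(0, variation / 2)) (areas scale with the square of the radius
    jitter), which keeps all radii positive; every osteoporotic specimen shares one disease
    parameter (``expansion_factor``, derived from ``cortical_area_ratio``
    when not given, or ``thinning_strength`` for regional mode).  Returns the
    specimens plus a tidy ground-truth table with one row per
    (specimen, level) carrying the generator parameters and, where closed
    forms exist, the analytic section properties.
    """
    if n_healthy < 2 or n_osteo < 2:
        raise ValidationError("need at least 2 specimens per group")
    if not (0.0 <= variation < 0.2):
        raise ValidationError("variation must be in [0, 0.2)")
    if osteo_mode not in OSTEO_MODES[1:]:
        raise ValidationError("cohort osteo_mode must be a disease mode")
    base = base_spec if base_spec is not None else default_spec()
    if osteo_mode == "uniform_endosteal_expansion" and expansion_factor is None:
        expansion_factor = expansion_for_area_ratio(base, cortical_area_ratio)
    if truth_levels is None:
        truth_levels = np.linspace(0.20, 0.80, 7)

    rng = np.random.default_rng(seed)
    specimens: list[BoneSpecimen] = []
    rows = []
    plan = [("healthy", i) for i in range(n_healthy)] + [
        ("osteoporosis", i) for i in range(n_osteo)
    ]
    for group, i in plan:
        scale = float(rng.lognormal(0.0, 0.5 * variation)) if variation > 0 else 1.0
        if group == "healthy":
            spec_i = _scaled_spec(base, scale, osteo_mode="none", seed=seed)
        elif osteo_mode == "uniform_endosteal_expansion":
            spec_i = _scaled_spec(base, scale, osteo_mode=osteo_mode,
                                  expansion_factor=float(expansion_factor), seed=seed)
        else:
            spec_i = _scaled_spec(base, scale, osteo_mode=osteo_mode,
                                  thinning_strength=thinning_strength, seed=seed)
        sid = f"{group[:4]}-{i:03d}"
        specimens.append(generate_bone(spec_i, specimen_id=sid))
        for level in truth_levels:
            row = {
                "specimen_id": sid,
                "group": group,
                "scale": scale,
                "expansion_factor": (float(expansion_factor)
                                     if group != "healthy"
                                     and osteo_mode == "uniform_endosteal_expansion"
                                     else 1.0),
                "thinning_strength": (thinning_strength
                                      if group != "healthy"
                                      and osteo_mode == "regional_thinning" else 0.0),
                "level": float(level),
            }
            try:
                truth = analytic_truth(spec_i, float(level))
                row.update(
                    total_area=truth.total_area,
                    medullary_area=truth.medullary_area,
                    cortical_area=truth.cortical_area,
                    Ix=truth.Ix, Iy=truth.Iy, J=truth.J,
                    Zx=truth.Zx, Zy=truth.Zy, Zpol=truth.Zpol,
                    periosteal_perimeter=truth.periosteal_perimeter,
                    endosteal_perimeter=truth.endosteal_perimeter,
                    thickness_mean=float(np.mean(truth.thickness)),
                )
            except NoClosedFormError:
                angles = 2.0 * np.pi * np.arange(21) / 21
                thick = analytic_thickness(spec_i, float(level), angles)
                row.update(thickness_mean=float(np.mean(thick)))
            rows.append(row)
    return specimens, pd.DataFrame(rows)
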
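"""Cross-sectional geometry: areas, second moments, section moduli.

All quantities are computed for the annular cortical region bounded by a
periosteal (outer) and an endosteal (inner) contour.  Exact polygon moments
use the Green's-theorem edge formulas; an independent grid-quadrature oracle
(`rasterize_oracle`) is provided for verification.

Conventions
-----------
* Contours are simple closed polylines, counterclockwise, first point not
  repeated at the end.
* Moments (Ix, Iy, Ixy) are reported about axes through the cortical-region
  area centroid, parallel to x (mediolateral) and y (anteroposterior).
* ``theta`` is the angle between the major principal axis and +x, folded
  into (-pi/4, pi/4] (the principal-axis pair is only defined modulo pi/2;
  the reported representative is the one nearest the x axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import shapely

from .errors import GeometryError

__all__ = [
    "SectionProperties",
    "COMPARISON_PROPERTIES",
    "polygon_area",
    "polygon_perimeter",
    "polygon_centroid",
    "cortical_moments",
    "principal_moments",
    "normalize_theta",
    "chord_lengths",
    "section_moduli",
    "section_properties",
    "rasterize_oracle",
]


@dataclass
class SectionProperties:
    """Every scalar property computed for one cross-section.

    Areas in mm^2, lengths in mm, moments in mm^4, moduli in mm^3,
    ``theta`` in radians.
    """

    total_area: float
    medullary_area: float
    cortical_area: float
    periosteal_perimeter: float
    endosteal_perimeter: float
    thickness_min: float
    thickness_mean: float
    thickness_max: float
    centroid_x: float
    centroid_y: float
    Ix: float
    Iy: float
    Ixy: float
    Imin: float
    Imax: float
    J: float
    theta: float
    dx: float
    dy: float
    dx_theta: float
    dy_theta: float
    rmax: float
    Zx: float
    Zy: float
    Zmin: float
    Zmax: float
    Zpol: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Properties entered into cohort-level group comparisons (23 quantities).
COMPARISON_PROPERTIES: tuple[str, ...] = (
    "total_area",
    "medullary_area",
    "cortical_area",
    "periosteal_perimeter",
    "endosteal_perimeter",
    "thickness_min",
    "thickness_mean",
    "thickness_max",
    "Ix",
    "Iy",
    "Ixy",
    "Imin",
    "Imax",
    "J",
    "theta",
    "dx",
    "dy",
    "rmax",
    "Zx",
    "Zy",
    "Zmin",
    "Zmax",
    "Zpol",
)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise GeometryError("polygon needs at least 3 planar points")
    # drop an explicitly repeated closing point
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    return pts


def polygon_area(points, *, signed: bool = False) -> float:
    """Shoelace area of a simple closed polygon.

    The absolute value is returned unless ``signed=True`` (positive for
    counterclockwise orientation).
    """
    pts = _as_points(points)
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    a = 0.5 * float(np.sum(x * y1 - x1 * y))
    return a if signed else abs(a)


def polygon_perimeter(points) -> float:
    """Total edge length of the closed polyline."""
    pts = _as_points(points)
    return float(np.sum(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)))


def polygon_centroid(points) -> np.ndarray:
    """Area (shoelace-weighted) centroid of a simple polygon."""
    pts = _as_points(points)
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cr = x * y1 - x1 * y
    a = 0.5 * np.sum(cr)
    if abs(a) < 1e-300:
        raise GeometryError("degenerate polygon: zero area")
    cx = np.sum((x + x1) * cr) / (6.0 * a)
    cy = np.sum((y + y1) * cr) / (6.0 * a)
    return np.array([cx, cy])


def _ring_integrals(pts: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Signed integrals (A, Sx, Sy, Sxx, Syy, Sxy) over the polygon interior.

    Sx = integral of x dA, Sxx = integral of x^2 dA, Sxy = integral of xy dA,
    etc., all about the coordinate origin; signs follow orientation.
    """
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cr = x * y1 - x1 * y
    a = 0.5 * np.sum(cr)
    sx = np.sum((x + x1) * cr) / 6.0
    sy = np.sum((y + y1) * cr) / 6.0
    sxx = np.sum((x * x + x * x1 + x1 * x1) * cr) / 12.0
    syy = np.sum((y * y + y * y1 + y1 * y1) * cr) / 12.0
    sxy = np.sum((x * y1 + 2.0 * x * y + 2.0 * x1 * y1 + x1 * y) * cr) / 24.0
    return float(a), float(sx), float(sy), float(sxx), float(syy), float(sxy)


def _require_ccw(pts: np.ndarray, label: str) -> np.ndarray:
    if polygon_area(pts, signed=True) <= 0:
        raise GeometryError(f"{label} contour must be counterclockwise")
    return pts


def cortical_moments(periosteal, endosteal):
    """Centroid and second moments of the annulus between two nested contours.

    Both contours must be counterclockwise; the endosteal polygon must lie
    inside the periosteal one.  Returns ``(centroid, Ix, Iy, Ixy)`` with the
    moments about centroidal axes parallel to x and y:
    Ix = integral of y^2 dA, Iy = integral of x^2 dA, Ixy = integral of xy dA.
    """
    po = _require_ccw(_as_points(periosteal), "periosteal")
    en = _require_ccw(_as_points(endosteal), "endosteal")
    outer = shapely.Polygon(po)
    inner = shapely.Polygon(en)
    if not outer.contains(inner):
        raise GeometryError("endosteal contour is not nested inside periosteal")

    ao, sxo, syo, sxxo, syyo, sxyo = _ring_integrals(po)
    ai, sxi, syi, sxxi, syyi, sxyi = _ring_integrals(en)
    a = ao - ai
    sx, sy = sxo - sxi, syo - syi
    sxx, syy, sxy = sxxo - sxxi, syyo - syyi, sxyo - sxyi
    if a <= 0:
        raise GeometryError("cortical region has non-positive area")
    cx, cy = sx / a, sy / a
    # parallel-axis shift to the cortical centroid
    ix = syy - a * cy * cy
    iy = sxx - a * cx * cx
    ixy = sxy - a * cx * cy
    return np.array([cx, cy]), ix, iy, ixy


def principal_moments(Ix: float, Iy: float, Ixy: float) -> tuple[float, float, float]:
    """Eigenvalues of the 2D inertia tensor and the major-axis angle.

    Imin/Imax = (Ix+Iy)/2 -/+ sqrt(((Iy-Ix)/2)^2 + Ixy^2).
    ``theta`` = 0.5 * atan2(2*Ixy, Iy - Ix): the angle from +x to the axis
    about which the moment is Imin, i.e. the major geometric axis of the
    section.  Range (-pi/2, pi/2]; 0 for a fully symmetric section.
    """
    mean = 0.5 * (Ix + Iy)
    half = math.hypot(0.5 * (Iy - Ix), Ixy)
    imin, imax = mean - half, mean + half
    if half <= 1e-12 * max(abs(mean), 1.0):
        theta = 0.0  # symmetric: principal direction undefined
    else:
        theta = 0.5 * math.atan2(2.0 * Ixy, Iy - Ix)
    return imin, imax, theta


def normalize_theta(theta: float) -> float:
    """Fold a principal-axis angle into (-pi/4, pi/4].

    Principal directions are defined modulo pi/2; the reported value is the
    representative closest to the mediolateral axis.
    """
    t = theta
    while t > math.pi / 4:
        t -= math.pi / 2
    while t <= -math.pi / 4:
        t += math.pi / 2
    return t


def chord_lengths(periosteal, centroid, theta: float):
    """Maximum outer-fibre distances of the periosteal contour.

    Returns ``(dx, dy, dx_theta, dy_theta, rmax)`` where dx/dy are maxima of
    |x - cx| / |y - cy| over the periosteal vertices, dx_theta/dy_theta are the
    same after rotating the vertices about the centroid by ``-theta``, and
    rmax is the largest radial distance from the centroid.
    """
    pts = _as_points(periosteal) - np.asarray(centroid, dtype=float)
    dx = float(np.max(np.abs(pts[:, 0])))
    dy = float(np.max(np.abs(pts[:, 1])))
    c, s = math.cos(-theta), math.sin(-theta)
    xr = c * pts[:, 0] - s * pts[:, 1]
    yr = s * pts[:, 0] + c * pts[:, 1]
    dxt = float(np.max(np.abs(xr)))
    dyt = float(np.max(np.abs(yr)))
    rmax = float(np.max(np.hypot(pts[:, 0], pts[:, 1])))
    return dx, dy, dxt, dyt, rmax


def section_moduli(Ix, Iy, Imin, Imax, J, dx, dy, dx_theta, dy_theta, rmax):
    """Section moduli: Zx = Ix/dy, Zy = Iy/dx, Zmin = Imin/dx_theta,
    Zmax = Imax/dy_theta, Zpol = J/rmax."""
    if min(dx, dy, dx_theta, dy_theta, rmax) <= 0:
        raise GeometryError("chord lengths must be strictly positive")
    return Ix / dy, Iy / dx, Imin / dx_theta, Imax / dy_theta, J / rmax


def section_properties(section) -> SectionProperties:
    """Compute the full property set for a sampled cross-section.

    ``section`` is a :class:`osteogeom.sectioning.CrossSection` whose
    semilandmarks have been sampled (needed for the thickness statistics).
    """
    from .sectioning import radial_thickness  # circular-import guard

    if section.periosteal_slm is None or section.endosteal_slm is None:
        raise GeometryError(
            "section has no semilandmarks; run sample_semilandmarks first"
        )
    po = section.periosteal.points
    en = section.endosteal.points

    ta = polygon_area(po)
    ma = polygon_area(en)
    ca = ta - ma
    # cross-check: shoelace on the combined boundary (inner traversed
    # clockwise) must reproduce CA
    combined = abs(
        polygon_area(po, signed=True) + polygon_area(en[::-1], signed=True)
    )
    if not math.isclose(combined, ca, rel_tol=1e-9, abs_tol=1e-12):
        raise GeometryError("combined-boundary area check failed")

    centroid, ix, iy, ixy = cortical_moments(po, en)
    imin, imax, theta_raw = principal_moments(ix, iy, ixy)
    theta = normalize_theta(theta_raw)
    j = ix + iy
    dx, dy, dxt, dyt, rmax = chord_lengths(po, centroid, theta)
    zx, zy, zmin, zmax, zpol = section_moduli(
        ix, iy, imin, imax, j, dx, dy, dxt, dyt, rmax
    )
    thick = radial_thickness(section)

    return SectionProperties(
        total_area=ta,
        medullary_area=ma,
        cortical_area=ca,
        periosteal_perimeter=polygon_perimeter(po),
        endosteal_perimeter=polygon_perimeter(en),
        thickness_min=float(np.min(thick)),
        thickness_mean=float(np.mean(thick)),
        thickness_max=float(np.max(thick)),
        centroid_x=float(centroid[0]),
        centroid_y=float(centroid[1]),
        Ix=ix,
        Iy=iy,
        Ixy=ixy,
        Imin=imin,
        Imax=imax,
        J=j,
        theta=theta,
        dx=dx,
        dy=dy,
        dx_theta=dxt,
        dy_theta=dyt,
        rmax=rmax,
        Zx=zx,
        Zy=zy,
        Zmin=zmin,
        Zmax=zmax,
        Zpol=zpol,
    )


def rasterize_oracle(periosteal, endosteal, cell_size: float):
    """Brute-force grid quadrature of the cortical region.

    Grid cells whose centres fall inside the periosteal polygon and outside
    the endosteal polygon each contribute dA = cell_size^2.  Returns a dict
    with keys ``cortical_area, centroid, Ix, Iy, Ixy, J`` about the
    discretized centroid.  Error is O(cell_size); intended purely as an
    independent check of the exact polygon formulas.
    """
    po = _as_points(periosteal)
    en = _as_points(endosteal)
    lo = po.min(axis=0)
    hi = po.max(axis=0)
    diag = float(np.linalg.norm(hi - lo))
    if cell_size <= 0 or cell_size > diag / 50.0:
        raise GeometryError(
            f"cell_size must be in (0, {diag / 50.0:.4g}] for this section"
        )
    xs = np.arange(lo[0] + cell_size / 2, hi[0], cell_size)
    ys = np.arange(lo[1] + cell_size / 2, hi[1], cell_size)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    outer = shapely.Polygon(po)
    inner = shapely.Polygon(en)
    keep = shapely.contains_xy(outer, gx, gy) & ~shapely.contains_xy(inner, gx, gy)
    gx, gy = gx[keep], gy[keep]
    da = cell_size * cell_size
    area = da * gx.size
    cx, cy = float(np.mean(gx)), float(np.mean(gy))
    ix = da * float(np.sum((gy - cy) ** 2))
    iy = da * float(np.sum((gx - cx) ** 2))
    ixy = da * float(np.sum((gx - cx) * (gy - cy)))
    return {
        "cortical_area": area,
        "centroid": np.array([cx, cy]),
        "Ix": ix,
        "Iy": iy,
        "Ixy": ixy,
        "J": ix + iy,
    }
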
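"""Specimen loading, mesh repair, decimation, and anatomical orientation.

The pipeline consumes watertight triangle meshes (STL, binary or ASCII) plus
a plain-text landmark sidecar per specimen.  ``clean_mesh`` brings a raw
export to the invariants the downstream stages rely on (single component,
no duplicate faces, watertight, manifold); ``decimate`` reduces to a fixed
face budget (default 20,000); ``orient_specimen`` puts the bone into the
anatomical frame: +z proximal along the long axis, +x mediolateral
(towards the lateral condyle), +y anteroposterior.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ._decimate import quadric_decimate
from .errors import (
    CleaningError,
    DecimationError,
    MeshFormatError,
    OrientationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "AnatomicalLandmarks",
    "BoneSpecimen",
    "load_stl",
    "save_stl",
    "load_landmarks",
    "save_landmarks",
    "load_specimen",
    "clean_mesh",
    "decimate",
    "orient_specimen",
]

GROUPS = ("healthy", "osteoporosis")
_LANDMARK_KEYS = ("neck_point", "medial_condyle_point", "lateral_condyle_point")


@dataclass(frozen=True)
class TriangleMesh:
    """An indexed triangle mesh: vertices (n, 3) in mm, faces (m, 3) indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValidationError("faces must be an (m, 3) array")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValidationError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def directed_edges(self) -> np.ndarray:
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def edge_counts(self):
        """Undirected edge keys and the number of incident faces per edge."""
        e = np.sort(self.directed_edges(), axis=1)
        return np.unique(e, axis=0, return_counts=True)

    def is_watertight(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        if self.n_faces == 0:
            return False
        _, counts = self.edge_counts()
        return bool(np.all(counts == 2))

    def volume(self) -> float:
        """Enclosed volume by the divergence theorem (orientation-signed)."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.sum(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(self.vertices @ rotation.T + translation, self.faces)


@dataclass(frozen=True)
class AnatomicalLandmarks:
    """The three points defining biomechanical length and the anatomical frame."""

    neck_point: np.ndarray
    medial_condyle_point: np.ndarray
    lateral_condyle_point: np.ndarray

    def __post_init__(self):
        for key in _LANDMARK_KEYS:
            p = np.asarray(getattr(self, key), dtype=np.float64).reshape(3)
            object.__setattr__(self, key, p)
        pts = self.as_array()
        if len(np.unique(np.round(pts, 9), axis=0)) != 3:
            raise ValidationError("landmarks must be three distinct points")
        for cond in (self.medial_condyle_point, self.lateral_condyle_point):
            if np.linalg.norm(self.neck_point - cond) <= 0:
                raise ValidationError("neck-to-condyle distance must be positive")

    def as_array(self) -> np.ndarray:
        return np.stack([self.neck_point, self.medial_condyle_point,
                         self.lateral_condyle_point])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray):
        return AnatomicalLandmarks(
            self.neck_point @ rotation.T + translation,
            self.medial_condyle_point @ rotation.T + translation,
            self.lateral_condyle_point @ rotation.T + translation,
        )


@dataclass(frozen=True)
class BoneSpecimen:
    """One bone: mesh + landmarks + group label, all in one coordinate frame."""

    specimen_id: str
    mesh: TriangleMesh
    landmarks: AnatomicalLandmarks
    group: str
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

def _looks_binary(raw: bytes, path: Path) -> bool:
    if len(raw) < 84:
        # too short for binary; could still be a tiny ASCII file
        return not raw.lstrip().startswith(b"solid")
    (n,) = struct.unpack_from("<I", raw, 80)
    if len(raw) == 84 + 50 * n:
        return True
    if raw.lstrip().startswith(b"solid"):
        return False
    raise MeshFormatError(
        f"{path}: binary STL declares {n} triangles "
        f"(expected {84 + 50 * n} bytes) but file has {len(raw)} bytes; "
        f"truncated at byte {len(raw)}"
    )


def _parse_binary_stl(raw: bytes, path: Path) -> np.ndarray:
    (n,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * n
    if len(raw) < expected:
        raise MeshFormatError(f"{path}: truncated binary STL at byte {len(raw)}")
    rec = np.frombuffer(raw, dtype=np.uint8, count=50 * n, offset=84).reshape(n, 50)
    tri = rec[:, 12:48].copy().view("<f4").reshape(n, 3, 3)
    return tri.astype(np.float64)


def _parse_ascii_stl(raw: bytes, path: Path) -> np.ndarray:
    coords = []
    for lineno, line in enumerate(raw.decode("ascii", errors="replace").splitlines(), 1):
        parts = line.split()
        if parts and parts[0] == "vertex":
            if len(parts) != 4:
                raise MeshFormatError(f"{path}:{lineno}: malformed vertex line")
            coords.append([float(p) for p in parts[1:]])
    if not coords or len(coords) % 3:
        raise MeshFormatError(
            f"{path}: ASCII STL has {len(coords)} vertex lines (not a multiple of 3)"
        )
    return np.asarray(coords, dtype=np.float64).reshape(-1, 3, 3)


def _index_triangles(tri: np.ndarray) -> TriangleMesh:
    """Merge per-triangle vertex soup into an indexed mesh (exact matches)."""
    flat = tri.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    return TriangleMesh(uniq, inverse.reshape(-1, 3))


def load_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file into an indexed TriangleMesh.

    Duplicate vertex positions shared between adjacent triangles are merged
    exactly (STL stores a triangle soup), so topology checks are meaningful
    on the result.
    """
    path = Path(path)
    raw = path.read_bytes()
    if not raw:
        raise MeshFormatError(f"{path}: empty file (truncated at byte 0)")
    tri = (_parse_binary_stl if _looks_binary(raw, path) else _parse_ascii_stl)(raw, path)
    mesh = _index_triangles(tri)
    logger.debug("loaded %s: %d faces, %d vertices", path, mesh.n_faces, len(mesh.vertices))
    return mesh


def save_stl(mesh: TriangleMesh, path, *, binary: bool = True) -> None:
    """Write STL.  Binary by default; ASCII for human-readable output."""
    path = Path(path)
    v = mesh.vertices
    tri = v[mesh.faces]  # (m, 3, 3)
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    if binary:
        rec = np.zeros(len(tri), dtype=np.dtype(
            [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]))
        rec["normal"] = n
        rec["verts"] = tri
        with open(path, "wb") as fh:
            fh.write(b"osteogeom binary STL".ljust(80, b" "))
            fh.write(struct.pack("<I", len(tri)))
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid osteogeom\n")
            for nn, t in zip(n, tri):
                fh.write(f"  facet normal {nn[0]:.9e} {nn[1]:.9e} {nn[2]:.9e}\n")
                fh.write("    outer loop\n")
                for p in t:
                    fh.write(f"      vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid osteogeom\n")


# ---------------------------------------------------------------------------
# Landmark sidecar files:  "key: x y z" lines plus "group: <label>"
# ---------------------------------------------------------------------------

def load_landmarks(path) -> tuple[AnatomicalLandmarks, str | None]:
    """Parse a landmark sidecar; returns (landmarks, group-or-None)."""
    path = Path(path)
    entries: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValidationError(f"{path}: malformed line {line!r}")
        key, _, value = line.partition(":")
        entries[key.strip()] = value.strip()
    pts = {}
    for key in _LANDMARK_KEYS:
        if key not in entries:
            raise ValidationError(f"{path}: missing landmark key {key!r}")
        vals = entries[key].split()
        if len(vals) != 3:
            raise ValidationError(f"{path}: landmark {key!r} needs 3 coordinates")
        pts[key] = np.array([float(v) for v in vals])
    group = entries.get("group")
    if group is not None and group not in GROUPS:
        raise ValidationError(f"{path}: unknown group {group!r}")
    return AnatomicalLandmarks(**pts), group


def save_landmarks(landmarks: AnatomicalLandmarks, path, *, group: str | None = None) -> None:
    lines = ["# osteogeom landmark sidecar (mm)"]
    for key in _LANDMARK_KEYS:
        p = getattr(landmarks, key)
        lines.append(f"{key}: {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    if group is not None:
        lines.append(f"group: {group}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_specimen(mesh_path, landmark_path, group: str | None = None) -> BoneSpecimen:
    """Load one specimen from an STL file plus its landmark sidecar.

    ``group`` overrides any group recorded in the sidecar; one of the two
    must provide it.
    """
    mesh = load_stl(mesh_path)
    landmarks, file_group = load_landmarks(landmark_path)
    group = group or file_group
    if group is None:
        raise ValidationError(f"{landmark_path}: no group label given")
    return BoneSpecimen(Path(mesh_path).stem, mesh, landmarks, group)


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def _remove_degenerate_and_duplicate_faces(faces: np.ndarray) -> np.ndarray:
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    faces = faces[ok]
    key = np.sort(faces, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    return faces[np.sort(first)]


def _largest_component(mesh: TriangleMesh) -> TriangleMesh:
    e = mesh.directed_edges()
    n = len(mesh.vertices)
    adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    ncomp, labels = connected_components(adj, directed=False)
    if ncomp <= 1:
        return mesh
    face_label = labels[mesh.faces[:, 0]]
    counts = np.bincount(face_label, minlength=ncomp)
    keep = face_label == np.argmax(counts)
    logger.info("isolated piece removal: dropped %d faces", int(np.sum(~keep)))
    return _compact(mesh.vertices, mesh.faces[keep])


def _compact(vertices: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    used = np.unique(faces)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(vertices[used], remap[faces])


def _fill_holes(mesh: TriangleMesh) -> TriangleMesh:
    """Fan-triangulate every boundary loop (edges with a single incident face)."""
    de = mesh.directed_edges()
    de_set = set(map(tuple, de))
    boundary = [e for e in de_set if (e[1], e[0]) not in de_set]
    if not boundary:
        return mesh
    succ: dict[int, int] = {}
    for a, b in boundary:
        if a in succ:
            raise CleaningError(f"non-manifold boundary at vertex {a}")
        succ[a] = b
    new_faces = []
    seen: set[int] = set()
    for a0 in list(succ):
        if a0 in seen:
            continue
        loop = [a0]
        seen.add(a0)
        cur = succ[a0]
        while cur != a0:
            loop.append(cur)
            seen.add(cur)
            cur = succ[cur]
        if len(loop) < 3:
            raise CleaningError(f"degenerate boundary loop {loop}")
        # fan with winding opposite to the boundary direction so the new
        # triangles pair with the existing directed edges
        for i in range(1, len(loop) - 1):
            new_faces.append((loop[0], loop[i + 1], loop[i]))
        logger.info("hole closure: filled loop of %d edges", len(loop))
    faces = np.concatenate([mesh.faces, np.asarray(new_faces, dtype=np.int64)])
    return TriangleMesh(mesh.vertices, faces)


def clean_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """Repair a raw mesh to the watertight single-component invariant.

    Steps: drop degenerate/duplicate faces, keep the largest connected
    component, fan-fill boundary loops, then validate manifoldness.
    Irreparable non-manifold topology raises :class:`CleaningError` listing
    the offending edges.
    """
    if mesh.n_faces < 4:
        raise ValidationError("mesh must have at least 4 faces")
    m = TriangleMesh(mesh.vertices, _remove_degenerate_and_duplicate_faces(mesh.faces))
    m = _largest_component(m)
    m = _fill_holes(m)
    edges, counts = m.edge_counts()
    bad = edges[counts > 2]
    if len(bad):
        raise CleaningError(f"irreparable non-manifold edges: {bad.tolist()[:20]}")
    if not m.is_watertight():
        raise CleaningError("mesh is not watertight after repair")
    return m


# ---------------------------------------------------------------------------
# Decimation
# ---------------------------------------------------------------------------

def decimate(mesh: TriangleMesh, target_faces: int = 20000) -> TriangleMesh:
    """Reduce a watertight mesh to exactly ``target_faces`` faces.

    Quadric edge collapse with manifoldness and normal-flip guards.  Inputs
    already at or below the target are returned unchanged (logged).  A closed
    triangle mesh always has an even face count, so an odd target stops one
    face above it.
    """
    if target_faces < 100:
        raise ValidationError("target_faces must be >= 100")
    if not mesh.is_watertight():
        raise ValidationError("decimation input must be watertight")
    if mesh.n_faces <= target_faces:
        logger.warning(
            "decimate: input has %d faces <= target %d; returning unchanged",
            mesh.n_faces, target_faces)
        return mesh
    v, f = quadric_decimate(mesh.vertices, mesh.faces, target_faces)
    out = TriangleMesh(v, f)
    if out.n_faces > target_faces + 1:
        raise DecimationError(
            f"could not reach target: stopped at {out.n_faces} faces "
            f"(valid collapses exhausted); retry with a higher target")
    if not out.is_watertight():
        raise DecimationError("decimation broke watertightness")
    return out


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def orientation_frame(landmarks: AnatomicalLandmarks) -> tuple[np.ndarray, np.ndarray]:
    """Rotation (world -> anatomical) and translation from the landmarks.

    +z: condyle-midpoint -> neck (proximal up); +x: component of the
    medial->lateral condyle direction orthogonal to +z; +y = z cross x.
    Origin: condyle midpoint.
    """
    neck = landmarks.neck_point
    mid = 0.5 * (landmarks.medial_condyle_point + landmarks.lateral_condyle_point)
    z = neck - mid
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise OrientationError("neck coincides with condyle midpoint")
    z = z / nz
    ml = landmarks.lateral_condyle_point - landmarks.medial_condyle_point
    x = ml - np.dot(ml, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise OrientationError("landmarks are collinear; mediolateral axis undefined")
    x = x / nx
    y = np.cross(z, x)
    rotation = np.stack([x, y, z])  # rows map world coords to anatomical
    translation = -rotation @ mid
    return rotation, translation


def orient_specimen(spec: BoneSpecimen) -> BoneSpecimen:
    """Rigidly transform the specimen into the anatomical frame.

    Pure rotation + translation (no scaling); landmarks move with the mesh.
    Idempotent: an already-aligned specimen maps to itself.
    """
    rotation, translation = orientation_frame(spec.landmarks)
    logger.debug("orientation transform for %s:\n%s", spec.specimen_id,
                 np.vstack([np.column_stack([rotation, translation]),
                            [0, 0, 0, 1]]))
    return replace(
        spec,
        mesh=spec.mesh.transformed(rotation, translation),
        landmarks=spec.landmarks.transformed(rotation, translation),
    )
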
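"""Coordinate-space bookkeeping and 3D primitives.

All world coordinates are RAS millimetres. Two coordinate spaces are
distinguished by a tag: ``patient`` (scanner-native) and ``template``
(the MNI-152-style group space in which spatial priors live). Points carry
their space tag and cross-space arithmetic is refused; moving between
spaces goes through an explicit :class:`AffineTransform`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import trimesh

Space = Literal["patient", "template"]

PATIENT: Space = "patient"
TEMPLATE: Space = "template"


class GeometryError(ValueError):
    """Invalid geometric input (degenerate segment, zero direction, ...)."""


@dataclass(frozen=True)
class Point3:
    """A point in RAS millimetres, tagged with the space it lives in."""

    x: float
    y: float
    z: float
    space: Space = PATIENT

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise GeometryError(f"non-finite coordinates: {(self.x, self.y, self.z)}")
        if self.space not in (PATIENT, TEMPLATE):
            raise GeometryError(f"unknown space tag: {self.space!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray, space: Space = PATIENT) -> "Point3":
        a = np.asarray(a, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]), space)

    def _check_same_space(self, other: "Point3") -> None:
        if self.space != other.space:
            raise GeometryError(
                f"cross-space operation: {self.space} vs {other.space}; "
                "apply an explicit transform first"
            )

    def distance_to(self, other: "Point3") -> float:
        self._check_same_space(other)
        return float(np.linalg.norm(self.as_array() - other.as_array()))

    def __sub__(self, other: "Point3") -> np.ndarray:
        self._check_same_space(other)
        return self.as_array() - other.as_array()


@dataclass(frozen=True)
class Segment3:
    """Directed segment between two distinct points in one space."""

    p0: Point3
    p1: Point3

    def __post_init__(self) -> None:
        self.p0._check_same_space(self.p1)
        if np.allclose(self.p0.as_array(), self.p1.as_array()):
            raise GeometryError("degenerate segment: endpoints coincide")

    @property
    def space(self) -> Space:
        return self.p0.space

    @property
    def length(self) -> float:
        return self.p0.distance_to(self.p1)

    def direction(self) -> np.ndarray:
        """Unit vector p0 -> p1."""
        d = self.p1 - self.p0
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class AffineTransform:
    """4x4 homogeneous affine mapping mm coordinates source -> destination."""

    matrix: np.ndarray
    source: Space = PATIENT
    destination: Space = TEMPLATE

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise GeometryError("affine last row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) <= 1e-9:
            raise GeometryError("affine upper 3x3 block is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, source: Space = PATIENT, destination: Space = TEMPLATE) -> "AffineTransform":
        return cls(np.eye(4), source, destination)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.destination, self.source)

    def apply_array(self, pts: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) or (3,) array of mm coordinates."""
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if single else out

    @classmethod
    def load(cls, path: str | Path, source: Space = PATIENT, destination: Space = TEMPLATE) -> "AffineTransform":
        m = np.loadtxt(path)
        return cls(m.reshape(4, 4), source, destination)

    def save(self, path: str | Path) -> None:
        np.savetxt(path, self.matrix, fmt="%.17g")


def apply_affine(t: AffineTransform, p: Point3) -> Point3:
    """Map a point through an affine; the space tag switches to the destination."""
    if p.space != t.source:
        raise GeometryError(f"point in {p.space} space but transform expects {t.source}")
    return Point3.from_array(t.apply_array(p.as_array()), space=t.destination)


class SurfaceMesh:
    """Triangle mesh with outward per-face unit normals.

    Thin wrapper over :class:`trimesh.Trimesh` that pins down the invariants
    the planner relies on (index bounds, unit normals, watertightness when
    used as an interior/exterior boundary) and carries the space tag.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, space: Space = PATIENT):
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise GeometryError("faces must be (m, 3)")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise GeometryError("face index out of range")
        self.space = space
        self._tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self._tm.vertices)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self._tm.faces)

    @property
    def face_normals(self) -> np.ndarray:
        return np.asarray(self._tm.face_normals)

    @property
    def is_watertight(self) -> bool:
        return bool(self._tm.is_watertight)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Boolean interior test for (n, 3) points (watertight meshes only).

        Ray-crossing parity along a fixed generic direction; no spatial
        index required.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        direction = np.array([0.5377397, 0.3316228, 0.7752239])
        direction /= np.linalg.norm(direction)
        tri = self.vertices[self.faces]
        out = np.empty(len(pts), dtype=bool)
        for i, p in enumerate(pts):
            t = _ray_triangles(p, direction, tri[:, 0], tri[:, 1], tri[:, 2])
            out[i] = (np.isfinite(t).sum() % 2) == 1
        return out

    def as_trimesh(self) -> trimesh.Trimesh:
        return self._tm

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, space: Space = PATIENT) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), space)

    @classmethod
    def icosphere(cls, radius: float, subdivisions: int = 3, space: Space = PATIENT) -> "SurfaceMesh":
        return cls.from_trimesh(trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius), space)

    @classmethod
    def load(cls, path: str | Path, space: Space = PATIENT) -> "SurfaceMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        return cls.from_trimesh(tm, space)

    def save(self, path: str | Path) -> None:
        self._tm.export(str(path))


def point_segment_distance(p: Point3, s: Segment3) -> float:
    """Minimum distance (mm) from a point to a segment, min over t in [0, 1]."""
    if p.space != s.space:
        raise GeometryError("point and segment in different spaces")
    return float(
        _points_segments_distance(
            p.as_array()[None, :], s.p0.as_array()[None, :], s.p1.as_array()[None, :]
        )[0, 0]
    )


def _points_segments_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise distances from (n, 3) points to (m, 3)-(m, 3) segments -> (n, m)."""
    ab = b - a                                 # (m, 3)
    denom = np.einsum("md,md->m", ab, ab)      # squared lengths
    if np.any(denom == 0):
        raise GeometryError("degenerate segment in batch")
    ap = pts[:, None, :] - a[None, :, :]       # (n, m, 3)
    t = np.clip(np.einsum("nmd,md->nm", ap, ab) / denom, 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    return np.linalg.norm(pts[:, None, :] - closest, axis=-1)


def segment_segment_distance(s1: Segment3, s2: Segment3) -> float:
    """Minimum distance between two segments (used for electrode spacing)."""
    if s1.space != s2.space:
        raise GeometryError("segments in different spaces")
    return float(
        _segment_segment_distance(
            s1.p0.as_array(), s1.p1.as_array(), s2.p0.as_array(), s2.p1.as_array()
        )
    )


def _segment_segment_distance(p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray) -> float:
    # Standard closest-point parametrisation clamped to [0, 1]^2 with
    # boundary fallback (Ericson, Real-Time Collision Detection, 5.1.9).
    d1, d2, r = q1 - p1, q2 - p2, p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    b, c = d1 @ d2, d1 @ r
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
    t = (b * s + f) / e if e > 1e-12 else 0.0
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0) if a > 1e-12 else 0.0
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm((p1 + s * d1) - (p2 + t * d2)))


_RAY_EPS = 1e-9


def _ray_triangles(origin: np.ndarray, direction: np.ndarray, v0, v1, v2) -> np.ndarray:
    """Moller-Trumbore ray parameters against (m, 3) triangle vertex arrays.

    Returns an (m,) array of ray parameters t (np.inf where missed).
    """
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(direction[None, :], e2)
    det = np.einsum("md,md->m", e1, h)
    t_out = np.full(len(v0), np.inf)
    ok = np.abs(det) > 1e-12
    if not np.any(ok):
        return t_out
    inv_det = np.zeros_like(det)
    inv_det[ok] = 1.0 / det[ok]
    s = origin[None, :] - v0
    u = np.einsum("md,md->m", s, h) * inv_det
    q = np.cross(s, e1)
    v = np.einsum("d,md->m", direction, q) * inv_det
    t = np.einsum("md,md->m", e2, q) * inv_det
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > _RAY_EPS)
    t_out[hit] = t[hit]
    return t_out


def ray_mesh_first_intersection(
    origin: Point3, direction: np.ndarray, mesh: SurfaceMesh
) -> Point3 | None:
    """First intersection of a ray with a mesh, or None if no face is hit.

    Tests every triangle (vectorised Moller-Trumbore) and returns the point at
    the smallest positive ray parameter.
    """
    direction = np.asarray(direction, dtype=float).reshape(3)
    n = np.linalg.norm(direction)
    if n < 1e-12:
        raise GeometryError("zero direction vector")
    if mesh.space != origin.space:
        raise GeometryError("origin and mesh in different spaces")
    direction = direction / n
    tri = mesh.vertices[mesh.faces]
    t = _ray_triangles(origin.as_array(), direction, tri[:, 0], tri[:, 1], tri[:, 2])
    tmin = t.min()
    if not np.isfinite(tmin):
        return None
    return Point3.from_array(origin.as_array() + tmin * direction, space=origin.space)


def angle_from_surface_normal(
    entry: Point3,
    direction: np.ndarray,
    mesh: SurfaceMesh,
    snap_tolerance: float = 0.5,
) -> float:
    """Angle (degrees) between a trajectory and the surface normal at entry.

    0 deg means the trajectory is orthogonal to the surface (parallel to the
    outward normal); 90 deg means tangent. The entry point must lie within
    ``snap_tolerance`` mm of a mesh face; the nearest face's normal is used.
    The result is insensitive to the normal's sign convention.
    """
    direction = np.asarray(direction, dtype=float).reshape(3)
    n = np.linalg.norm(direction)
    if n < 1e-12:
        raise GeometryError("zero direction vector")
    if mesh.space != entry.space:
        raise GeometryError("entry and mesh in different spaces")
    # naive variant: exact, pure numpy, no spatial-index dependency
    closest, dist, face_id = trimesh.proximity.closest_point_naive(
        mesh.as_trimesh(), entry.as_array()[None, :]
    )
    if float(dist[0]) > snap_tolerance:
        raise GeometryError(
            f"entry point {float(dist[0]):.3f} mm from the mesh exceeds the "
            f"{snap_tolerance} mm snap tolerance"
        )
    normal = mesh.face_normals[int(face_id[0])]
    cosang = abs(float(np.dot(direction / n, normal)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
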
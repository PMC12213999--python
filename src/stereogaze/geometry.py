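"""Exact 3-D primitives shared by all modules.

All lengths are in millimetres and all angles returned to callers are in
degrees; internal trigonometry is in radians.  Direction vectors are unit
vectors.  The scene lives in a right-handed Cartesian screen coordinate
system with its origin at the screen centre and +z pointing toward the
subject; +x is to the subject's left and +y points down, so positive gaze
angles are to the left and down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: tolerance on normalized dot products below which geometry is treated as
#: degenerate (parallel rays, ray parallel to plane).
PARALLEL_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised when a construction has no unique solution (parallel rays,
    ray parallel to plane, zero-length normal, ...)."""


def as_vec3(v) -> np.ndarray:
    """Coerce to a float ``(3,)`` array."""
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    return a


def normalize(v) -> np.ndarray:
    """Return ``v / ||v||``; raises on (near-)zero vectors."""
    a = as_vec3(v)
    n = np.linalg.norm(a)
    if n < 1e-15:
        raise DegenerateGeometryError("cannot normalize a zero vector")
    return a / n


@dataclass(frozen=True)
class Ray:
    """Half-infinite line: ``origin + s * direction`` for s >= 0 (mm)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", as_vec3(self.origin))
        object.__setattr__(self, "direction", normalize(self.direction))

    def point_at(self, s: float) -> np.ndarray:
        return self.origin + s * self.direction


@dataclass(frozen=True)
class Plane:
    """Plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", as_vec3(self.point))
        object.__setattr__(self, "normal", normalize(self.normal))

    def signed_distance(self, p) -> float:
        return float(np.dot(as_vec3(p) - self.point, self.normal))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", as_vec3(self.translation))

    def apply(self, p) -> np.ndarray:
        return self.rotation @ as_vec3(p) + self.translation

    def apply_direction(self, d) -> np.ndarray:
        return self.rotation @ as_vec3(d)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def triangulate_rays(r1: Ray, r2: Ray) -> tuple[np.ndarray, float]:
    """Pseudo-intersection of two skew rays.

    Returns the midpoint of the common perpendicular segment between the two
    (infinite) lines and the length of that segment (the *gap*, a quality
    metric: 0 for truly intersecting rays).
    """
    d1, d2 = r1.direction, r2.direction
    b = float(np.dot(d1, d2))
    if abs(b) > 1.0 - PARALLEL_TOL:
        raise DegenerateGeometryError("rays are parallel; triangulation is undefined")
    w0 = r1.origin - r2.origin
    # Solve for the closest points r1(s1), r2(s2) on the two lines.
    d = float(np.dot(d1, w0))
    e = float(np.dot(d2, w0))
    denom = 1.0 - b * b
    s1 = (b * e - d) / denom
    s2 = (e - b * d) / denom
    p1 = r1.point_at(s1)
    p2 = r2.point_at(s2)
    return 0.5 * (p1 + p2), float(np.linalg.norm(p1 - p2))


def reflect_point(p, mirror: Plane) -> np.ndarray:
    """Mirror image of a point in a plane (the law of reflection applied to
    positions: used to recover real light/screen locations from their
    virtual images)."""
    p = as_vec3(p)
    return p - 2.0 * mirror.signed_distance(p) * mirror.normal


def reflect_direction(d, normal) -> np.ndarray:
    """Specular reflection of a direction about a unit surface normal."""
    d = as_vec3(d)
    n = normalize(normal)
    return d - 2.0 * float(np.dot(d, n)) * n


def intersect_line_plane(r: Ray, pl: Plane) -> np.ndarray:
    """Intersection point of a line (extended ray) with a plane."""
    denom = float(np.dot(r.direction, pl.normal))
    if abs(denom) < PARALLEL_TOL:
        raise DegenerateGeometryError("ray is parallel to the plane")
    s = np.dot(pl.point - r.origin, pl.normal) / denom
    return r.point_at(float(s))


def angle_between(u, v) -> float:
    """Angle between two vectors in degrees, in [0, 180].

    Evaluated as atan2(||u x v||, u . v) — the numerically safe form of the
    inverse-cosine formula: it resolves nearly-parallel vectors (where a
    bare acos loses half the significant digits) and can never produce NaN.
    Invariant to positive scaling of either argument.
    """
    u = as_vec3(u)
    v = as_vec3(v)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-15 or nv < 1e-15:
        raise ValueError("angle_between requires nonzero vectors")
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


def intersect_planes(p1: Plane, p2: Plane, through: np.ndarray | None = None) -> Ray:
    """Line of intersection of two planes as a Ray.

    If ``through`` is given it must lie on both planes (used when the line is
    known to pass through a common point such as a camera origin).
    """
    d = np.cross(p1.normal, p2.normal)
    n = np.linalg.norm(d)
    if n < PARALLEL_TOL:
        raise DegenerateGeometryError("planes are parallel")
    d = d / n
    if through is not None:
        return Ray(as_vec3(through), d)
    # Point on the line closest to the origin, via the 2-plane linear system.
    A = np.stack([p1.normal, p2.normal])
    b = np.array([np.dot(p1.normal, p1.point), np.dot(p2.normal, p2.point)])
    p0, *_ = np.linalg.lstsq(A, b, rcond=None)
    return Ray(p0, d)


def fit_plane(points: np.ndarray) -> tuple[Plane, float]:
    """Total-least-squares plane through >= 3 points.

    Returns the plane (anchored at the centroid, normal = smallest singular
    vector of the centered point matrix) and the RMS out-of-plane residual
    in mm.  Raises for degenerate (collinear) input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("fit_plane needs an (n>=3, 3) array")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; plane fit is degenerate")
    normal = vt[2]
    resid = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return Plane(centroid, normal), resid
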
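"""Rigid-body and quaternion algebra shared by every other module.

Conventions
-----------
* Column vectors; transforms act on the left, so ``compose(T1, T2)`` maps a
  point ``p`` to ``T1(T2(p))`` and matches the 4x4 homogeneous product.
* Lengths are millimetres, angles are degrees at API boundaries (radians
  internally).
* Quaternions are stored scalar-first with the canonical sign ``s >= 0``
  (ties broken by the first nonzero vector component), which makes solver
  outputs unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "UnitQuaternion",
    "Ray",
    "Plane3D",
    "quat_multiply",
    "quat_to_rotation",
    "rotation_to_quat",
    "compose",
    "invert",
    "apply",
    "skew",
    "rotation_angle_deg",
    "rotation_about_axis",
    "minimal_rotation_between",
]

_ORTHO_TOL = 1e-9


def _as_vec3(v, name: str = "vector") -> np.ndarray:
    arr = np.asarray(v, dtype=float).reshape(-1)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def _check_rotation(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection (det = -1), not a rotation")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """SE(3) pose: 3x3 rotation plus translation in mm."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        object.__setattr__(self, "translation", _as_vec3(self.translation, "translation"))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, M) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        if M.shape != (4, 4):
            raise ValueError(f"homogeneous matrix must be 4x4, got {M.shape}")
        if not np.allclose(M[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("last row of a homogeneous rigid transform must be [0 0 0 1]")
        return cls(M[:3, :3], M[:3, 3])

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    # Operator sugar: T1 @ T2 composes, T @ p applies.
    def __matmul__(self, other):
        if isinstance(other, RigidTransform):
            return compose(self, other)
        return apply(self, other)

    def inverse(self) -> "RigidTransform":
        return invert(self)


@dataclass(frozen=True)
class UnitQuaternion:
    """Unit quaternion q = s + v, scalar-first, canonical sign s >= 0."""

    s: float
    v: np.ndarray

    def __post_init__(self):
        v = _as_vec3(self.v, "quaternion vector part")
        s = float(self.s)
        norm = np.sqrt(s * s + v @ v)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"quaternion is not unit (norm {norm})")
        s, v = s / norm, v / norm
        # canonical sign: s >= 0; if s == 0, first nonzero of v >= 0
        if s < 0 or (s == 0 and _first_nonzero(v) < 0):
            s, v = -s, -v
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "v", v)

    @classmethod
    def identity(cls) -> "UnitQuaternion":
        return cls(1.0, np.zeros(3))

    def as_array(self) -> np.ndarray:
        """(s, vx, vy, vz) as a flat array."""
        return np.concatenate([[self.s], self.v])


def _first_nonzero(v: np.ndarray) -> float:
    for x in v:
        if x != 0:
            return x
    return 0.0


@dataclass(frozen=True)
class Ray:
    """Half-infinite ray: origin c (mm) and unit direction u."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin, "origin"))
        d = _as_vec3(self.direction, "direction")
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("ray direction must be nonzero")
        object.__setattr__(self, "direction", d / n)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class Plane3D:
    """Plane given by a point on it (mm) and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_vec3(self.point, "point"))
        n = _as_vec3(self.normal, "normal")
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / nn)

    def signed_distance(self, p) -> float:
        return float((np.asarray(p, dtype=float) - self.point) @ self.normal)


# ---------------------------------------------------------------------------
# quaternion algebra
# ---------------------------------------------------------------------------

def quat_multiply(q1: UnitQuaternion, q2: UnitQuaternion) -> UnitQuaternion:
    """Hamilton product q1 * q2 (composition of the rotations, q1 applied last)."""
    s = q1.s * q2.s - q1.v @ q2.v
    v = q1.s * q2.v + q2.s * q1.v + np.cross(q1.v, q2.v)
    return UnitQuaternion(s, v)


def quat_to_rotation(q: UnitQuaternion) -> np.ndarray:
    """Rotation matrix of a unit quaternion (standard Rodrigues form)."""
    s, (x, y, z) = q.s, q.v
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - s * z), 2 * (x * z + s * y)],
            [2 * (x * y + s * z), 1 - 2 * (x * x + z * z), 2 * (y * z - s * x)],
            [2 * (x * z - s * y), 2 * (y * z + s * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotation_to_quat(R) -> UnitQuaternion:
    """Quaternion of a rotation matrix, canonical sign. Rejects non-rotations."""
    R = _check_rotation(R)
    # Shepperd's method: pick the largest diagonal combination for stability.
    t = np.trace(R)
    if t > 0:
        r = np.sqrt(1.0 + t)
        s = 0.5 * r
        w = 0.5 / r
        v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]) * w
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        r = np.sqrt(1.0 + R[i, i] - R[j, j] - R[k, k])
        v = np.zeros(3)
        v[i] = 0.5 * r
        w = 0.5 / r
        s = (R[k, j] - R[j, k]) * w
        v[j] = (R[j, i] + R[i, j]) * w
        v[k] = (R[k, i] + R[i, k]) * w
    return UnitQuaternion(s, v)


# ---------------------------------------------------------------------------
# SE(3)
# ---------------------------------------------------------------------------

def compose(T1: RigidTransform, T2: RigidTransform) -> RigidTransform:
    """T1 o T2 (apply T2 first): homogeneous-matrix product semantics."""
    return RigidTransform(T1.rotation @ T2.rotation, T1.rotation @ T2.translation + T1.translation)


def invert(T: RigidTransform) -> RigidTransform:
    Rt = T.rotation.T
    return RigidTransform(Rt, -Rt @ T.translation)


def apply(T: RigidTransform, point) -> np.ndarray:
    """Map a 3-point (or an (N, 3) stack of points) through the transform."""
    p = np.asarray(point, dtype=float)
    if p.ndim == 1:
        return T.rotation @ _as_vec3(p, "point") + T.translation
    if p.ndim == 2 and p.shape[1] == 3:
        return p @ T.rotation.T + T.translation
    raise ValueError(f"point must be a 3-vector or (N, 3) array, got {p.shape}")


def skew(v) -> np.ndarray:
    """Cross-product matrix [v]x such that skew(v) @ w == v x w."""
    x, y, z = _as_vec3(v, "v")
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


# ---------------------------------------------------------------------------
# small helpers used across modules
# ---------------------------------------------------------------------------

def rotation_angle_deg(R) -> float:
    """Geodesic angle of a rotation matrix, in degrees.

    Computed through the quaternion (2 atan2(|v|, s)), which stays accurate
    for very small angles where the arccos-of-trace form loses half the
    available precision.
    """
    q = rotation_to_quat(np.asarray(R, dtype=float))
    return float(np.degrees(2.0 * np.arctan2(np.linalg.norm(q.v), q.s)))


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    a = _as_vec3(axis, "axis")
    n = np.linalg.norm(a)
    if n < 1e-12:
        raise ValueError("rotation axis must be nonzero")
    a = a / n
    th = np.radians(angle_deg)
    K = skew(a)
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def minimal_rotation_between(a, b) -> np.ndarray:
    """Smallest rotation carrying unit vector a onto unit vector b.

    For anti-parallel inputs the 180 deg axis is chosen deterministically as
    the coordinate axis most orthogonal to a.
    """
    a = _as_vec3(a, "a")
    b = _as_vec3(b, "b")
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = np.cross(a, b)
    d = float(a @ b)
    if np.linalg.norm(c) < 1e-12:
        if d > 0:
            return np.eye(3)
        # anti-parallel: rotate 180 deg about a deterministic perpendicular
        e = np.zeros(3)
        e[int(np.argmin(np.abs(a)))] = 1.0
        axis = np.cross(a, e)
        return rotation_about_axis(axis, 180.0)
    angle = np.degrees(np.arctan2(np.linalg.norm(c), d))
    return rotation_about_axis(c, angle)
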
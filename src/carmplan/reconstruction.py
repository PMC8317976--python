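"""Multi-view landmark triangulation and trajectory reconstruction.

Each annotated pixel in a frustum image defines a ray (c_i, u_i) from the
X-ray source through the landmark. The 3D landmark is the least-squares
closest point to the N >= 2 rays,

    x* = argmin_x sum_i || (I - u_i u_i^T) x - t_i ||^2,
    t_i = (I - u_i u_i^T) c_i,

solved through its normal equations. A drilling trajectory annotated as an
entry and an exit pixel in each of two views is reconstructed as the
intersection of the two backprojection planes: with plane normals
n_i = u_1i x u_2i, the line direction is d_12 = n_i x n_j, anchored at the
triangulated entry landmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import Ray
from .frustum import Frustum, backproject_pixel

__all__ = [
    "Annotation",
    "ReconstructedPoint",
    "Trajectory3D",
    "DegenerateRaysError",
    "annotation_ray",
    "triangulate",
    "trajectory_from_views",
]

#: relative eigenvalue ratio below which the ray system is called degenerate
DEGENERACY_THRESHOLD = 1e-6


class DegenerateRaysError(ValueError):
    """The annotated rays do not determine the quantity (e.g. all parallel)."""


@dataclass(frozen=True)
class Annotation:
    """One picked pixel on one frustum image."""

    frustum_id: str
    pixel: np.ndarray
    label: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixel, dtype=float).reshape(2)
        if not np.all(np.isfinite(px)):
            raise ValueError("annotation pixel must be finite")
        object.__setattr__(self, "pixel", px)


@dataclass(frozen=True)
class ReconstructedPoint:
    x_star: np.ndarray
    residual: float  # RMS perpendicular distance to the rays, mm
    n_rays: int


@dataclass(frozen=True)
class Trajectory3D:
    """3D line: anchor point (mm) and unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("trajectory direction must be nonzero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)

    def distance_to_point(self, p) -> float:
        v = np.asarray(p, dtype=float) - self.point
        return float(np.linalg.norm(v - (v @ self.direction) * self.direction))


def annotation_ray(frustum: Frustum, annotation: Annotation) -> Ray:
    """Backprojection ray of one annotation: origin at the source."""
    return backproject_pixel(frustum, annotation.pixel)


def triangulate(rays: Sequence[Ray]) -> ReconstructedPoint:
    """Least-squares closest point to N >= 2 rays (normal equations).

    Raises DegenerateRaysError when the rays are mutually (near) parallel,
    judged by the relative smallest eigenvalue of sum_i (I - u_i u_i^T).
    """
    if len(rays) < 2:
        raise ValueError(f"need at least 2 rays, got {len(rays)}")
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for ray in rays:
        P = np.eye(3) - np.outer(ray.direction, ray.direction)
        A += P
        b += P @ ray.origin
    w = np.linalg.eigvalsh(A)
    if w[0] < DEGENERACY_THRESHOLD * w[-1]:
        raise DegenerateRaysError("rays are (near) parallel; intersection undetermined")
    x = np.linalg.solve(A, b)
    sq = [np.linalg.norm((np.eye(3) - np.outer(r.direction, r.direction)) @ (x - r.origin)) ** 2
          for r in rays]
    return ReconstructedPoint(x, float(np.sqrt(np.mean(sq))), len(rays))


def _plane_normal(frustum: Frustum, entry_px, exit_px) -> np.ndarray:
    u1 = backproject_pixel(frustum, entry_px).direction
    u2 = backproject_pixel(frustum, exit_px).direction
    n = np.cross(u1, u2)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise DegenerateRaysError("entry and exit rays are parallel in one view")
    return n / nn


def trajectory_from_views(
    entry_a,
    exit_a,
    frustum_a: Frustum,
    entry_b,
    exit_b,
    frustum_b: Frustum,
    degeneracy_threshold: float = 1e-9,
) -> Trajectory3D:
    """Reconstruct a 3D drilling line from entry/exit pixels in two views.

    Direction = cross product of the two backprojection-plane normals,
    oriented entry -> exit; anchor = triangulated entry landmark.
    """
    ea = entry_a.pixel if isinstance(entry_a, Annotation) else np.asarray(entry_a, float)
    xa = exit_a.pixel if isinstance(exit_a, Annotation) else np.asarray(exit_a, float)
    eb = entry_b.pixel if isinstance(entry_b, Annotation) else np.asarray(entry_b, float)
    xb = exit_b.pixel if isinstance(exit_b, Annotation) else np.asarray(exit_b, float)

    n_a = _plane_normal(frustum_a, ea, xa)
    n_b = _plane_normal(frustum_b, eb, xb)
    d = np.cross(n_a, n_b)
    if np.linalg.norm(d) < degeneracy_threshold:
        raise DegenerateRaysError(
            "the two views see the line in coincident planes; direction undetermined"
        )
    entry3d = triangulate(
        [backproject_pixel(frustum_a, ea), backproject_pixel(frustum_b, eb)]
    )
    exit3d = triangulate(
        [backproject_pixel(frustum_a, xa), backproject_pixel(frustum_b, xb)]
    )
    d = d / np.linalg.norm(d)
    if (exit3d.x_star - entry3d.x_star) @ d < 0:
        d = -d
    return Trajectory3D(entry3d.x_star, d)
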
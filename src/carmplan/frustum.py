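"""The flying-frustum camera model of a C-arm X-ray acquisition.

A frustum is the full pyramid of vision of one acquisition: apex at the
X-ray source, base at the detector (the *far* plane at focal distance f).
The acquired image can slide along the principal axis on a *near* plane at
a user-controlled distance n, 0 <= n <= f, remaining a geometrically valid
image of the same anatomy: image coordinates simply scale by n/f.

Pixel convention: origin at the top-left, x to the right, y down, with the
principal point at the image centre by default. The source pose ^OR^T_X is
the camera-to-world transform (camera +Z is the viewing direction); the
projection uses its inverse, as a pinhole camera does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import RigidTransform, Ray, invert, rotation_angle_deg

__all__ = [
    "Intrinsics",
    "Frustum",
    "XRayImage",
    "BehindSourceError",
    "frustum_projection",
    "scale_to_near",
    "image_pose",
    "project_point",
    "backproject_pixel",
    "frustum_alignment_error",
]


class BehindSourceError(ValueError):
    """A point to be projected has non-positive depth along the viewing axis."""


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics of the X-ray camera.

    focal_length   source-to-detector distance f (mm)
    principal_point  (px), defaults to the image centre
    pixel_spacing  detector pixel pitch (mm/px)
    image_size     (width, height) in px
    """

    focal_length: float = 1000.0
    pixel_spacing: float = 0.3
    image_size: tuple = (1024, 1024)
    principal_point: Optional[tuple] = None

    def __post_init__(self):
        if self.focal_length <= 0:
            raise ValueError("focal length must be positive")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel spacing must be positive")
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError("image size must be positive")
        pp = self.principal_point
        if pp is None:
            pp = (w / 2.0, h / 2.0)
        pp = (float(pp[0]), float(pp[1]))
        if not (0 <= pp[0] <= w and 0 <= pp[1] <= h):
            raise ValueError("principal point must lie inside the image bounds")
        object.__setattr__(self, "principal_point", pp)
        object.__setattr__(self, "image_size", (int(w), int(h)))

    @property
    def K(self) -> np.ndarray:
        """3x3 intrinsic matrix in pixel units."""
        fpx = self.focal_length / self.pixel_spacing
        cx, cy = self.principal_point
        return np.array([[fpx, 0.0, cx], [0.0, fpx, cy], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class XRayImage:
    """Single-channel raster with its physical pixel spacing."""

    pixels: np.ndarray
    bit_depth: int = 16
    spacing: float = 0.3

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2D grid")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> tuple:
        h, w = self.pixels.shape
        return (w, h)


@dataclass(frozen=True)
class Frustum:
    """One X-ray acquisition: source pose ^OR^T_X, intrinsics, near plane n."""

    source_pose: RigidTransform = field(default_factory=RigidTransform.identity)
    intrinsics: Intrinsics = field(default_factory=Intrinsics)
    near: Optional[float] = None
    image: Optional[XRayImage] = None
    frustum_id: str = ""

    def __post_init__(self):
        n = self.near
        if n is None:
            n = self.intrinsics.focal_length
        _check_near(n, self.intrinsics.focal_length)
        object.__setattr__(self, "near", float(n))

    @property
    def source_center(self) -> np.ndarray:
        """Position of the X-ray source in the OR frame (mm)."""
        return self.source_pose.translation

    @property
    def principal_axis(self) -> np.ndarray:
        """Unit viewing direction (camera +Z) in the OR frame."""
        return self.source_pose.rotation[:, 2]


def _check_near(n: float, f: float) -> None:
    if not (0.0 <= n <= f):
        raise ValueError(f"near plane n={n} outside the valid range [0, f={f}]")


def frustum_projection(frustum: Frustum, near: Optional[float] = None) -> np.ndarray:
    """3x4 flying-frustum projection P_f mapping homogeneous OR points to
    near-plane image coordinates.

    P_f = diag(n/f, n/f, 1) . K . [I|0] . (^OR^T_X)^-1 : at n = f this is the
    plain pinhole projection onto the detector.
    """
    f = frustum.intrinsics.focal_length
    n = frustum.near if near is None else float(near)
    _check_near(n, f)
    S = np.diag([n / f, n / f, 1.0])
    E = invert(frustum.source_pose)  # world -> camera
    ext = np.hstack([E.rotation, E.translation[:, None]])
    return S @ frustum.intrinsics.K @ ext


def scale_to_near(x_img, n: float, f: float) -> np.ndarray:
    """Scale detector-plane coordinates to the near plane: x_f = (n/f) x_i."""
    _check_near(n, f)
    return (n / f) * np.asarray(x_img, dtype=float)


def image_pose(frustum: Frustum, n: Optional[float] = None) -> RigidTransform:
    """Pose ^OR^T_I of the interactive image plane at distance n from the source.

    Orientation equals the source orientation; the origin is displaced by n
    along the principal axis, so at n = f the image sits at the detector and
    at n = 0 it collapses onto the source.
    """
    f = frustum.intrinsics.focal_length
    n = frustum.near if n is None else float(n)
    _check_near(n, f)
    R = frustum.source_pose.rotation
    t = frustum.source_pose.translation + n * R[:, 2]
    return RigidTransform(R, t)


def project_point(frustum: Frustum, x_world, near: Optional[float] = None) -> np.ndarray:
    """Project an OR-frame point (mm) to image coordinates (px) on the near plane.

    Raises BehindSourceError for points with non-positive depth.
    """
    P = frustum_projection(frustum, near=near)
    p = np.asarray(x_world, dtype=float).reshape(3)
    h = P @ np.append(p, 1.0)
    if h[2] <= 1e-12:
        raise BehindSourceError("point is behind (or at) the X-ray source")
    return h[:2] / h[2]


def backproject_pixel(frustum: Frustum, pixel, near: Optional[float] = None) -> Ray:
    """Ray from the source through a (near-plane) pixel, in the OR frame.

    Out-of-bounds pixels are allowed with a warning; the ray is still valid.
    """
    f = frustum.intrinsics.focal_length
    n = frustum.near if near is None else float(near)
    _check_near(n, f)
    px = np.asarray(pixel, dtype=float).reshape(2)
    w, h = frustum.intrinsics.image_size
    scale = f / n if n > 0 else 1.0
    det = px * scale  # undo the near-plane scaling -> detector pixels
    if not (0 <= det[0] <= w and 0 <= det[1] <= h):
        warnings.warn("pixel outside image bounds; backprojecting anyway", stacklevel=2)
    cx, cy = frustum.intrinsics.principal_point
    rho = frustum.intrinsics.pixel_spacing
    d_cam = np.array([(det[0] - cx) * rho, (det[1] - cy) * rho, f])
    d_world = frustum.source_pose.rotation @ d_cam
    return Ray(frustum.source_center, d_world)


def frustum_alignment_error(current: Frustum, target: Frustum) -> tuple:
    """(rotation deg, translation mm) between two frustum source poses.

    Used to express how far the scanner is from a desired perspective.
    """
    dR = current.source_pose.rotation.T @ target.source_pose.rotation
    rot = rotation_angle_deg(dR)
    trans = float(np.linalg.norm(current.source_center - target.source_center))
    return rot, trans
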
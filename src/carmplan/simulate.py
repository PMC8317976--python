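"""Synthetic operating-room scenes: phantoms, C-arm orbits, pose and pixel
noise, and calibration datasets.

Everything downstream of real hardware is emulated here so that the whole
pipeline is exercisable end to end. The tube phantom mirrors the K-wire
drilling target (a ~10 mm bone canal, 2.8 mm wire); the pelvis phantom is a
landmark set (two ASIS points, pubic symphysis, acetabulum centre). C-arm
views are sampled on an orbit about an isocenter (default source radius
600 mm), SLAM-like pose noise is axis-angle rotation noise plus isotropic
translation noise, and annotation noise is isotropic in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation as _R

from .geometry import RigidTransform, compose, invert, rotation_about_axis
from .frustum import Frustum, Intrinsics, project_point, BehindSourceError
from .reconstruction import Annotation, Trajectory3D

__all__ = [
    "TubePhantom",
    "PelvisPhantom",
    "NoiseSpec",
    "sample_orbit_poses",
    "orbit_frustums",
    "perturb_pose",
    "render_annotations",
    "generate_handeye_dataset",
    "simulate_insertion",
    "default_pelvis",
]

DEFAULT_ORBIT_RADIUS = 600.0  # mm, source-to-isocenter


@dataclass(frozen=True)
class TubePhantom:
    """Tubular bone canal: centerline entry/exit centres plus diameters.

    The default centerline is oblique to all three axes so that no standard
    orbit view happens to look straight down the canal (which would make
    two-view reconstruction degenerate)."""

    entry: np.ndarray = field(default_factory=lambda: np.array([5.0, -8.0, -40.0]))
    exit: np.ndarray = field(default_factory=lambda: np.array([-3.0, 6.0, 42.0]))
    inner_diameter: float = 10.0
    wire_diameter: float = 2.8

    def __post_init__(self):
        e = np.asarray(self.entry, float).reshape(3)
        x = np.asarray(self.exit, float).reshape(3)
        if np.allclose(e, x):
            raise ValueError("tube entry and exit centres must differ")
        if self.inner_diameter <= 0 or self.wire_diameter <= 0:
            raise ValueError("diameters must be positive")
        object.__setattr__(self, "entry", e)
        object.__setattr__(self, "exit", x)

    @property
    def centerline(self) -> Trajectory3D:
        return Trajectory3D(self.entry, self.exit - self.entry)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.exit - self.entry))


@dataclass(frozen=True)
class PelvisPhantom:
    """Named pelvic landmarks in the OR frame (mm)."""

    landmarks: Dict[str, np.ndarray]

    def __post_init__(self):
        lm = {k: np.asarray(v, float).reshape(3) for k, v in self.landmarks.items()}
        for req in ("l_asis", "r_asis", "pubis"):
            if req not in lm:
                raise ValueError(f"pelvis phantom requires landmark {req!r}")
        t = lm["l_asis"] - lm["r_asis"]
        u = (lm["l_asis"] + lm["r_asis"]) / 2 - lm["pubis"]
        if np.linalg.norm(np.cross(t, u)) < 1e-9:
            raise ValueError("ASIS/pubis landmarks must not be collinear")
        object.__setattr__(self, "landmarks", lm)


def default_pelvis() -> PelvisPhantom:
    """Compact pelvis landmark phantom centred at the isocenter (mm).

    Roughly half adult scale so that every landmark stays inside the default
    detector field of view across oblique orbit angles. Anterior is +z (the
    patient faces the angle-0 detector); the acetabulum centre lies posterior
    to the anterior pelvic plane, as in anatomy.
    """
    return PelvisPhantom(
        {
            "l_asis": np.array([60.0, 15.0, 8.0]),
            "r_asis": np.array([-60.0, 15.0, 8.0]),
            "pubis": np.array([0.0, -70.0, 0.0]),
            "acetabulum": np.array([25.0, -35.0, -25.0]),
        }
    )


@dataclass(frozen=True)
class NoiseSpec:
    """SLAM-like noise magnitudes: rotation SD (deg), translation SD (mm),
    annotation pixel SD (px)."""

    rotation_sd_deg: float = 0.0
    translation_sd_mm: float = 0.0
    pixel_sd_px: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if min(self.rotation_sd_deg, self.translation_sd_mm, self.pixel_sd_px) < 0:
            raise ValueError("noise SDs must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def sample_orbit_poses(
    isocenter,
    source_radius: float = DEFAULT_ORBIT_RADIUS,
    angles_deg: Sequence[float] = (0.0, 90.0),
) -> List[RigidTransform]:
    """Source poses on a circular orbit about the isocenter.

    The orbit lies in the world X-Z plane (rotation about world Y). At angle
    0 the pose is canonical: the source sits at isocenter - radius * z_hat
    viewing along +z with identity orientation; every principal axis passes
    through the isocenter.
    """
    if source_radius <= 0:
        raise ValueError("orbit radius must be positive")
    iso = np.asarray(isocenter, float).reshape(3)
    poses = []
    for a in angles_deg:
        R = rotation_about_axis([0.0, 1.0, 0.0], a)
        t = iso - source_radius * R[:, 2]
        poses.append(RigidTransform(R, t))
    return poses


def orbit_frustums(
    isocenter,
    angles_deg: Sequence[float],
    source_radius: float = DEFAULT_ORBIT_RADIUS,
    intrinsics: Optional[Intrinsics] = None,
) -> List[Frustum]:
    """Convenience: orbit poses wrapped as frustums with ids 'view0', ..."""
    intr = intrinsics if intrinsics is not None else Intrinsics(focal_length=1000.0)
    poses = sample_orbit_poses(isocenter, source_radius, angles_deg)
    return [
        Frustum(source_pose=p, intrinsics=intr, frustum_id=f"view{i}")
        for i, p in enumerate(poses)
    ]


def perturb_pose(
    pose: RigidTransform,
    noise: NoiseSpec,
    rng: Optional[np.random.Generator] = None,
) -> RigidTransform:
    """Right-multiply an axis-angle rotation perturbation (uniform random
    axis, normal magnitude) and add isotropic normal translation noise."""
    rng = noise.rng() if rng is None else rng
    if noise.rotation_sd_deg > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(0.0, noise.rotation_sd_deg)
        dR = rotation_about_axis(axis, angle)
    else:
        dR = np.eye(3)
    dt = rng.normal(0.0, noise.translation_sd_mm, size=3) if noise.translation_sd_mm > 0 else np.zeros(3)
    return RigidTransform(pose.rotation @ dR, pose.translation + dt)


def render_annotations(
    landmarks: Dict[str, np.ndarray],
    frustum: Frustum,
    noise: Optional[NoiseSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[Annotation]:
    """Project named landmarks into one frustum as pixel annotations.

    With zero noise the pixels equal project_point exactly. Landmarks behind
    the source raise BehindSourceError (flagged, not silently skipped).
    """
    noise = NoiseSpec() if noise is None else noise
    rng = noise.rng() if rng is None else rng
    out = []
    for name, p in landmarks.items():
        try:
            px = project_point(frustum, p)
        except BehindSourceError as err:
            raise BehindSourceError(f"landmark {name!r} is behind the source") from err
        if noise.pixel_sd_px > 0:
            px = px + rng.normal(0.0, noise.pixel_sd_px, size=2)
        out.append(Annotation(frustum.frustum_id, px, label=name))
    return out


def generate_handeye_dataset(
    n_poses: int,
    true_X: RigidTransform,
    noise: Optional[NoiseSpec] = None,
    seed: Optional[int] = None,
    translation_range_mm: float = 500.0,
) -> Tuple[List[RigidTransform], List[RigidTransform]]:
    """Corresponding (source, tracker) pose streams consistent with a known
    calibration X before noise.

    Source poses ^IR^T_X get uniformly random orientations (so the motion set
    spans many axes) and uniform translations; tracker poses follow from the
    closed loop ^IR^T_X . X . (^OR^T_H)^-1 = const. Noise, when given, is
    applied independently to both streams.
    """
    if n_poses < 2:
        raise ValueError("need at least 2 poses")
    noise = NoiseSpec() if noise is None else noise
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    # fixed OR-to-IR offset closing the loop; arbitrary but reproducible
    C = RigidTransform(
        _R.random(rng=rng).as_matrix(), rng.uniform(-200, 200, size=3)
    )
    source, tracker = [], []
    for _ in range(n_poses):
        T_x = RigidTransform(
            _R.random(rng=rng).as_matrix(),
            rng.uniform(-translation_range_mm, translation_range_mm, size=3),
        )
        # T_H solves T_x . X . T_H^-1 = C
        T_h = compose(invert(C), compose(T_x, true_X))
        source.append(perturb_pose(T_x, noise, rng))
        tracker.append(perturb_pose(T_h, noise, rng))
    return source, tracker


def simulate_insertion(
    planned: Trajectory3D,
    angle_sd_deg: float = 0.0,
    offset_sd_mm: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory3D:
    """Executed wire line: the plan perturbed by an angular deviation (random
    tilt axis perpendicular to the wire) and a perpendicular entry offset."""
    rng = np.random.default_rng(seed) if rng is None else rng
    d = planned.direction
    # orthonormal basis of the plane perpendicular to the wire
    e = np.zeros(3)
    e[int(np.argmin(np.abs(d)))] = 1.0
    b1 = np.cross(d, e)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(d, b1)
    new_d = d
    if angle_sd_deg > 0:
        phase = rng.uniform(0, 2 * np.pi)
        tilt_axis = np.cos(phase) * b1 + np.sin(phase) * b2
        tilt = rng.normal(0.0, angle_sd_deg)
        new_d = rotation_about_axis(tilt_axis, tilt) @ d
    offset = np.zeros(3)
    if offset_sd_mm > 0:
        offset = rng.normal(0.0, offset_sd_mm) * b1 + rng.normal(0.0, offset_sd_mm) * b2
    return Trajectory3D(planned.point + offset, new_d)
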
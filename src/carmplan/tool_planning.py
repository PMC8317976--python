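"""Staged, DOF-constrained alignment of a virtual tool against 2D targets.

The virtual tool (a drill with a K-wire along its local +Z axis) is posed in
the OR frame and its wire is forward-projected into every frustum. Instead of
free 6-DOF manipulation, alignment proceeds in three stages with shrinking
freedom:

stage 1 (4 DOF)  theta about local Y plus full translation - align the wire
                 with the target line in the first frustum. Beforehand the
                 tool's local Y axis is rotated onto the first frustum's
                 viewing direction, so the remaining DOF move the projection
                 in well-behaved ways.
stage 2 (4 DOF)  phi about local X, psi about local Z, translation along
                 local Y and Z - align in the second frustum. With local Y
                 along the viewing ray through the tool origin, each of these
                 DOF leaves the wire's projected line in the first frustum
                 unchanged: phi rotates the wire inside the viewing plane,
                 psi spins the tool about the wire itself, t_y slides along
                 the ray and t_z along the wire.
stage 3 (2 DOF)  psi about local Z and t_z along it - the wire line is
                 invariant, so no projection changes anywhere.

Consensus in two non-coplanar frustums pins the wire to the intersection of
the two target backprojection planes, i.e. the true 3D line.

Note on stage 2: the closed-form 4x4 ``stage2_transform`` combines the two
angles as R_z(psi) . R_x(phi). Applied in one shot with both angles nonzero,
that order tips the wire out of the frustum-1 viewing plane (the offending
term is sin(psi) sin(phi)). The alignment application therefore applies the
angles intrinsically X-then-Z (R_x(phi) . R_z(psi)), which realises the
exact same interaction - phi in-plane, psi about the wire - while preserving
frustum-1 alignment exactly for every parameter combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .geometry import (
    RigidTransform,
    compose,
    minimal_rotation_between,
)
from .frustum import Frustum, backproject_pixel, project_point

__all__ = [
    "VirtualTool",
    "StagedAlignment",
    "TargetLine2D",
    "init_stage1",
    "stage1_transform",
    "stage2_transform",
    "stage3_transform",
    "apply_stage",
    "project_tool",
    "alignment_residual",
    "auto_align",
    "AutoAlignResult",
]


@dataclass(frozen=True)
class VirtualTool:
    """Virtual drill: the K-wire runs along local +Z from the local origin."""

    wire_length: float = 150.0
    body_points: Optional[np.ndarray] = None  # (N, 3) mm, local frame

    def __post_init__(self):
        if self.wire_length <= 0:
            raise ValueError("wire length must be positive")
        if self.body_points is not None:
            bp = np.asarray(self.body_points, dtype=float)
            if bp.ndim != 2 or bp.shape[1] != 3:
                raise ValueError("body points must be (N, 3)")
            object.__setattr__(self, "body_points", bp)

    def wire_endpoints_local(self) -> np.ndarray:
        return np.array([[0.0, 0.0, 0.0], [0.0, 0.0, self.wire_length]])


@dataclass(frozen=True)
class TargetLine2D:
    """Desired wire appearance in one frustum image: entry and exit pixels."""

    frustum_id: str
    entry: np.ndarray
    exit: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.entry, dtype=float).reshape(2)
        x = np.asarray(self.exit, dtype=float).reshape(2)
        if np.allclose(e, x):
            raise ValueError("target entry and exit pixels must differ")
        object.__setattr__(self, "entry", e)
        object.__setattr__(self, "exit", x)

    @property
    def direction(self) -> np.ndarray:
        d = self.exit - self.entry
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class StagedAlignment:
    """Tool pose in the OR frame plus the forward-only stage counter."""

    tool: VirtualTool
    pose: RigidTransform
    stage: int = 1
    anchor_frustum_id: str = ""

    def __post_init__(self):
        if self.stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")

    def advance(self) -> "StagedAlignment":
        if self.stage >= 3:
            raise ValueError("already at the final stage")
        return replace(self, stage=self.stage + 1)

    def wire_endpoints_world(self) -> np.ndarray:
        return self.pose @ self.tool.wire_endpoints_local()

    def wire_line(self) -> tuple:
        """(point, unit direction) of the wire in the OR frame."""
        p = self.pose.translation
        d = self.pose.rotation[:, 2]
        return p, d


def init_stage1(
    tool: VirtualTool,
    tool_pose: RigidTransform,
    frustum1: Frustum,
    mode: str = "viewing_ray",
) -> StagedAlignment:
    """Rotate the tool (minimal rotation) so its local Y axis points along the
    first frustum's viewing direction.

    ``mode='principal_axis'`` uses the frustum principal axis (the literal
    reading); ``'viewing_ray'`` uses the ray from the source through the tool
    origin, which is what makes the stage-2 DOF exactly image-1 neutral.
    """
    if mode == "principal_axis":
        axis = frustum1.principal_axis
    elif mode == "viewing_ray":
        v = tool_pose.translation - frustum1.source_center
        n = np.linalg.norm(v)
        axis = frustum1.principal_axis if n < 1e-9 else v / n
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    y_world = tool_pose.rotation[:, 1]
    R_fix = minimal_rotation_between(y_world, axis)
    new_pose = RigidTransform(R_fix @ tool_pose.rotation, tool_pose.translation)
    return StagedAlignment(tool, new_pose, stage=1, anchor_frustum_id=frustum1.frustum_id)


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def stage1_transform(theta_deg: float, t_x: float, t_y: float, t_z: float) -> np.ndarray:
    """4-DOF stage-1 matrix: rotation theta about local Y, full translation."""
    M = np.eye(4)
    M[:3, :3] = _rot_y(np.radians(theta_deg))
    M[:3, 3] = (t_x, t_y, t_z)
    return M


def stage2_transform(phi_deg: float, psi_deg: float, t_y: float, t_z: float) -> np.ndarray:
    """4-DOF stage-2 matrix: R_z(psi) . R_x(phi), translation (0, t_y, t_z)."""
    M = np.eye(4)
    M[:3, :3] = _rot_z(np.radians(psi_deg)) @ _rot_x(np.radians(phi_deg))
    M[:3, 3] = (0.0, t_y, t_z)
    return M


def stage3_transform(psi_deg: float, t_z: float) -> np.ndarray:
    """2-DOF stage-3 matrix: spin about and slide along the wire axis."""
    M = np.eye(4)
    M[:3, :3] = _rot_z(np.radians(psi_deg))
    M[:3, 3] = (0.0, 0.0, t_z)
    return M


def apply_stage(alignment: StagedAlignment, params: Dict[str, float]) -> StagedAlignment:
    """Apply the current stage's DOF in the tool's local frame (right-mult).

    Stage-2 angles are applied intrinsically X-then-Z (see module note) so
    that frustum-1 alignment is preserved exactly.
    """
    s = alignment.stage
    if s == 1:
        M = stage1_transform(
            params.get("theta", 0.0),
            params.get("t_x", 0.0),
            params.get("t_y", 0.0),
            params.get("t_z", 0.0),
        )
    elif s == 2:
        R = _rot_x(np.radians(params.get("phi", 0.0))) @ _rot_z(np.radians(params.get("psi", 0.0)))
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = (0.0, params.get("t_y", 0.0), params.get("t_z", 0.0))
    else:
        M = stage3_transform(params.get("psi", 0.0), params.get("t_z", 0.0))
    T = RigidTransform(M[:3, :3], M[:3, 3])
    return replace(alignment, pose=compose(alignment.pose, T))


def project_tool(alignment: StagedAlignment, frustum: Frustum) -> np.ndarray:
    """(2, 2) projected entry/exit pixels of the wire in one frustum."""
    ends = alignment.wire_endpoints_world()
    return np.array([project_point(frustum, p) for p in ends])


def alignment_residual(
    segment: np.ndarray, target: TargetLine2D, n_samples: int = 33
) -> tuple:
    """How far a projected wire segment is from the target line.

    Returns (rms_px, overlap): the RMS point-to-line distance of points
    sampled densely along the projected segment to the target's *infinite*
    line, and the fraction of the target segment longitudinally covered by
    the projection.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.shape != (2, 2):
        raise ValueError("segment must be two 2D endpoints")
    d = target.direction
    normal = np.array([-d[1], d[0]])
    ts = np.linspace(0.0, 1.0, n_samples)[:, None]
    pts = seg[0] * (1 - ts) + seg[1] * ts
    dist = (pts - target.entry) @ normal
    rms = float(np.sqrt(np.mean(dist**2)))
    # longitudinal coverage of the target segment by the projected wire
    length = float(np.linalg.norm(target.exit - target.entry))
    proj = (pts - target.entry) @ d
    lo, hi = float(proj.min()), float(proj.max())
    overlap = max(0.0, min(hi, length) - max(lo, 0.0)) / length
    return rms, overlap


@dataclass(frozen=True)
class AutoAlignResult:
    alignment: StagedAlignment
    residuals_px: Dict[str, float]
    line_point: np.ndarray
    line_direction: np.ndarray
    underdetermined: bool = False
    coplanar: bool = False
    stage_params: Dict[int, Dict[str, float]] = field(default_factory=dict)


def _wire_residual(alignment: StagedAlignment, frustum: Frustum, target: TargetLine2D) -> float:
    return alignment_residual(project_tool(alignment, frustum), target)[0]


def _target_plane_normal(frustum: Frustum, target: TargetLine2D) -> np.ndarray:
    u1 = backproject_pixel(frustum, target.entry).direction
    u2 = backproject_pixel(frustum, target.exit).direction
    n = np.cross(u1, u2)
    return n / np.linalg.norm(n)


def auto_align(
    tool: VirtualTool,
    frustums: Sequence[Frustum],
    targets: Sequence[TargetLine2D],
    initial_pose: Optional[RigidTransform] = None,
    mode: str = "viewing_ray",
    tol_px: float = 0.5,
    coplanarity_threshold: float = 1e-6,
    anchor_depth_fraction: float = 0.6,
) -> AutoAlignResult:
    """Run the staged alignment automatically against per-frustum targets.

    Stage 1 uses its translation DOF to re-anchor the tool origin on the
    backprojected ray of the first target's entry pixel (the origin then
    projects exactly onto the target line) and its spin theta to rotate the
    wire into the target's backprojection plane, zeroing the frustum-1
    residual. Stage 2 adjusts (phi, t_y) against the second frustum - DOF
    that are frustum-1 neutral in viewing-ray mode - and stage 3 slides the
    wire along itself to cover the targets longitudinally. Each angular DOF
    is solved by a coarse grid plus Levenberg-Marquardt refinement.
    """
    if len(frustums) != len(targets):
        raise ValueError("one target per frustum required")
    if len(frustums) == 0:
        raise ValueError("at least one frustum required")
    f1, t1 = frustums[0], targets[0]
    if initial_pose is None:
        initial_pose = RigidTransform()

    # stage-1 translation: anchor the origin on the entry-pixel ray of view 1,
    # at the depth of the initial origin (fallback: a mid-frustum depth)
    entry_ray = backproject_pixel(f1, t1.entry)
    depth = float((initial_pose.translation - entry_ray.origin) @ entry_ray.direction)
    if depth < 0.05 * f1.intrinsics.focal_length:
        depth = anchor_depth_fraction * f1.intrinsics.focal_length
    anchor = entry_ray.point_at(depth)
    t_local = initial_pose.rotation.T @ (anchor - initial_pose.translation)
    pre = StagedAlignment(tool, initial_pose, stage=1, anchor_frustum_id=f1.frustum_id)
    pre = apply_stage(pre, {"t_x": t_local[0], "t_y": t_local[1], "t_z": t_local[2]})
    aln = init_stage1(tool, pre.pose, f1, mode=mode)
    stage_params: Dict[int, Dict[str, float]] = {
        1: {"t_x": float(t_local[0]), "t_y": float(t_local[1]), "t_z": float(t_local[2])}
    }

    # stage-1 spin: rotate the wire into the target's backprojection plane
    normal1 = np.array([-t1.direction[1], t1.direction[0]])

    def s1_residual(x):
        cand = apply_stage(aln, {"theta": x[0]})
        tip = project_point(f1, cand.wire_endpoints_world()[1])
        return [(tip - t1.entry) @ normal1]

    best = None
    for theta0 in np.arange(0.0, 360.0, 15.0):
        sol = least_squares(s1_residual, [theta0], method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    theta = float(best.x[0])
    # of the two in-plane roots (theta, theta + 180) keep the one whose
    # projection points with the target's entry->exit direction
    seg = project_tool(apply_stage(aln, {"theta": theta}), f1)
    if (seg[1] - seg[0]) @ t1.direction < 0:
        theta += 180.0
    p1 = {"theta": theta}
    stage_params[1].update(p1)
    aln = apply_stage(aln, p1)

    if len(frustums) == 1:
        rms, _ = alignment_residual(project_tool(aln, f1), t1)
        pt, dr = aln.wire_line()
        return AutoAlignResult(
            aln, {f1.frustum_id: rms}, pt, dr, underdetermined=True,
            stage_params=stage_params,
        )

    f2, t2 = frustums[1], targets[1]
    # coplanarity check: the two target backprojection planes must differ
    n1 = _target_plane_normal(f1, t1)
    n2 = _target_plane_normal(f2, t2)
    coplanar = bool(np.linalg.norm(np.cross(n1, n2)) < coplanarity_threshold)

    # ---- stage 2: (phi, t_y) against frustum 2; psi would only spin the tool
    aln = aln.advance()
    normal2 = np.array([-t2.direction[1], t2.direction[0]])

    def s2_residual(x):
        cand = apply_stage(aln, {"phi": x[0], "t_y": x[1]})
        seg = project_tool(cand, f2)
        return (seg - t2.entry) @ normal2

    best = None
    for phi0 in np.arange(-90.0, 91.0, 10.0):
        sol = least_squares(s2_residual, [phi0, 0.0], method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    phi, t_y = float(best.x[0]), float(best.x[1])
    # phi + 180 keeps the same wire line (reversed); pick the orientation that
    # points with the target's entry->exit direction
    seg = project_tool(apply_stage(aln, {"phi": phi, "t_y": t_y}), f2)
    if (seg[1] - seg[0]) @ t2.direction < 0:
        phi += 180.0
    p2 = {"phi": phi, "psi": 0.0, "t_y": t_y, "t_z": 0.0}
    stage_params[2] = p2
    aln = apply_stage(aln, p2)

    # ---- stage 3: slide along the wire so the projection covers the targets
    aln = aln.advance()

    def s3_residual(x):
        cand = apply_stage(aln, {"t_z": x[0]})
        out = []
        for fr, tg in ((f1, t1), (f2, t2)):
            seg = project_tool(cand, fr)
            mid = seg.mean(axis=0)
            tmid = (tg.entry + tg.exit) / 2.0
            out.append((mid - tmid) @ tg.direction)
        return out

    sol = least_squares(s3_residual, [0.0], method="lm")
    p3 = {"psi": 0.0, "t_z": float(sol.x[0])}
    stage_params[3] = p3
    aln = apply_stage(aln, p3)

    residuals = {}
    for fr, tg in zip(frustums, targets):
        residuals[fr.frustum_id] = _wire_residual(aln, fr, tg)
    pt, dr = aln.wire_line()
    return AutoAlignResult(
        aln, residuals, pt, dr, underdetermined=False, coplanar=coplanar,
        stage_params=stage_params,
    )
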
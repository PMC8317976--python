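"""Hand-eye calibration between the X-ray source and its rigidly attached
visual tracker.

The scanner is posed at times t_i while an external tracker records the
source pose ^IR^T_X and the on-gantry visual tracker reports its own pose
^OR^T_H. Because both sensors are rigidly coupled by the unknown constant
X = ^X^T_H, corresponding relative motions satisfy A X = X B with

    A = T_X(t_{i+1})^-1 T_X(t_i),    B = T_H(t_{i+1})^-1 T_H(t_i).

Rotation and translation are solved separately. Writing the rotations as
unit quaternions q_A q_X = q_X q_B and splitting scalar/vector parts gives,
per motion pair, one homogeneous 4x4 block

    [[s_A - s_B,  (v_A - v_B)^T             ],
     [v_A - v_B,  (s_A - s_B) I_3 + [v_A + v_B]_x]]

acting on q_X = (s_X, v_X). Stacking N blocks into M (4N x 4), q_X is the
right singular vector of the smallest singular value of M (min ||M q|| s.t.
||q|| = 1). The translation then solves the stacked linear system
(R_A - I_3) t_X = R_X t_B - t_A in least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    RigidTransform,
    UnitQuaternion,
    compose,
    invert,
    quat_to_rotation,
    rotation_angle_deg,
    rotation_to_quat,
    skew,
)

__all__ = [
    "MotionPair",
    "HandEyeResult",
    "DegenerateMotionError",
    "make_motion_pairs",
    "build_rotation_system",
    "solve_rotation",
    "solve_translation",
    "calibrate",
    "sampling_experiment",
]

#: below this relative motion the translation system is ill-conditioned
DEFAULT_MIN_ANGLE_DEG = 5.0
#: sigma_3/sigma_4 of M below this flags an unobservable rotation axis
DEFAULT_DEGENERACY_GAP = 10.0


class DegenerateMotionError(ValueError):
    """The motion set does not constrain the calibration (e.g. no rotation)."""


@dataclass(frozen=True)
class MotionPair:
    """Relative source motion A and the matching tracker motion B."""

    A: RigidTransform
    B: RigidTransform

    def angle_mismatch_deg(self) -> float:
        """|angle(A) - angle(B)|: conjugate rotations share their angle, so a
        large mismatch flags a bad correspondence."""
        return abs(rotation_angle_deg(self.A.rotation) - rotation_angle_deg(self.B.rotation))


@dataclass(frozen=True)
class HandEyeResult:
    X: RigidTransform
    rotation_residual: float  # ||M q|| at the solution
    translation_residual_rms: float  # mm
    n_pairs: int
    degenerate: bool
    n_dropped: int = 0


def make_motion_pairs(
    source_poses: Sequence[RigidTransform],
    tracker_poses: Sequence[RigidTransform],
    pairing: str = "consecutive",
    min_angle_deg: float = DEFAULT_MIN_ANGLE_DEG,
    max_angle_mismatch_deg: float = 2.0,
) -> List[MotionPair]:
    """Build relative-motion pairs from time-aligned pose streams.

    ``pairing='consecutive'`` uses (t_i, t_{i+1}); ``'all'`` uses every index
    pair i < j. Pairs whose rotation is below ``min_angle_deg`` or whose
    A/B rotation angles disagree by more than ``max_angle_mismatch_deg`` are
    dropped (they carry little or inconsistent signal).
    """
    if len(source_poses) != len(tracker_poses):
        raise ValueError(
            f"pose lists must be time-aligned and equal length "
            f"({len(source_poses)} vs {len(tracker_poses)})"
        )
    if len(source_poses) < 2:
        raise ValueError("need at least 2 poses")
    if pairing == "consecutive":
        index_pairs = [(i, i + 1) for i in range(len(source_poses) - 1)]
    elif pairing == "all":
        n = len(source_poses)
        index_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        raise ValueError(f"unknown pairing strategy {pairing!r}")

    pairs = []
    for i, j in index_pairs:
        A = compose(invert(source_poses[j]), source_poses[i])
        B = compose(invert(tracker_poses[j]), tracker_poses[i])
        pair = MotionPair(A, B)
        if rotation_angle_deg(A.rotation) < min_angle_deg:
            continue
        if pair.angle_mismatch_deg() > max_angle_mismatch_deg:
            continue
        pairs.append(pair)
    if not pairs:
        raise DegenerateMotionError("no usable motion pairs after filtering")
    return pairs


def build_rotation_system(pairs: Sequence[MotionPair]) -> np.ndarray:
    """Stack one 4x4 quaternion block per motion pair into M (4N x 4)."""
    blocks = []
    for pair in pairs:
        qa = rotation_to_quat(pair.A.rotation)
        qb = rotation_to_quat(pair.B.rotation)
        block = np.zeros((4, 4))
        block[0, 0] = qa.s - qb.s
        block[0, 1:] = qa.v - qb.v
        block[1:, 0] = qa.v - qb.v
        block[1:, 1:] = (qa.s - qb.s) * np.eye(3) + skew(qa.v + qb.v)
        blocks.append(block)
    return np.vstack(blocks)


def solve_rotation(
    M: np.ndarray, degeneracy_gap: float = DEFAULT_DEGENERACY_GAP
) -> tuple:
    """min ||M q|| s.t. ||q|| = 1 via SVD.

    Returns (q_X, residual, degenerate). The solution is the right singular
    vector of the smallest singular value; when the two smallest singular
    values are closer than ``degeneracy_gap`` (ratio), the rotation axis set
    was (nearly) collinear and the answer is not unique -> degenerate flag.
    """
    if M.shape[0] < 8 or M.shape[1] != 4:
        raise ValueError("M must stack at least two 4x4 pair blocks")
    _, sv, Vt = np.linalg.svd(M)
    q = Vt[-1]
    quat = UnitQuaternion(q[0], q[1:])
    residual = float(sv[-1])
    # a second near-zero singular value means a whole family of quaternions
    # fits: the motion axes were (nearly) collinear
    floor = max(residual, 1e-12 * sv[0], 1e-300)
    degenerate = bool(sv[-2] < degeneracy_gap * floor)
    return quat, residual, degenerate


def solve_translation(pairs: Sequence[MotionPair], R_X: np.ndarray) -> tuple:
    """Least-squares solution of the stacked (R_A - I) t_X = R_X t_B - t_A.

    Returns (t_X, rms residual in mm). Raises DegenerateMotionError when all
    A rotations are (near) identity, which leaves the system singular.
    """
    rows = []
    rhs = []
    for pair in pairs:
        rows.append(pair.A.rotation - np.eye(3))
        rhs.append(R_X @ pair.B.translation - pair.A.translation)
    C = np.vstack(rows)
    d = np.concatenate(rhs)
    sv = np.linalg.svd(C, compute_uv=False)
    if sv[0] < 1e-12 or sv[2] / sv[0] < 1e-9:
        raise DegenerateMotionError(
            "translation system is singular: motion rotations do not span enough axes"
        )
    t, *_ = np.linalg.lstsq(C, d, rcond=None)
    rms = float(np.sqrt(np.mean((C @ t - d) ** 2)))
    return t, rms


def calibrate(
    source_poses: Sequence[RigidTransform],
    tracker_poses: Sequence[RigidTransform],
    pairing: str = "consecutive",
    min_angle_deg: float = DEFAULT_MIN_ANGLE_DEG,
    degeneracy_gap: float = DEFAULT_DEGENERACY_GAP,
) -> HandEyeResult:
    """Full pipeline: pair motions, solve rotation (SVD), then translation."""
    n_candidates = (
        len(source_poses) - 1
        if pairing == "consecutive"
        else len(source_poses) * (len(source_poses) - 1) // 2
    )
    pairs = make_motion_pairs(source_poses, tracker_poses, pairing, min_angle_deg)
    M = build_rotation_system(pairs)
    q, rot_residual, degenerate = solve_rotation(M, degeneracy_gap)
    R_X = quat_to_rotation(q)
    t_X, trans_rms = solve_translation(pairs, R_X)
    return HandEyeResult(
        X=RigidTransform(R_X, t_X),
        rotation_residual=rot_residual,
        translation_residual_rms=trans_rms,
        n_pairs=len(pairs),
        degenerate=degenerate,
        n_dropped=n_candidates - len(pairs),
    )


def _pose_errors(estimate: RigidTransform, truth: RigidTransform) -> tuple:
    dR = estimate.rotation.T @ truth.rotation
    return rotation_angle_deg(dR), float(np.linalg.norm(estimate.translation - truth.translation))


def sampling_experiment(
    source_poses: Sequence[RigidTransform],
    tracker_poses: Sequence[RigidTransform],
    true_X: RigidTransform,
    n_values: Sequence[int],
    reps: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    **calibrate_kwargs,
) -> pd.DataFrame:
    """Monte-Carlo pose-sampling study of calibration accuracy.

    For each N in ``n_values``, ``reps`` random subsets of N poses are drawn
    from the pool, calibrated, and compared against the known ground-truth X.
    Returns a table of mean/SD rotation (deg) and translation (mm) errors,
    mirroring how accuracy-vs-pose-count is usually reported.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    pool = len(source_poses)
    rows = []
    for n in n_values:
        if n > pool:
            raise ValueError(f"cannot sample {n} poses from a pool of {pool}")
        rot_err, trans_err = [], []
        for _ in range(reps):
            idx = np.sort(rng.choice(pool, size=n, replace=False))
            try:
                res = calibrate(
                    [source_poses[i] for i in idx],
                    [tracker_poses[i] for i in idx],
                    **calibrate_kwargs,
                )
            except DegenerateMotionError:
                continue
            e_rot, e_trans = _pose_errors(res.X, true_X)
            rot_err.append(e_rot)
            trans_err.append(e_trans)
        rot_err = np.asarray(rot_err)
        trans_err = np.asarray(trans_err)
        rows.append(
            {
                "n_poses": n,
                "n_successful": len(rot_err),
                "rot_err_mean_deg": rot_err.mean() if len(rot_err) else np.nan,
                "rot_err_sd_deg": rot_err.std() if len(rot_err) > 1 else 0.0,
                "rot_err_median_deg": float(np.median(rot_err)) if len(rot_err) else np.nan,
                "trans_err_mean_mm": trans_err.mean() if len(trans_err) else np.nan,
                "trans_err_sd_mm": trans_err.std() if len(trans_err) > 1 else 0.0,
                "trans_err_median_mm": float(np.median(trans_err)) if len(trans_err) else np.nan,
            }
        )
    return pd.DataFrame(rows)
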
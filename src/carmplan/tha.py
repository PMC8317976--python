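"""Acetabular cup planning relative to the anterior pelvic plane (APP).

The APP is spanned by three pelvic landmarks: the left and right anterior
superior iliac spines (ASIS) and the pubic symphysis. Cup orientation is
expressed in the radiographic convention:

* anteversion = out-of-plane tilt, arcsin of the cup axis' component along
  the anterior APP normal;
* abduction = in-plane angle between the APP-projection of the cup axis and
  the longitudinal (caudal -> cranial) axis.

The two definitions live in ``cup_angles`` / ``desired_cup_axis`` and are
exact inverses of each other on (0, 90) x (0, 90) degrees. Clinical safe-zone
targets in this toolkit default to 40 deg abduction / 15 deg anteversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .frustum import Frustum
from .reconstruction import Annotation, annotation_ray, triangulate

__all__ = [
    "APPFrame",
    "CupPlan",
    "build_app",
    "cup_angles",
    "desired_cup_axis",
    "plan_cup",
    "cup_angle_error",
    "APP_LANDMARKS",
]

#: landmark labels plan_cup expects in the annotation set
APP_LANDMARKS = ("l_asis", "r_asis", "pubis", "acetabulum")


@dataclass(frozen=True)
class APPFrame:
    """Right-handed orthonormal anatomical frame anchored at the pubis.

    transverse:   right ASIS -> left ASIS
    longitudinal: caudal -> cranial, in-plane
    normal:       anterior
    """

    origin: np.ndarray
    transverse: np.ndarray
    longitudinal: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        for name in ("origin", "transverse", "longitudinal", "normal"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        R = np.column_stack([self.transverse, self.longitudinal, self.normal])
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("APP axes must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("APP axes must be right-handed")


@dataclass(frozen=True)
class CupPlan:
    center: np.ndarray
    axis: np.ndarray
    abduction: float
    anteversion: float
    residuals_mm: Optional[Dict[str, float]] = None


def build_app(l_asis, r_asis, pubis, anterior_reference=None) -> APPFrame:
    """Construct the APP frame from the three pelvic landmarks.

    The anterior normal is transverse x longitudinal, which points anterior
    for anatomically labelled landmarks. If ``anterior_reference`` (a point
    expected to lie posterior, e.g. the acetabulum centre) is given and found
    on the anterior side, the normal and longitudinal axes are flipped with a
    warning - that combination keeps the frame right-handed and indicates the
    landmarks were supplied with inverted orientation.
    """
    l = np.asarray(l_asis, float).reshape(3)
    r = np.asarray(r_asis, float).reshape(3)
    p = np.asarray(pubis, float).reshape(3)
    t = l - r
    tn = np.linalg.norm(t)
    mid = (l + r) / 2.0
    up = mid - p
    if tn < 1e-9 or np.linalg.norm(np.cross(t, up)) < 1e-9:
        raise ValueError("APP landmarks are collinear (or coincident)")
    t = t / tn
    up = up - (up @ t) * t  # in-plane component orthogonal to transverse
    up = up / np.linalg.norm(up)
    n = np.cross(t, up)
    if anterior_reference is not None:
        ref = np.asarray(anterior_reference, float).reshape(3)
        if (ref - p) @ n > 0:
            warnings.warn(
                "anterior reference lies on the anterior side; flipping the APP "
                "normal (landmark orientation looks inverted)",
                stacklevel=2,
            )
            n, up = -n, -up
    return APPFrame(p, t, up, n)


def cup_angles(axis, app: APPFrame, degeneracy_tol: float = 1e-9) -> Tuple[float, float]:
    """(abduction deg, anteversion deg) of a unit cup axis w.r.t. the APP.

    When the axis is normal to the APP the in-plane projection vanishes and
    abduction is reported as 0 with a warning (degenerate).
    """
    a = np.asarray(axis, float).reshape(3)
    a = a / np.linalg.norm(a)
    ante = np.degrees(np.arcsin(np.clip(a @ app.normal, -1.0, 1.0)))
    proj = a - (a @ app.normal) * app.normal
    if np.linalg.norm(proj) < degeneracy_tol:
        warnings.warn("cup axis is normal to the APP; abduction undefined, reporting 0",
                      stacklevel=2)
        return 0.0, float(ante)
    abd = np.degrees(np.arctan2(proj @ app.transverse, proj @ app.longitudinal))
    return float(abd), float(ante)


def desired_cup_axis(app: APPFrame, abduction: float, anteversion: float) -> np.ndarray:
    """Unit cup axis realising the given angles; exact inverse of cup_angles."""
    abd = np.radians(abduction)
    ante = np.radians(anteversion)
    in_plane = np.cos(abd) * app.longitudinal + np.sin(abd) * app.transverse
    return np.sin(ante) * app.normal + np.cos(ante) * in_plane


def plan_cup(
    annotations: Sequence[Annotation],
    frustums: Dict[str, Frustum],
    abduction: float = 40.0,
    anteversion: float = 15.0,
) -> CupPlan:
    """Triangulate the APP landmarks and the acetabulum centre from >= 2 views
    each, then orient the cup axis at the target angles.

    ``annotations`` carry labels from APP_LANDMARKS; every landmark must be
    annotated in at least two distinct frustums.
    """
    rays: Dict[str, list] = {name: [] for name in APP_LANDMARKS}
    for ann in annotations:
        if ann.label not in rays:
            continue
        if ann.frustum_id not in frustums:
            raise ValueError(f"annotation references unknown frustum {ann.frustum_id!r}")
        rays[ann.label].append(annotation_ray(frustums[ann.frustum_id], ann))
    points: Dict[str, np.ndarray] = {}
    residuals: Dict[str, float] = {}
    for name, rr in rays.items():
        if len(rr) < 2:
            raise ValueError(
                f"landmark {name!r} must be annotated in at least two views "
                f"(got {len(rr)})"
            )
        rec = triangulate(rr)
        points[name] = rec.x_star
        residuals[name] = rec.residual
    app = build_app(points["l_asis"], points["r_asis"], points["pubis"],
                    anterior_reference=points["acetabulum"])
    axis = desired_cup_axis(app, abduction, anteversion)
    return CupPlan(points["acetabulum"], axis, float(abduction), float(anteversion),
                   residuals_mm=residuals)


def cup_angle_error(achieved_axis, app: APPFrame,
                    target: Tuple[float, float] = (40.0, 15.0)) -> Tuple[float, float]:
    """Absolute (delta abduction, delta anteversion) in degrees vs the target."""
    abd, ante = cup_angles(achieved_axis, app)
    return abs(abd - target[0]), abs(ante - target[1])
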
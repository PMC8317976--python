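"""K-wire trajectory planning from two X-ray views, both ways.

A tubular bone-canal phantom is imaged by two C-arm frustums 90 degrees
apart. The canal's entry/exit appear as 2D annotations in each view. The
trajectory is reconstructed (a) by intersecting the two backprojection
planes (ray method) and (b) by the staged DOF-constrained alignment of a
virtual drill whose projections must match both targets (tool method).
"""

import numpy as np

from carmplan import (
    TargetLine2D,
    Trajectory3D,
    TubePhantom,
    VirtualTool,
    auto_align,
    orbit_frustums,
    project_point,
    trajectory_from_views,
    wire_error,
)

frustums = orbit_frustums([0.0, 0.0, 0.0], [0.0, 90.0])
tube = TubePhantom()  # ~10 mm canal, oblique through the isocenter
targets = [
    TargetLine2D(fr.frustum_id, project_point(fr, tube.entry), project_point(fr, tube.exit))
    for fr in frustums
]
truth = tube.centerline

ray_traj = trajectory_from_views(
    targets[0].entry, targets[0].exit, frustums[0],
    targets[1].entry, targets[1].exit, frustums[1],
)
angle = np.degrees(np.arccos(np.clip(abs(ray_traj.direction @ truth.direction), 0, 1)))
print(f"ray method:  direction error {angle:.2e} deg, "
      f"wire error {wire_error(ray_traj, tube):.2e} mm")

result = auto_align(VirtualTool(wire_length=100.0), frustums, targets)
tool_traj = Trajectory3D(result.line_point, result.line_direction)
angle = np.degrees(np.arccos(np.clip(abs(tool_traj.direction @ truth.direction), 0, 1)))
print(f"tool method: direction error {angle:.2e} deg, "
      f"wire error {wire_error(tool_traj, tube):.2e} mm")
print(f"tool method residuals per view (px): "
      + ", ".join(f"{k}={v:.1e}" for k, v in result.residuals_px.items()))
print("\nBoth methods recover the 3D drilling line exactly from noiseless "
      "annotations; the wire error is the mean distance from the planned wire "
      "to the canal centerline at the entry and exit faces.")
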
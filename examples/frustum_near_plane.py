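"""The flying frustum: sliding the X-ray image along its own pyramid of vision.

One acquisition defines a pyramid with apex at the source and base at the
detector (focal distance f). The image can be displayed on a near plane at
any distance n in [0, f]; its coordinates simply scale by n/f and the image
pose translates n millimetres along the principal axis, so the picture stays
a geometrically valid view of the same anatomy.
"""

import numpy as np

from carmplan import Frustum, image_pose, project_point, scale_to_near, backproject_pixel

frustum = Frustum()  # source at origin viewing +z, f = 1000 mm, 1024 px
point = np.array([30.0, -15.0, 750.0])

print("world point:", point, "mm")
for n in (1000.0, 500.0, 250.0):
    px = project_point(frustum, point, near=n)
    pose = image_pose(frustum, n)
    print(f"  n = {n:6.1f} mm -> image coords {np.round(px, 3)} px, "
          f"image plane at z = {pose.translation[2]:.0f} mm")

detector_px = project_point(frustum, point)
print("scaling check: detector pixel", np.round(detector_px, 3),
      "scaled by n/f = 0.5 ->", np.round(scale_to_near(detector_px, 500.0, 1000.0), 3))

ray = backproject_pixel(frustum, detector_px)
print("backprojection ray direction:", np.round(ray.direction, 6))
print("\nHalving n exactly halves the image coordinates while the "
      "backprojection ray (and therefore all 3D reasoning) is unchanged.")
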
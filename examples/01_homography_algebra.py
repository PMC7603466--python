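"""4-point homographies: conversions, decomposition, accumulation.

Builds a rigid transform (rotation + translation, the motion model of a
scope pivoting about its incision point), converts it between the 3x3
and 4-point corner-displacement parameterizations, decomposes it into
rotation-scale-rotation parameters, and accumulates a short chain of
pairwise transforms into a reference frame.
"""

import numpy as np

from fetomosaic import (
    compose_relative,
    decompose,
    default_corners,
    fourpt_to_matrix,
    matrix_to_fourpt,
    rigid_matrix,
)

# a 3 deg rotation with an (8, -5) px translation
h = rigid_matrix(3.0, 8.0, -5.0, degrees=True)
corners = default_corners(128, 128)

fp = matrix_to_fourpt(h, corners)
print("corner displacements (du, dv) per corner:")
for c, d in zip(fp.corners, fp.displacements):
    print(f"  corner {c} -> displacement ({d[0]:+.3f}, {d[1]:+.3f})")

h_back = fourpt_to_matrix(fp)
print(f"\nround-trip matrix error: {np.abs(h_back - h).max():.2e}")

d = decompose(h)
print(f"decomposition: theta={np.rad2deg(d.theta):+.3f} deg, "
      f"gamma={np.rad2deg(d.gamma):+.3f} deg, "
      f"scales=({d.s_g:.6f}, {d.s_h:.6f}), t=({d.t_x:+.1f}, {d.t_y:+.1f})")
print("-> a rigid map: unit scales, no second rotation, the full 3 deg in theta")

# accumulate 5 identical pairwise transforms into frame 0's plane
relative = compose_relative([h] * 5, reference_index=0)
print(f"\nframe 5 relative to frame 0 (translation part): "
      f"({relative[5][0, 2]:+.2f}, {relative[5][1, 2]:+.2f}) px")
print("-> the chained motion of 5 frames, each rotated+shifted by the same step")
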
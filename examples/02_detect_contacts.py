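"""Automatic contact detection in the phantom CT.

Builds the brain and projection surfaces from the tissue maps, then runs
the threshold-stability search: 21 thresholds spanning the 99th-100th
intensity percentile, contact-sized connected components inside the
projection surface, optimal threshold at the center of the widest stable
stretch of the detection curve.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from electrolocate import PhantomSpec, auto_detect, build_surfaces, make_head_phantom

spec = PhantomSpec(seed=0)
ct, gm, wm, atlas, fields, truth = make_head_phantom(spec)
brain, projection = build_surfaces(gm, wm)

result = auto_detect(ct, projection)
print(f"optimal threshold: {result.optimal_threshold_hu:.0f} HU")
print("detection curve (threshold HU -> n detected):")
for t, n in result.curve[::4]:
    print(f"  {t:7.0f} -> {n}")

detected = result.electrodes.positions
planted = truth.positions_mm
D = np.linalg.norm(detected[:, None] - planted[None], axis=2)
rows, cols = linear_sum_assignment(D)
print(f"\ndetected {len(detected)} of {len(planted)} planted contacts")
print(f"worst centroid error: {D[rows, cols].max():.3f} mm "
      f"({D[rows, cols].max() / spec.voxel_mm:.2f} voxels)")
print("A perfect run finds every planted blob with sub-voxel centroid error")
print("and no false positives (skull voxels are excluded by the volume filter")
print("and the projection-surface interior test).")
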
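"""Generate a synthetic humerus-like phantom and fracture it.

Builds the default intact phantom (spherical head + cylindrical shaft +
tuberosity bumps, bright cortical shell over a dimmer trabecular
interior), applies a 3-part surgical-neck-style fracture with a
comminution void, and reports the exported ground truth.
"""

import numpy as np

import fracmap as fm
from fracmap.studies import default_fracture_spec

intact = fm.make_intact_phantom(fm.ShapeParams(), seed=0)
volume, truth = intact
print(f"intact volume: {volume.shape} voxels at {volume.spacing} mm")
print(f"cortical shell: {truth.intact_mask.sum()} voxels, "
      f"interior: {truth.interior_mask.sum()} voxels")
print(f"landmarks: {', '.join(truth.landmarks.names)}")

spec = default_fracture_spec(truth, comminution_radius=1.5, seed=0)
fractured, ftruth = fm.apply_fracture(intact, spec)
print(f"\nfracture: {len(spec.cut_surfaces)} cuts -> "
      f"{len(ftruth.fragment_labels.ids)} fragments "
      f"{[int((ftruth.fragment_labels.labels == i).sum()) for i in ftruth.fragment_labels.ids]} voxels")
print(f"comminution removed {ftruth.removed_voxels.sum()} cortical voxels")
print(f"cut rim curves: {[len(c) for c in ftruth.cut_curves]} points each")
# The rim curves are the true fracture lines on the intact outer
# surface; they are the reference every traced line is scored against.
rim = np.vstack(ftruth.cut_curves)
print(f"rim extent (z): {rim[:, 2].min():.1f}..{rim[:, 2].max():.1f} mm")
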
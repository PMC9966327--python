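"""Virtually reduce a displaced fragment onto the intact template.

The head fragment is displaced by a known rigid transform (as a real
fracture would be) and registered back onto the intact outer surface by
point-to-plane ICP.  The printed errors compare the recovered pose with
the known displacement: sub-degree / sub-0.1 mm values mean the virtual
reduction found the anatomical position.
"""

import numpy as np
import trimesh

import fracmap as fm
from fracmap.core import RigidTransform
from fracmap.fracture_lines import mesh_fragment, outer_vertex_mask
from fracmap.phantom import FractureSpec, PlanarCut
from fracmap.reduction import principal_axis_init, reduce_fragment

intact = fm.make_intact_phantom(fm.ShapeParams())
fo = intact[1].frame_origin
spec = FractureSpec(cut_surfaces=[PlanarCut(
    point=tuple(fo + [0, 0, -0.75 * 6.5]), normal=(0.15, 0.1, 1.0))])
_, truth = fm.apply_fracture(intact, spec)

mesh = mesh_fragment(truth.fragment_labels, 2, smooth_sigma=1.0)
outer = outer_vertex_mask(mesh, truth.fragment_labels.labels > 0,
                          truth.spacing, truth.origin)
template = intact[1].outer_surface(smooth_sigma=1.0)

rng = np.random.default_rng(4)
axis = rng.normal(size=3); axis /= np.linalg.norm(axis)
angle = np.radians(12.0)
K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
              [-axis[1], axis[0], 0]])
R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
pivot = mesh.vertices.mean(axis=0)
T = RigidTransform(rotation=R, translation=pivot - R @ pivot + [3.0, -2.0, 1.0])
displaced = trimesh.Trimesh(vertices=T.apply(mesh.vertices), faces=mesh.faces,
                            process=False)
print(f"applied displacement: {T.rotation_angle_deg():.1f} deg, "
      f"{np.linalg.norm([3.0, -2.0, 1.0]):.1f} mm")

result = min(
    (reduce_fragment(displaced, template, init=init, vertex_mask=outer, seed=0)
     for init in (None, principal_axis_init(displaced, template))),
    key=lambda r: r.residual)
err = result.transform.compose(T)
print(f"ICP: {len(result.residual_history)} iterations, "
      f"residual {result.residual:.3f} mm, converged={result.converged}")
print(f"pose recovery error: {err.rotation_angle_deg():.2f} deg, "
      f"{np.linalg.norm(err.apply(pivot[None])[0] - pivot):.3f} mm")
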
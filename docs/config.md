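# Study configuration (YAML)

`fracmap run --config study.yaml` validates the file against the
`StudyConfig` schema (unknown keys are rejected) and executes a full
phantom study. All keys are optional; values below are the defaults.

```yaml
seed: 0                  # master seed, split deterministically per case/stage
out_dir: null            # persist per-case artifacts and maps here

segmentation:
  window_radius: 8       # voxels; adaptive-threshold window half-size
  min_contrast: 100.0    # intensity; windows below this range are background
  connectivity: 26       # 6 or 26
  min_voxels: 27         # discard smaller fragments as noise

lines:
  quantile: 0.90         # curvature quantile for guide-marker candidates
  floor: 0.25            # 1/mm; absolute curvature floor
  w_boundary: 1.0        # ridge-distance weight in the edge cost
  w_angle: 1.0           # dihedral-deviation weight
  min_markers: 2
  close_gap: 4.0         # mm; geodesic end gap below which loops close
  close_fraction: 0.2    # ... or this fraction of the open path length
  smooth_sigma: 1.0      # voxels; indicator smoothing before meshing
  outer_only: true       # keep lines on the outer cortical surface
  convex_only: true      # fracture rims are convex creases
  valley_refine: true    # re-center lines on the radiolucent cleft
  border_dist: 3.0       # mm; fracture borders face another fragment

reduction:
  max_iterations: 200
  tol: 1.0e-4            # mm; residual-change convergence threshold
  sample: 2500           # fragment vertices used per ICP iteration

ssm:
  with_scaling: true     # similarity (vs rigid) Procrustes
  n_secondary: 5         # secondary landmarks per connecting line
  connecting_lines:      # named primary-landmark pairs
    - [head_apex, greater_tuberosity]
    - [head_apex, lesser_tuberosity]
    - [greater_tuberosity, shaft_lateral]
    - [lesser_tuberosity, shaft_anterior]
    - [head_medial, shaft_medial]
    - [neck_posterior, shaft_posterior]

mapping:
  line_radius: null      # mm; default 1.5x mean edge length of the mean surface
  fragment_max_dist: 1.0 # mm; case point counts as covered within this distance
```

A top-level `study:` block passes keyword arguments to
`fracmap.studies.run_phantom_study` (e.g. `n_cases`, `right_fraction`,
`displace_deg`, `comminution_radius`, `noise_sd`, `grid`).

Exit codes of `fracmap run`: 2 = configuration error, 4 = study error.
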
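# Methods

This note documents the models, algorithms and design choices behind
`fracmap`, and what the synthetic phantoms do and do not establish
about performance on clinical data.

## Synthetic phantom

The phantom is an analytic signed-distance body: a sphere ("humeral
head") unioned with a capped cylinder ("shaft"), plus Gaussian surface
bumps for the greater and lesser tuberosities. The cortical shell is
the signed-distance band `[-cortical_thickness, 0]`, so ground-truth
masks, the outer surface, cut rim curves and landmark positions are
exact by construction and do not depend on a second segmentation.

Default geometry is a scaled-down proximal humerus sized to a
64³ grid at 0.5 mm spacing with margin: head radius 6.5 mm, shaft
radius 4 mm, shaft length 14 mm, cortical thickness 1.5 mm, two
tuberosity bumps (1.2 / 0.8 mm amplitude, σ = 2.2 mm). Rendered
intensities are fixed at background 0, trabecular interior 200,
cortex 700 (arbitrary CT-like units giving bimodal contrast comparable
to cortical bone on clinical CT), optionally followed by Gaussian blur
(FWHM in mm) and additive Gaussian noise. Working at this reduced
anatomical scale keeps every end-to-end test and the acceptance script
fast while preserving the geometric structure of the problem (shell
topology, rim creases, near-symmetric fragments).

Fractures are applied by partitioning the body with parametric cut
surfaces (planes or quadratic sheets): voxels are assigned to
fragments by the sign pattern of all cuts plus 26-connectivity,
comminution spheres delete cortical voxels, and each fragment is
rigidly displaced (nearest-neighbour label resampling, linear
grayscale). Fragment ids are ordered by descending cortical voxel
count with a C-order tie-break, so outputs are deterministic.

A minimally displaced fracture is invisible in a naively rendered
volume (both sides of the cut are cortex-bright). Real CT shows a thin
radiolucent cleft at the fracture; the phantom therefore dims cortical
voxels within `cleft_half_width` (default 0.45 mm) of a cut surface to
`cleft_intensity` (default 450). This is what gives the gradient-based
splitter and the intensity-valley line refinement something physical to
work with. Cut rim curves — the reference for every line-accuracy
measurement — are computed as the zero-level set of the cut function
interpolated along the edges of the exact outer-surface mesh.

Solid test phantoms (`make_solid_phantom`, ball or cube) isolate
cut/tracing behaviour from shell geometry.

Cohort sampling perturbs shape fields with per-field relative SDs
(defaults ≈ 5–10 %) using one documented RNG stream, with the
left/right side drawn first for all cases; identical seeds reproduce
cohorts bit for bit.

## Segmentation

Adaptive thresholding is local mid-range thresholding: a voxel is
foreground iff its value reaches `local_mean + offset` where the
contrast-dependent offset shifts the threshold to
`(local_min + local_max)/2` over a `(2r+1)³` window (default r = 8),
and the window range is at least `min_contrast` (default 100). On a
noise-free two-level phantom this recovers the cortical mask exactly;
on volumes with drifting shell and background intensities it separates
them where no global threshold can.

The marker-driven splitter follows descending gradient magnitude
(central differences over physical spacing, computed once from the
input grayscale; ties broken toward the smaller C-order index) and
removes voxels until no two marker groups are connected. This is
implemented as a binary search for the minimal removal prefix — 
equivalent to the sequential loop because disconnection is monotone
under further removal — followed by a re-add pass in removal order
that returns every voxel whose return joins no two groups (tracked
incrementally with a union-find). Kept voxels disconnected from every
marker (isolated pockets) are assigned the group of the nearest
labelled voxel so that labels plus the removed barrier exactly
partition the input mask. Marker voxels themselves are never removed.
The surviving barrier is a one-voxel separator whose exact position
within the cleft's high-gradient band can wander by a voxel or two;
this is inherent to the voxel process and is compensated downstream by
the line refinement.

Fragments below 27 voxels (configurable) are discarded as noise.

## Fracture-line detection

Fragment meshes come from marching cubes on the (optionally
Gaussian-smoothed, default σ = 1 voxel) fragment indicator, oriented
outward. Discrete mean curvature is the cotangent-Laplacian
mean-curvature-normal norm halved, with barycentric vertex areas;
boundary or degenerate vertices inherit the nearest interior value; a
signed variant uses the vertex normals (positive = convex).

Guide markers are vertices above both a curvature quantile (default
0.90) and an absolute floor (default 0.25 /mm — a smooth head of
radius ≥ 4 mm stays below it), thinned by geodesic non-maximum
suppression (radius 2× mean edge length). The pipeline additionally
keeps only markers that are (a) on the outer cortical surface
(exterior-air adjacency after morphologically sealing the clefts),
(b) convex creases, and (c) within `border_dist` (default 3 mm) of
another fragment — a fragment border is a fracture border only where
it faces an opposing fragment across the cleft.

Tracing orders markers by a nearest-neighbour tour on pairwise
geodesic costs refined by 2-opt (delta-evaluated, five starts, best
kept — single-start 2-opt was observed to lock into double-lap tours
when markers lie on two parallel crease shoulders). Consecutive
markers are joined by least-cost paths where edge cost is
`length × (1 + w_b · min(d_ridge/ℓ̄, 4) + w_a · (1 − φ/(π/2))₊)` with
`d_ridge` the geodesic distance to the high-curvature ridge, `ℓ̄` the
mean edge length and `φ` the dihedral angle between adjacent faces;
both weights default to 1. The ridge term is capped at 4 so that a
short ridge-free stretch is never costlier than detouring around the
fragment. The loop closes when the tour ends are within a geodesic gap
(default 3× mean edge length, or 20 % of the open path length in the
pipeline, where borders are loops).

The raw trace runs along its own fragment's crease, half a cleft width
off the true fracture plane, and the segmentation barrier adds its own
voxel-scale wander. Three refinements correct this using only observed
data: (1) midpoint refinement moves each point halfway to its closest
point on the opposing fragments; (2) valley refinement re-centers each
point on the radiolucent intensity valley, sampled along the surface
binormal 0.6 mm beneath the sealed outer surface (valley = samples
below 0.8× the profile maximum; runs touching the sampling window
edge are background air and ignored); (3) Laplacian polyline smoothing
and a final projection onto the sealed outer surface remove zigzag and
restore the point depth. On planar-cut solid phantoms at 0.5 mm
spacing the traced border's symmetric Hausdorff distance to the true
rim is ≈ 1 voxel; on hollow-shell phantoms worst-case errors reach
≈ 2 mm near the inner/outer rim ambiguity, which the probability-map
kernel absorbs.

## Virtual reduction

Registration is point-to-plane ICP of fragment vertices against the
template surface: exact closest-point queries (KDTree candidates over
triangle centroids with a verification pass, so results equal the
exhaustive answer), a linearized twist solve, and step-halving
backtracking that guarantees a non-increasing RMS point-to-surface
residual. Correspondences beyond 2.5× the median distance are trimmed
from each step. Convergence is declared when the residual improves by
less than 1e-4 mm (max 200 iterations); non-convergence sets a flag
rather than raising.

The pipeline registers only outer-cortex vertices (cut faces and the
medullary wall have no counterpart on the intact template) and runs
two starts — in place, and centroid-aligned — keeping the lower
residual. In-place initialization reflects the clinical setting where
fragments lie near their anatomical site; centroid alignment rescues
larger global offsets. Pose recovery for displacements up to 20° /
10 mm is sub-degree and sub-0.1 mm for geometrically identifiable
fragments (shaft, head with tuberosities). Recovery is evaluated at
0.35 mm voxels: the bumps pinning the head's axial rotation are
~1 mm tall, so at coarser spacing voxelization noise is of the same
order as that rotational signal and equal-residual wrong poses
appear. Near-symmetric fragments
(bare spherical caps) admit equal-residual wrong poses for any rigid
registration method — the clinical remedy is manual reduction, and
the API accepts externally supplied transforms for exactly this case.
Uniform scaling is fixed at 1 (the contralateral is assumed
size-matched).

The mirror plane for contralateral templates defaults to the grid's
first-axis mid-plane and is configurable; mirroring reverses triangle
winding so outward normals and signed volumes are preserved.

## Mean shape and probability maps

Generalized Procrustes alignment iterates similarity (or rigid)
Kabsch fits of every configuration to the running mean until the mean
moves less than 1e-6× centroid size (max 100 iterations); the mean is
centered at the origin and, in similarity mode, restored to the
cohort's average centroid size. Scaling is enabled by default: the
probability maps are about pattern location, not bone size.

Secondary landmarks are placed at equal arc-length fractions along
graph-geodesic connecting lines between named primary landmarks (the
connecting-line set and count are configuration). Dense
correspondence warps the template case (the case closest to the mean
configuration) onto every member with a thin-plate-spline landmark
interpolant followed by exact closest-point refinement; each mean
vertex stores a case triangle id plus barycentric coordinates, so
matched points reconstruct exactly on the case surface. Matches
farther than 10× the mean edge length are flagged, and more than 5 %
flagged vertices is an error.

Line incidence: a case's projected lines are resampled at half the
kernel radius, pulled back through the inverse correspondence (nearest
corresponded mean vertex), and all mean vertices within the geodesic
kernel radius (default 1.5× mean edge length) of a hit are flagged.
Fragment incidence: a mean vertex is flagged iff its corresponded case
point lies within `fragment_max_dist` (default 1 mm) of a reduced
fragment surface. Both channels are binarized per case before
summation, so a vertex count is the number of cohort cases — never
inflated by multiplicity.

## What the phantom studies show — and what they do not

Passing tests establish that each algorithm implements its contract
and that the pipeline composes correctly: exact conservation laws,
known-displacement recovery, σ/√N noise averaging, and probability
maps whose structure matches the programmed fracture exactly (counts
are 0 or N, the fracture band follows the rim, fragment-map holes
coincide with comminution). The phantoms do not emulate trabecular
texture, beam hardening, metal artefacts, osteoporotic cortical
thinning, anatomical variation beyond smooth parameter perturbation,
or the ambiguity of real comminuted margins; clinical accuracy claims
would require validation against expert segmentations, as would the
inter-operator reproducibility of a manual reduction, which has no
synthetic counterpart here.

## Numerical choices and degenerate inputs

Tolerances: rigid rotations validated to 1e-9 orthonormality; ICP
convergence 1e-4 mm; Procrustes 1e-6× centroid size; line metrics
resample at 0.5 mm by default. Ties are always broken
deterministically (C-order voxel index; marker id; lower fragment id),
and every stochastic step takes an explicit seed, so identical inputs
give byte-identical outputs. Degenerate inputs raise early: cuts that
do not divide the shell, markers outside the mask, collinear landmark
configurations, mixed-channel accumulation, mismatched grid
geometries.

## Known limitations

- Hollow-shell border tracing can lock onto the inner cortical rim in
  regions where the outer filter is ambiguous; worst-case rim error is
  ≈ 4 voxels there.
- The splitter's barrier position within the cleft is determined by
  gradient ordering and re-add order, not by sub-voxel cleft geometry.
- Thin-plate-spline correspondence is only as anatomical as the
  landmark set; with few landmarks the warp under-constrains regions
  far from any landmark.
- ICP cannot disambiguate near-symmetric fragments; supply manual
  transforms for those.
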
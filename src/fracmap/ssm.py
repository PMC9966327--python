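"""Landmark-based statistical mean shape of the intact cohort.

Primary anatomical landmarks are densified with secondary landmarks
placed at equal arc-length fractions along on-surface geodesic
connecting lines; the landmark configurations of all (left-side)
cases are brought into a common frame by generalized Procrustes
analysis; and a mean surface with dense per-case correspondence is
built by warping a template case onto every cohort member with a
landmark-interpolating smooth deformation (thin-plate-spline kernel)
followed by closest-point refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree

from . import _geometry
from .core import LandmarkSet, RigidTransform


@dataclass
class CorrespondenceMap:
    """For each mean-surface vertex: matched case triangle + barycentric coords."""

    triangle_ids: np.ndarray
    barycentric: np.ndarray
    case_id: str = ""

    def __post_init__(self) -> None:
        self.triangle_ids = np.asarray(self.triangle_ids, dtype=np.int64)
        self.barycentric = np.asarray(self.barycentric, dtype=float)
        if self.barycentric.shape != (len(self.triangle_ids), 3):
            raise ValueError("barycentric must be (n, 3)")
        if np.any(self.barycentric < -1e-9):
            raise ValueError("barycentric coordinates must be non-negative")
        if not np.allclose(self.barycentric.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("barycentric coordinates must sum to 1")

    def matched_points(self, surface: trimesh.Trimesh) -> np.ndarray:
        """Reconstruct the matched case-surface point per mean vertex."""
        tri = surface.triangles.view(np.ndarray)[self.triangle_ids]
        return (tri * self.barycentric[:, :, None]).sum(axis=1)


@dataclass
class MeanShapeModel:
    mean_surface: trimesh.Trimesh
    mean_landmarks: LandmarkSet
    correspondences: dict[str, CorrespondenceMap]
    transforms: dict[str, RigidTransform]
    template_case: str = ""


def densify_landmarks(
    primary: LandmarkSet,
    surface: trimesh.Trimesh,
    lines: list[tuple[str, str]],
    n_secondary: int = 5,
) -> LandmarkSet:
    """Add secondary landmarks along geodesic connecting lines.

    For each named pair, the on-surface geodesic (graph shortest path
    between the nearest mesh vertices) is computed and ``n_secondary``
    points are placed at equal arc-length fractions, excluding the
    endpoints.  Line ids are ``"name_a:name_b"``, appended in input
    order; the result is deterministic.
    """
    if n_secondary < 0:
        raise ValueError("n_secondary must be >= 0")
    if n_secondary == 0 or not lines:
        return replace(primary, secondary=dict(primary.secondary))
    tree = cKDTree(surface.vertices)
    graph = _geometry.edge_graph(surface)
    secondary = dict(primary.secondary)
    for a, b in lines:
        if a not in primary.primary or b not in primary.primary:
            raise KeyError(f"connecting line ({a}, {b}) names unknown landmarks")
        va = int(tree.query(primary.primary[a])[1])
        vb = int(tree.query(primary.primary[b])[1])
        path, _ = _geometry.shortest_path(graph, va, vb)
        pts = surface.vertices.view(np.ndarray)[path]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        fracs = np.arange(1, n_secondary + 1) / (n_secondary + 1)
        samples = np.empty((n_secondary, 3))
        for d in range(3):
            samples[:, d] = np.interp(fracs * total, s, pts[:, d])
        secondary[f"{a}:{b}"] = samples
    return replace(primary, secondary=secondary)


def generalized_procrustes(
    configs: list[LandmarkSet],
    with_scaling: bool = True,
    tol: float | None = None,
    max_iterations: int = 100,
) -> tuple[list[np.ndarray], np.ndarray, list[RigidTransform]]:
    """Generalized Procrustes alignment of landmark configurations.

    Iteratively aligns every configuration to the running mean by
    least-squares similarity (or rigid, if ``with_scaling`` is False)
    and re-estimates the mean until its change drops below ``tol``
    (default 1e-6 x mean centroid size).  The mean is centered at the
    origin.  Returns (aligned stacked configs, mean configuration,
    per-case transforms).
    """
    if len(configs) < 2:
        raise ValueError("at least 2 configurations are required")
    ref = configs[0]
    for c in configs[1:]:
        if not ref.compatible_with(c):
            raise ValueError(f"landmark sets incompatible: {c.case_id!r}")
    X = [c.stacked() for c in configs]
    n_lm = X[0].shape[0]
    if n_lm < 3:
        raise ValueError("need at least 3 landmarks")
    if np.linalg.matrix_rank(X[0] - X[0].mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) landmark configuration")

    centroid_size = float(np.linalg.norm(X[0] - X[0].mean(axis=0)))
    if tol is None:
        tol = 1e-6 * centroid_size

    mean = X[0] - X[0].mean(axis=0)
    if with_scaling:
        mean = mean / np.linalg.norm(mean)
    aligned = [x.copy() for x in X]
    transforms = [RigidTransform.identity() for _ in X]
    for _ in range(max_iterations):
        for i, x in enumerate(X):
            R, t, s = _geometry.kabsch(x, mean, with_scaling=with_scaling)
            transforms[i] = RigidTransform(rotation=R, translation=t, scale=s)
            aligned[i] = transforms[i].apply(x)
        new_mean = np.mean(aligned, axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        if with_scaling:
            norm = np.linalg.norm(new_mean)
            if norm > 0:
                new_mean = new_mean / norm
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    if with_scaling:
        # the iteration works at unit centroid size; restore the cohort's
        # average physical size into the mean, transforms and aligned configs
        target = float(np.mean([np.linalg.norm(x - x.mean(axis=0)) for x in X]))
        mean = mean * target
        transforms = [
            RigidTransform(rotation=t.rotation, translation=t.translation * target,
                           scale=t.scale * target)
            for t in transforms
        ]
        aligned = [a * target for a in aligned]
    return aligned, mean, transforms


def _tps_warp(
    source_landmarks: np.ndarray, target_landmarks: np.ndarray
) -> RBFInterpolator:
    """Smooth interpolating deformation taking source landmarks to targets."""
    return RBFInterpolator(
        source_landmarks, target_landmarks, kernel="thin_plate_spline", degree=1
    )


def correspond_surface(
    template: trimesh.Trimesh,
    template_landmarks: np.ndarray,
    case_surface: trimesh.Trimesh,
    case_landmarks: np.ndarray,
    max_match_fraction: float = 0.05,
    max_match_distance: float | None = None,
) -> tuple[np.ndarray, CorrespondenceMap]:
    """Warp template vertices onto a case surface; return matched points.

    Landmark-driven thin-plate-spline deformation followed by exact
    closest-point refinement.  Matches farther than
    ``max_match_distance`` (default 10x the case's mean edge length) are
    flagged; an error is raised if more than ``max_match_fraction`` of
    vertices fail.
    """
    warp = _tps_warp(template_landmarks, case_landmarks)
    warped = warp(template.vertices.view(np.ndarray))
    dist = _geometry.MeshDistance(case_surface)
    matched, d, tri = dist.query(warped)
    if max_match_distance is None:
        max_match_distance = 10.0 * float(case_surface.edges_unique_length.mean())
    bad = d > max_match_distance
    if bad.mean() > max_match_fraction:
        raise ValueError(
            f"correspondence failure: {bad.mean():.1%} of vertices matched "
            f"farther than {max_match_distance:.2f} mm"
        )
    bary = dist.barycentric(matched, tri)
    return matched, CorrespondenceMap(triangle_ids=tri, barycentric=bary)


def build_mean_shape(
    cohort: list[tuple[trimesh.Trimesh, LandmarkSet]],
    with_scaling: bool = True,
    lines: list[tuple[str, str]] | None = None,
    n_secondary: int = 5,
) -> MeanShapeModel:
    """Build the cohort mean surface with dense per-case correspondence.

    All cases must already be left-sided (mirror right bones upstream).
    Landmarks are densified per case, aligned by generalized Procrustes;
    the case closest to the mean configuration serves as topology
    template and is warped onto every case; the mean surface averages
    the corresponded positions in the aligned frame.
    """
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least 2 cases")
    lines = lines or []
    dense = [
        densify_landmarks(lm, surf, lines, n_secondary) for surf, lm in cohort
    ]
    for i, d in enumerate(dense):
        if not d.case_id:
            dense[i] = replace(d, case_id=f"case{i:03d}")
    aligned, mean_config, transforms = generalized_procrustes(
        dense, with_scaling=with_scaling
    )
    dists = [np.linalg.norm(a - mean_config) for a in aligned]
    t_idx = int(np.argmin(dists))
    template_surf, _ = cohort[t_idx]
    template_aligned = trimesh.Trimesh(
        vertices=transforms[t_idx].apply(template_surf.vertices.view(np.ndarray)),
        faces=template_surf.faces,
        process=False,
    )
    template_lm = aligned[t_idx]

    accum = np.zeros_like(template_aligned.vertices.view(np.ndarray))
    correspondences: dict[str, CorrespondenceMap] = {}
    for i, (surf, _) in enumerate(cohort):
        case_aligned = trimesh.Trimesh(
            vertices=transforms[i].apply(surf.vertices.view(np.ndarray)),
            faces=surf.faces,
            process=False,
        )
        matched, corr = correspond_surface(
            template_aligned, template_lm, case_aligned, aligned[i]
        )
        corr.case_id = dense[i].case_id
        correspondences[dense[i].case_id] = corr
        accum += matched
    mean_vertices = accum / len(cohort)
    mean_surface = trimesh.Trimesh(
        vertices=mean_vertices, faces=template_aligned.faces, process=False
    )

    names = sorted(dense[0].primary)
    secondary: dict[str, np.ndarray] = {}
    offset = len(names)
    for k in sorted(dense[0].secondary):
        m = len(dense[0].secondary[k])
        secondary[k] = mean_config[offset : offset + m]
        offset += m
    mean_landmarks = LandmarkSet(
        primary={k: mean_config[j] for j, k in enumerate(names)},
        secondary=secondary,
        case_id="mean",
        side="left",
    )
    return MeanShapeModel(
        mean_surface=mean_surface,
        mean_landmarks=mean_landmarks,
        correspondences={
            dense[i].case_id: correspondences[dense[i].case_id]
            for i in range(len(cohort))
        },
        transforms={dense[i].case_id: transforms[i] for i in range(len(cohort))},
        template_case=dense[t_idx].case_id,
    )


def correspond_case(
    model: MeanShapeModel,
    surface: trimesh.Trimesh,
    landmarks: LandmarkSet,
    lines: list[tuple[str, str]] | None = None,
    n_secondary: int | None = None,
) -> tuple[CorrespondenceMap, RigidTransform]:
    """Map the mean surface onto a new case via landmark homology.

    The case is aligned to the mean landmark configuration by similarity
    Procrustes, then each mean vertex is carried over by the
    thin-plate-spline deformation + closest-point refinement.  Returns
    the correspondence map together with the case-to-mean transform.
    """
    if sorted(landmarks.primary) != sorted(model.mean_landmarks.primary):
        raise ValueError("landmark names incompatible with the model")
    if n_secondary is None:
        ref = model.mean_landmarks.secondary
        counts = {len(v) for v in ref.values()}
        n_secondary = counts.pop() if len(counts) == 1 else 0
    if lines is None:
        lines = [tuple(k.split(":")) for k in sorted(model.mean_landmarks.secondary)]
    dense = densify_landmarks(landmarks, surface, lines, n_secondary)
    x = dense.stacked()
    mean_x = model.mean_landmarks.stacked()
    R, t, s = _geometry.kabsch(x, mean_x, with_scaling=True)
    transform = RigidTransform(rotation=R, translation=t, scale=s)
    case_aligned = trimesh.Trimesh(
        vertices=transform.apply(surface.vertices.view(np.ndarray)),
        faces=surface.faces,
        process=False,
    )
    _, corr = correspond_surface(
        model.mean_surface, mean_x, case_aligned, transform.apply(x)
    )
    corr.case_id = landmarks.case_id
    return corr, transform
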
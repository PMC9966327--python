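"""Virtual fracture reduction against the mirrored contralateral template.

Fragments are rigidly registered to the intact template surface by
iterative closest point (point-to-plane), replacing the manual puzzle
solving a surgeon would perform; externally supplied transforms (e.g.
from a manual reduction) are accepted through the same interface.
Reduced fragments' fracture lines are projected onto the template by
exact closest-point matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from ._geometry import MeshDistance, reflect_points
from .core import FractureLine, RigidTransform


def mirror_mesh(
    mesh: trimesh.Trimesh, plane_point, plane_normal
) -> trimesh.Trimesh:
    """Reflect a mesh across a plane, keeping outward normals outward.

    Triangle winding is reversed so the signed volume is preserved
    rather than negated.
    """
    verts = reflect_points(mesh.vertices.view(np.ndarray), plane_point, plane_normal)
    faces = mesh.faces[:, ::-1]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def _solve_point_to_plane(
    src: np.ndarray, tgt: np.ndarray, normals: np.ndarray
) -> RigidTransform:
    """Small-angle point-to-plane least squares step (linearized twist)."""
    c = np.cross(src, normals)
    A = np.hstack([c, normals])  # (n, 6): rotation then translation
    b = ((tgt - src) * normals).sum(axis=1)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    w, t = x[:3], x[3:]
    angle = np.linalg.norm(w)
    if angle < 1e-12:
        R = np.eye(3)
    else:
        k = w / angle
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
    return RigidTransform(rotation=R, translation=t)


def _scale_step(step: RigidTransform, factor: float) -> RigidTransform:
    """Shrink a rigid step toward identity (rotation via axis-angle)."""
    R = step.rotation
    c = (np.trace(R) - 1) / 2
    angle = np.arccos(np.clip(c, -1, 1))
    if angle < 1e-12:
        Rs = np.eye(3)
    else:
        axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        axis = axis / np.linalg.norm(axis)
        a = angle * factor
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        Rs = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K
    return RigidTransform(rotation=Rs, translation=step.translation * factor)


@dataclass
class ICPResult:
    transform: RigidTransform
    residual: float
    converged: bool
    residual_history: list[float] = field(default_factory=list)

    def __iter__(self):
        return iter((self.transform, self.residual, self.converged))


def reduce_fragment(
    fragment: trimesh.Trimesh,
    template: trimesh.Trimesh,
    init: RigidTransform | None = None,
    max_iterations: int = 200,
    tol: float = 1e-4,
    sample: int = 2500,
    seed: int = 0,
    vertex_mask: np.ndarray | None = None,
    trim: float = 2.5,
) -> ICPResult:
    """Rigidly register a fragment onto the template surface (ICP).

    Point-to-plane steps with step-halving backtracking, so the RMS
    closest-point residual is non-increasing across iterations.
    ``vertex_mask`` restricts registration to a vertex subset (e.g. the
    outer cortical surface, excluding cut faces and the medullary
    wall).  Correspondences farther than ``trim`` x the median distance
    are down-weighted out of each step (robustness against non-matching
    regions).  Convergence: residual change below ``tol`` (mm) between
    iterations; non-convergence is reported via the flag, never as an
    exception.
    """
    if len(fragment.vertices) == 0 or len(template.vertices) == 0:
        raise ValueError("fragment and template must be non-empty")
    init = init or RigidTransform.identity()
    dist = MeshDistance(template)
    pts_all = fragment.vertices.view(np.ndarray)
    if vertex_mask is not None:
        pts_all = pts_all[np.asarray(vertex_mask, bool)]
    if len(pts_all) > sample:
        rng = np.random.default_rng(seed)
        pts_all = pts_all[rng.choice(len(pts_all), sample, replace=False)]
    face_normals = template.face_normals.view(np.ndarray)

    current = init

    def rms(transform: RigidTransform) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
        moved = transform.apply(pts_all)
        closest, d, tri = dist.query(moved)
        return float(np.sqrt((d**2).mean())), closest, face_normals[tri], d

    residual, closest, normals, dists = rms(current)
    history = [residual]
    converged = False
    for _ in range(max_iterations):
        moved = current.apply(pts_all)
        cutoff = max(trim * float(np.median(dists)), 1e-6) if trim else np.inf
        use = dists <= cutoff
        if use.sum() < 6:
            use = np.ones_like(use)
        step = _solve_point_to_plane(moved[use], closest[use], normals[use])
        candidate = step.compose(current)
        new_res, new_closest, new_normals, new_d = rms(candidate)
        shrink = 0
        while new_res > residual and shrink < 8:
            step = _scale_step(step, 0.5)
            candidate = step.compose(current)
            new_res, new_closest, new_normals, new_d = rms(candidate)
            shrink += 1
        if new_res > residual:
            converged = True  # cannot improve further
            break
        improvement = residual - new_res
        current, residual = candidate, new_res
        closest, normals, dists = new_closest, new_normals, new_d
        history.append(residual)
        if improvement < tol:
            converged = True
            break
    return ICPResult(transform=current, residual=residual, converged=converged,
                     residual_history=history)


def principal_axis_init(
    fragment: trimesh.Trimesh, template: trimesh.Trimesh
) -> RigidTransform:
    """Coarse initialization: align centroids (identity rotation).

    Fragment principal axes are unreliable for partial shells, so only
    the translation is initialized; rotation search is left to ICP.
    """
    t = template.vertices.mean(axis=0) - fragment.vertices.mean(axis=0)
    return RigidTransform(translation=t)


def project_line_to_surface(
    line: FractureLine, surface: trimesh.Trimesh
) -> FractureLine:
    """Replace each line point by its exact closest point on the surface."""
    proj, _, _ = MeshDistance(surface).query(line.points)
    keep = np.concatenate([[True], np.any(np.diff(proj, axis=0) != 0, axis=1)])
    return FractureLine(points=proj[keep], closed=line.closed, fragment=line.fragment)


def save_transforms(path: str | Path, transforms: dict[int, RigidTransform]) -> None:
    """Write per-fragment transforms as JSON 4x4 row-major matrices."""
    payload = [
        {"fragment": int(fid), "matrix": t.matrix.tolist()}
        for fid, t in sorted(transforms.items())
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_transforms(path: str | Path) -> dict[int, RigidTransform]:
    """Read per-fragment transforms, validating the rigid invariants."""
    payload = json.loads(Path(path).read_text())
    out: dict[int, RigidTransform] = {}
    for entry in payload:
        m = np.asarray(entry["matrix"], dtype=float)
        A = m[:3, :3]
        det = np.linalg.det(A)
        if det <= 0:
            raise ValueError(
                f"fragment {entry['fragment']}: rotation determinant {det:.3g} "
                "is not positive (improper rotation rejected)"
            )
        out[int(entry["fragment"])] = RigidTransform.from_matrix(m)
    return out
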
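"""End-to-end orchestration: per-case processing and the cohort study.

Per case: segment the fractured volume, mesh the fragments, trace
fracture lines, reduce the fragments onto the intact template (the
mirrored contralateral in a clinical setting; the intact twin for
phantoms), and project the lines onto the template.  Cohort level:
mirror right-sided templates to the left, build the mean shape, map
every case's lines and fragment areas, and accumulate the two
probability maps.

Every stage writes its artifacts to documented file formats when an
output directory is given; completed stages are skipped on re-runs
unless forced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh
from pydantic import BaseModel, ConfigDict

from . import io
from ._geometry import reflect_points
from .core import FractureLine, LabelMap, LandmarkSet, RigidTransform, VolumeImage
from .fracture_lines import (
    mesh_fragment,
    outer_vertex_mask,
    propose_guide_markers,
    trace_fracture_line,
    vertex_curvature,
)
from .mapping import (
    IncidenceVector,
    ProbabilityMap,
    accumulate_probability,
    combine_case_incidence,
    default_kernel_radius,
    map_fragment_incidence,
    map_line_incidence,
)
from .reduction import (
    mirror_mesh,
    principal_axis_init,
    project_line_to_surface,
    reduce_fragment,
)
from .segmentation import SeedMarkers, adaptive_threshold, label_components, split_fragment
from .ssm import MeanShapeModel, build_mean_shape

log = logging.getLogger("fracmap")


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window_radius: int = 8
    min_contrast: float = 100.0
    connectivity: int = 26
    min_voxels: int = 27


class LineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    quantile: float = 0.90
    floor: float = 0.25
    w_boundary: float = 1.0
    w_angle: float = 1.0
    min_markers: int = 2
    close_gap: float = 4.0       # mm, geodesic gap below which loops close
    close_fraction: float = 0.2  # ... or this fraction of the path length
    smooth_sigma: float = 1.0  # voxels, indicator smoothing before meshing
    outer_only: bool = True    # keep lines on the outer cortical surface
    convex_only: bool = True   # fracture rims are convex creases
    valley_refine: bool = True  # re-center on the radiolucent cleft
    border_dist: float = 3.0   # mm; fracture borders face another fragment


class ReductionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_iterations: int = 200
    tol: float = 1e-4
    sample: int = 2500


class SsmConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    with_scaling: bool = True
    n_secondary: int = 5
    connecting_lines: list[tuple[str, str]] = [
        ("head_apex", "greater_tuberosity"),
        ("head_apex", "lesser_tuberosity"),
        ("greater_tuberosity", "shaft_lateral"),
        ("lesser_tuberosity", "shaft_anterior"),
        ("head_medial", "shaft_medial"),
        ("neck_posterior", "shaft_posterior"),
    ]


class MappingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    line_radius: Optional[float] = None  # default: 1.5x mean edge length
    fragment_max_dist: float = 1.0


class StudyConfig(BaseModel):
    """All pipeline parameters; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    segmentation: SegmentationConfig = SegmentationConfig()
    lines: LineConfig = LineConfig()
    reduction: ReductionConfig = ReductionConfig()
    ssm: SsmConfig = SsmConfig()
    mapping: MappingConfig = MappingConfig()
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.model_validate(io.read_yaml(path) or {})


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and case id."""

    def __init__(self, stage: str, case_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for case {case_id!r}: {cause}")
        self.stage = stage
        self.case_id = case_id
        self.__cause__ = cause


@dataclass
class CaseInputs:
    """Everything one case needs: the fractured volume, seed markers for
    fragments that are not fully detached, the intact template surface in
    the fractured bone's frame, and the template's landmarks."""

    case_id: str
    fractured: VolumeImage
    template: trimesh.Trimesh
    template_landmarks: LandmarkSet
    side: str = "left"
    markers: SeedMarkers | None = None
    transforms: dict[int, RigidTransform] | None = None  # externally supplied


@dataclass
class CaseRecord:
    case_id: str
    side: str
    labels: LabelMap | None = None
    fragment_meshes: dict[int, trimesh.Trimesh] = field(default_factory=dict)
    fracture_lines: dict[int, FractureLine] = field(default_factory=dict)
    transforms: dict[int, RigidTransform] = field(default_factory=dict)
    residuals: dict[int, float] = field(default_factory=dict)
    projected_lines: dict[int, FractureLine] = field(default_factory=dict)
    template: trimesh.Trimesh | None = None
    template_landmarks: LandmarkSet | None = None


def _segment_stage(config: StudyConfig, case: CaseInputs) -> LabelMap:
    c = config.segmentation
    mask = adaptive_threshold(case.fractured, c.window_radius, c.min_contrast)
    labels = label_components(mask, connectivity=c.connectivity, min_voxels=c.min_voxels)
    labels = np.asarray(labels)
    if case.markers is not None:
        by_component: dict[int, list[tuple[int, tuple[int, int, int]]]] = {}
        for g, idx in case.markers.markers:
            comp = int(labels[idx])
            if comp == 0:
                raise ValueError(f"marker {idx} lies outside the segmented mask")
            by_component.setdefault(comp, []).append((g, idx))
        next_id = int(labels.max())
        out = labels.copy()
        for comp, marks in sorted(by_component.items()):
            if len({g for g, _ in marks}) < 2:
                continue
            sub_markers = SeedMarkers(markers=marks)
            sub_labels, _removed = split_fragment(
                case.fractured, labels == comp, sub_markers, c.connectivity
            )
            out[labels == comp] = 0
            for g in sorted({g for g, _ in marks}):
                next_id += 1
                out[sub_labels.labels == g] = next_id
        # renumber 1..K by descending size, C-order seed tie-break
        ids = [i for i in np.unique(out) if i > 0]
        counts = {i: int((out == i).sum()) for i in ids}
        flat = out.ravel()
        first = {i: int(np.flatnonzero(flat == i)[0]) for i in ids}
        remap = np.zeros(max(ids) + 1, dtype=np.int32)
        for new, old in enumerate(
            sorted(ids, key=lambda i: (-counts[i], first[i])), start=1
        ):
            remap[old] = new
        labels = remap[out]
        log.info("case %s: split produced %d fragments", case.case_id, int(labels.max()))
    return LabelMap.like(case.fractured, labels.astype(np.int32))


def _lines_stage(
    config: StudyConfig, record: CaseRecord, volume: VolumeImage | None = None
) -> tuple[dict[int, trimesh.Trimesh], dict[int, FractureLine]]:
    from ._geometry import MeshDistance
    from .fracture_lines import (
        bone_outer_surface,
        refine_line_to_cleft,
        refine_line_to_valley,
        smooth_polyline,
    )

    c = config.lines
    lines: dict[int, FractureLine] = {}
    assert record.labels is not None
    full_mask = record.labels.labels > 0
    ids = record.labels.ids
    meshes: dict[int, trimesh.Trimesh] = {
        fid: mesh_fragment(record.labels, fid, smooth_sigma=c.smooth_sigma)
        for fid in ids
    }
    sealed: trimesh.Trimesh | None = None
    for fid in ids:
        mesh = meshes[fid]
        signed = vertex_curvature(mesh, signed=True)
        curvature = np.abs(signed)
        markers = propose_guide_markers(mesh, curvature, c.quantile, c.floor)
        ridge = np.flatnonzero(
            curvature > max(np.quantile(curvature, c.quantile), c.floor)
        )
        if c.convex_only:
            markers = [m for m in markers if signed[m] > 0]
            ridge = ridge[signed[ridge] > 0]
        if c.outer_only:
            outer = outer_vertex_mask(mesh, full_mask, record.labels.spacing,
                                      record.labels.origin)
            markers = [m for m in markers if outer[m]]
            ridge = ridge[outer[ridge]]
        opposing = None
        if c.border_dist > 0 and len(ids) > 1:
            # a fracture border faces another fragment across the cleft
            opposing = trimesh.util.concatenate(
                [meshes[other] for other in ids if other != fid]
            )
            dist = MeshDistance(opposing)
            if markers:
                _, dm, _ = dist.query(mesh.vertices.view(np.ndarray)[markers])
                markers = [m for m, d in zip(markers, dm) if d <= c.border_dist]
            if len(ridge):
                _, dr, _ = dist.query(mesh.vertices.view(np.ndarray)[ridge])
                ridge = ridge[dr <= c.border_dist]
        if len(markers) < c.min_markers:
            log.warning("case %s fragment %d: %d guide markers, no line traced",
                        record.case_id, fid, len(markers))
            continue
        line = trace_fracture_line(
            mesh, markers, weights=(c.w_boundary, c.w_angle), ridge_vertices=ridge,
            close_gap=c.close_gap, close_fraction=c.close_fraction,
        )
        line.fragment = fid
        if opposing is not None:
            line = refine_line_to_cleft(line, opposing, max_gap=c.border_dist)
        if c.valley_refine and volume is not None:
            if sealed is None:
                sealed = bone_outer_surface(record.labels, c.smooth_sigma)
            # uniform resampling first: stable tangents for the
            # binormal valley search
            step = max(record.labels.spacing)
            line = FractureLine(points=line.resample(step), closed=line.closed,
                                fragment=fid)
            line = smooth_polyline(line, iterations=4)
            for _ in range(2):
                line = refine_line_to_valley(line, sealed, volume)
                line = smooth_polyline(line)
            # the border trace and smoothing leave points slightly below
            # the cortex: restore them onto the outer surface
            line = project_line_to_surface(line, sealed)
        lines[fid] = line
    return meshes, lines


def run_case(
    config: StudyConfig,
    case: CaseInputs,
    out_dir: str | Path | None = None,
    force: bool = False,
) -> CaseRecord:
    """Process one case: segment → mesh → trace → reduce → project.

    With ``out_dir`` every stage artifact is persisted; re-runs load
    completed stage outputs instead of recomputing unless ``force``.
    """
    record = CaseRecord(case_id=case.case_id, side=case.side,
                        template=case.template,
                        template_landmarks=case.template_landmarks)
    if case.template is None:
        raise StageError("reduction", case.case_id,
                         ValueError("missing contralateral template surface"))
    base = Path(out_dir) / case.case_id if out_dir is not None else None
    if base is not None:
        base.mkdir(parents=True, exist_ok=True)

    # segmentation
    labels_path = base / "labels.nii.gz" if base else None
    try:
        if labels_path is not None and labels_path.exists() and not force:
            record.labels = io.read_labels(labels_path)
        else:
            record.labels = _segment_stage(config, case)
            if labels_path is not None:
                io.write_volume(record.labels, labels_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("segmentation", case.case_id, e) from e

    # meshing + fracture lines
    try:
        record.fragment_meshes, record.fracture_lines = _lines_stage(
            config, record, volume=case.fractured
        )
        if base is not None:
            for fid, m in record.fragment_meshes.items():
                io.write_mesh(m, base / f"fragment_{fid:02d}.ply")
            for fid, ln in record.fracture_lines.items():
                io.write_line(ln, base / f"line_{fid:02d}.json")
    except Exception as e:  # noqa: BLE001
        raise StageError("fracture_lines", case.case_id, e) from e

    # reduction: multi-start ICP (in-place and centroid-aligned inits),
    # restricted to outer-cortex vertices
    try:
        from .fracture_lines import outer_vertex_mask

        r = config.reduction
        full_mask = record.labels.labels > 0
        for fid, mesh in record.fragment_meshes.items():
            if case.transforms is not None and fid in case.transforms:
                record.transforms[fid] = case.transforms[fid]
                record.residuals[fid] = float("nan")
                continue
            outer = outer_vertex_mask(mesh, full_mask, record.labels.spacing,
                                      record.labels.origin)
            if outer.sum() < 10:
                outer = None
            candidates = [
                reduce_fragment(
                    mesh, case.template, init=init,
                    max_iterations=r.max_iterations, tol=r.tol, sample=r.sample,
                    seed=config.seed, vertex_mask=outer,
                )
                for init in (None, principal_axis_init(mesh, case.template))
            ]
            result = min(candidates, key=lambda c: c.residual)
            record.transforms[fid] = result.transform
            record.residuals[fid] = result.residual
            if not result.converged:
                log.warning("case %s fragment %d: ICP did not converge "
                            "(residual %.3f mm)", case.case_id, fid, result.residual)
    except Exception as e:  # noqa: BLE001
        raise StageError("reduction", case.case_id, e) from e

    # line projection onto the template
    try:
        for fid, line in record.fracture_lines.items():
            t = record.transforms[fid]
            reduced = FractureLine(points=t.apply(line.points), closed=line.closed,
                                   fragment=fid)
            record.projected_lines[fid] = project_line_to_surface(reduced, case.template)
        if base is not None:
            for fid, ln in record.projected_lines.items():
                io.write_line(ln, base / f"projected_line_{fid:02d}.json")
            from .reduction import save_transforms

            save_transforms(base / "transforms.json", record.transforms)
    except Exception as e:  # noqa: BLE001
        raise StageError("projection", case.case_id, e) from e
    return record


@dataclass
class StudyResult:
    model: MeanShapeModel
    fracture_map: ProbabilityMap
    fragment_map: ProbabilityMap


def _mirror_record_to_left(record: CaseRecord) -> CaseRecord:
    """Mirror a right-sided case (template, lines, fragments) to the left."""
    assert record.template is not None and record.template_landmarks is not None
    bounds = record.template.bounds
    point = bounds.mean(axis=0)
    normal = np.array([1.0, 0.0, 0.0])
    out = CaseRecord(case_id=record.case_id, side="left")
    out.labels = record.labels
    out.template = mirror_mesh(record.template, point, normal)
    out.template_landmarks = record.template_landmarks.mirrored(point, normal)
    out.fragment_meshes = {
        fid: mirror_mesh(m, point, normal) for fid, m in record.fragment_meshes.items()
    }
    for fid, ln in record.projected_lines.items():
        out.projected_lines[fid] = FractureLine(
            points=reflect_points(ln.points, point, normal), closed=ln.closed,
            fragment=fid,
        )
    # reduced fragment positions are re-expressed by mirroring the moved mesh
    for fid, t in record.transforms.items():
        moved = t.apply(record.fragment_meshes[fid].vertices.view(np.ndarray))
        out.fragment_meshes[fid] = trimesh.Trimesh(
            vertices=reflect_points(moved, point, normal),
            faces=record.fragment_meshes[fid].faces[:, ::-1],
            process=False,
        )
        out.transforms[fid] = RigidTransform.identity()
    return out


def run_study(
    config: StudyConfig,
    cases: list[CaseRecord],
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Cohort analysis: mean shape + fracture and fragment probability maps."""
    if len(cases) < 2:
        raise ValueError("at least 2 completed cases are required")
    prepared = [
        _mirror_record_to_left(c) if c.side == "right" else c for c in cases
    ]
    bad = [c.case_id for c in prepared
           if c.template is None or c.template_landmarks is None]
    if bad:
        raise ValueError(f"cases missing template/landmarks: {bad}")
    ref = prepared[0].template_landmarks
    incompatible = [
        c.case_id for c in prepared[1:]
        if not ref.compatible_with(c.template_landmarks)  # type: ignore[arg-type]
    ]
    if incompatible:
        raise ValueError(f"incompatible landmark sets for cases: {incompatible}")

    cohort = [(c.template, c.template_landmarks) for c in prepared]
    for c in prepared:
        if not c.template_landmarks.case_id:  # type: ignore[union-attr]
            c.template_landmarks.case_id = c.case_id  # type: ignore[union-attr]
    model = build_mean_shape(
        cohort,  # type: ignore[arg-type]
        with_scaling=config.ssm.with_scaling,
        lines=config.ssm.connecting_lines,
        n_secondary=config.ssm.n_secondary,
    )

    radius = config.mapping.line_radius
    if radius is None:
        radius = default_kernel_radius(model.mean_surface)

    line_vectors: list[IncidenceVector] = []
    frag_vectors: list[IncidenceVector] = []
    for c in prepared:
        cid = c.template_landmarks.case_id  # type: ignore[union-attr]
        corr = model.correspondences[cid]
        align = model.transforms[cid]
        case_aligned = trimesh.Trimesh(
            vertices=align.apply(c.template.vertices.view(np.ndarray)),  # type: ignore[union-attr]
            faces=c.template.faces,  # type: ignore[union-attr]
            process=False,
        )
        aligned_lines = [
            FractureLine(points=align.apply(ln.points), closed=ln.closed,
                         fragment=ln.fragment)
            for ln in c.projected_lines.values()
        ]
        lv = map_line_incidence(corr, case_aligned, aligned_lines,
                                model.mean_surface, radius=radius)
        lv.case_id = cid
        line_vectors.append(lv)

        per_frag = []
        for fid, mesh in c.fragment_meshes.items():
            t = c.transforms.get(fid, RigidTransform.identity())
            aligned_frag = trimesh.Trimesh(
                vertices=align.apply(t.apply(mesh.vertices.view(np.ndarray))),
                faces=mesh.faces,
                process=False,
            )
            per_frag.append(
                map_fragment_incidence(
                    corr, case_aligned, aligned_frag,
                    max_dist=config.mapping.fragment_max_dist * align.scale,
                )
            )
        if per_frag:
            fv = combine_case_incidence(per_frag)
            fv.case_id = cid
            frag_vectors.append(fv)

    fracture_map = accumulate_probability(line_vectors)
    fragment_map = accumulate_probability(frag_vectors)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_mesh(model.mean_surface, out / "mean_surface.ply")
        io.write_probability_map(fracture_map, model.mean_surface,
                                 out / "fracture_probability")
        io.write_probability_map(fragment_map, model.mean_surface,
                                 out / "fragment_probability")
        render_four_views(model.mean_surface, fracture_map.counts,
                          out / "fracture_probability.png",
                          title="Fracture-line probability (cases)")
        render_four_views(model.mean_surface, fragment_map.counts,
                          out / "fragment_probability.png",
                          title="Fragment probability (cases)")
    return StudyResult(model=model, fracture_map=fracture_map,
                       fragment_map=fragment_map)


def render_four_views(
    mesh: trimesh.Trimesh, scalars: np.ndarray, path: str | Path, title: str = ""
) -> None:
    """Anterior/lateral/posterior/medial snapshots of a per-vertex map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    views = [("anterior", 90), ("lateral", 0), ("posterior", 270), ("medial", 180)]
    fig = plt.figure(figsize=(14, 4))
    v = mesh.vertices.view(np.ndarray)
    for i, (name, azim) in enumerate(views, start=1):
        ax = fig.add_subplot(1, 4, i, projection="3d")
        p = ax.scatter(v[:, 0], v[:, 1], v[:, 2], c=scalars, s=2, cmap="turbo")
        ax.view_init(elev=0, azim=azim)
        ax.set_title(name)
        ax.set_axis_off()
        ax.set_box_aspect((np.ptp(v[:, 0]), np.ptp(v[:, 1]), np.ptp(v[:, 2])))
    fig.colorbar(p, ax=fig.axes, shrink=0.6, label="cases")
    if title:
        fig.suptitle(title)
    fig.savefig(path, dpi=110)
    plt.close(fig)
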
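"""Phantom-driven study helpers: ready-made fracture specs, markers and
cohort runs that exercise the full pipeline with known ground truth."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import LabelMap, RigidTransform, VolumeImage
from .phantom import (
    FractureSpec,
    GridSpec,
    GroundTruth,
    PlanarCut,
    ShapeParams,
    apply_fracture,
    sample_cohort,
)
from .pipeline import (
    CaseInputs,
    CaseRecord,
    StudyConfig,
    StudyResult,
    run_case,
    run_study,
)
from .segmentation import SeedMarkers


def default_fracture_spec(
    truth: GroundTruth,
    displace_deg: float = 0.0,
    displace_mm: float = 0.0,
    comminution_radius: float = 1.5,
    noise_sd: float = 0.0,
    blur_fwhm: float = 0.0,
    seed: int = 0,
) -> FractureSpec:
    """A 3-part surgical-neck-style fracture derived from the case geometry.

    One transverse cut below the head (the surgical neck corridor) and
    one oblique cut shearing off the greater-tuberosity bump, plus an
    optional comminution sphere at the anterior neck — the displacement
    and bone-loss pattern the cohort statistics are built around.
    """
    if truth.frame_origin is None or truth.params is None:
        raise ValueError("ground truth lacks phantom frame information")
    p = truth.params
    fo = np.asarray(truth.frame_origin, dtype=float)
    m = -1.0 if truth.landmarks.side == "right" else 1.0

    def mx(v: np.ndarray) -> tuple[float, float, float]:
        return (m * v[0], v[1], v[2])

    neck_point = fo + np.array([0.0, 0.0, -0.75 * p.head_radius])
    neck_normal = np.array([0.15, 0.10, 1.0])
    tub_dir = np.asarray(p.tuberosity_offsets[0][0], dtype=float)
    tub_point = fo + np.array(mx(tub_dir * 0.60 * p.head_radius))
    cuts = [
        PlanarCut(point=tuple(neck_point), normal=mx(neck_normal)),
        PlanarCut(point=tuple(tub_point), normal=mx(tub_dir)),
    ]
    zones = []
    if comminution_radius > 0:
        # anterior surface point at the neck level
        z = -0.75 * p.head_radius
        r_surf = np.sqrt(max(p.head_radius**2 - z**2, p.shaft_radius**2))
        center = fo + np.array([0.0, r_surf, z])
        zones.append((tuple(center), float(comminution_radius)))

    displacements: dict[int, RigidTransform] = {}
    if displace_deg > 0 or displace_mm > 0:
        rng = np.random.default_rng(seed)
        for fid in (2, 3):  # keep the largest fragment (shaft) fixed
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.radians(rng.uniform(0.25, 1.0) * displace_deg)
            K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
            t = rng.uniform(0.25, 1.0) * displace_mm * rng.normal(size=3)
            t = t / max(np.linalg.norm(t) / displace_mm, 1.0) if displace_mm else t * 0
            # rotate about the fragment's own region (near the head)
            pivot = fo
            displacements[fid] = RigidTransform(
                rotation=R, translation=pivot - R @ pivot + t
            )
    return FractureSpec(
        cut_surfaces=cuts,
        fragment_displacements=displacements,
        comminution_zones=zones,
        noise_sd=noise_sd,
        blur_fwhm=blur_fwhm,
        seed=seed,
    )


def markers_from_truth(truth: GroundTruth, max_depth: float = 3.0) -> SeedMarkers:
    """One seed voxel per ground-truth fragment, away from its boundary.

    Depth is capped at ``max_depth`` mm: adaptive thresholding only
    segments voxels with local contrast, so seeds deep inside large
    solid fragments would fall outside the mask.
    """
    assert truth.fragment_labels is not None
    markers = []
    for fid in truth.fragment_labels.ids:
        mask = truth.fragment_labels.labels == fid
        d = ndimage.distance_transform_edt(mask, sampling=truth.spacing)
        score = np.minimum(d, max_depth)
        # among maximal-score voxels take the first in C-order
        idx = np.unravel_index(int(np.argmax(score)), mask.shape)
        markers.append((fid, tuple(int(i) for i in idx)))
    return SeedMarkers(markers=markers)


@dataclass
class PhantomCase:
    inputs: CaseInputs
    truth: GroundTruth
    record: CaseRecord | None = None


@dataclass
class PhantomStudyResult(StudyResult):
    cases: list[PhantomCase] = None  # type: ignore[assignment]


def build_phantom_case(
    intact: tuple[VolumeImage, GroundTruth],
    spec: FractureSpec,
    case_id: str,
) -> PhantomCase:
    """Fracture an intact phantom and assemble the pipeline inputs.

    The intact twin of the same case serves as the contralateral
    template (already in the fractured bone's frame, so no mirroring is
    needed before reduction)."""
    _, intact_truth = intact
    fractured, truth = apply_fracture(intact, spec)
    landmarks = replace(intact_truth.landmarks, case_id=case_id)
    inputs = CaseInputs(
        case_id=case_id,
        fractured=fractured,
        template=intact_truth.outer_surface(),
        template_landmarks=landmarks,
        side=intact_truth.landmarks.side,
        markers=markers_from_truth(truth),
    )
    return PhantomCase(inputs=inputs, truth=truth)


def run_phantom_study(
    config: StudyConfig,
    n_cases: int = 10,
    right_fraction: float = 0.0,
    variation: dict[str, float] | None = None,
    identical: bool = True,
    displace_deg: float = 0.0,
    displace_mm: float = 0.0,
    comminution_radius: float = 1.5,
    noise_sd: float = 0.0,
    blur_fwhm: float = 0.0,
    grid: GridSpec | dict | None = None,
    base_shape: ShapeParams | dict | None = None,
    out_dir: str | None = None,
) -> PhantomStudyResult:
    """Generate a phantom cohort, fracture every case, run the pipeline.

    ``identical=True`` zeroes the shape variation so all cases share one
    geometry and fracture — the controlled setting in which the cohort
    probability maps have exactly known structure.
    """
    if isinstance(grid, dict):
        grid = GridSpec(**grid)
    if isinstance(base_shape, dict):
        base_shape = ShapeParams(**base_shape)
    if identical:
        variation = {k: 0.0 for k in ("head_radius", "shaft_radius", "shaft_length",
                                      "cortical_thickness", "tuberosity_amplitude")}
    cohort = sample_cohort(
        n_cases, base=base_shape, variation=variation,
        right_fraction=right_fraction, seed=config.seed, grid=grid,
    )
    cases: list[PhantomCase] = []
    records: list[CaseRecord] = []
    for i, intact in enumerate(cohort):
        spec = default_fracture_spec(
            intact[1], displace_deg=displace_deg, displace_mm=displace_mm,
            comminution_radius=comminution_radius, noise_sd=noise_sd,
            blur_fwhm=blur_fwhm, seed=config.seed + 1000 + i,
        )
        case = build_phantom_case(intact, spec, case_id=f"case{i:03d}")
        case.record = run_case(config, case.inputs, out_dir=out_dir)
        cases.append(case)
        records.append(case.record)
    result = run_study(config, records, out_dir=out_dir)
    return PhantomStudyResult(
        model=result.model,
        fracture_map=result.fracture_map,
        fragment_map=result.fragment_map,
        cases=cases,
    )
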
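"""Shared fixtures: phantoms and fractured cases are expensive, so the
ones reused across modules are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

import fracmap as fm
from fracmap.phantom import FractureSpec, PlanarCut, make_solid_phantom
from fracmap.pipeline import CaseInputs, StudyConfig, _segment_stage
from fracmap.studies import default_fracture_spec, markers_from_truth


@pytest.fixture(scope="session")
def intact_case():
    """Default humerus-like phantom, noise-free."""
    return fm.make_intact_phantom(fm.ShapeParams())


@pytest.fixture(scope="session")
def three_part_case(intact_case):
    """Default 3-part fracture (neck + tuberosity cuts, comminution)."""
    spec = default_fracture_spec(intact_case[1], seed=5)
    return fm.apply_fracture(intact_case, spec)


@pytest.fixture(scope="session")
def neck_cut_case(intact_case):
    """Single oblique planar neck cut, no comminution, no displacement."""
    fo = intact_case[1].frame_origin
    spec = FractureSpec(
        cut_surfaces=[
            PlanarCut(point=tuple(fo + [0, 0, -0.75 * 6.5]), normal=(0.15, 0.1, 1.0))
        ]
    )
    return fm.apply_fracture(intact_case, spec)


@pytest.fixture(scope="session")
def ball_cut_case():
    """Solid ball with one oblique planar cut — the cleanest rim geometry."""
    intact = make_solid_phantom("ball", 10.0)
    fo = intact[1].frame_origin
    spec = FractureSpec(
        cut_surfaces=[PlanarCut(point=tuple(fo + [0, 0, -2.0]), normal=(0.15, 0.1, 1.0))]
    )
    return fm.apply_fracture(intact, spec)


@pytest.fixture(scope="session")
def segmented_three_part(three_part_case):
    """Marker-split segmentation of the 3-part case."""
    volume, truth = three_part_case
    markers = markers_from_truth(truth)
    config = StudyConfig()
    case = CaseInputs(case_id="fx", fractured=volume, template=None,  # type: ignore[arg-type]
                      template_landmarks=None, markers=markers)  # type: ignore[arg-type]
    return _segment_stage(config, case), markers


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same deterministic stream
    # regardless of which other tests ran before it
    return np.random.default_rng(1234)


def random_rigid(rng, max_deg: float, max_mm: float, pivot=None):
    """Random proper rigid transform with bounded rotation/translation."""
    from fracmap.core import RigidTransform

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.3, 1.0) * max_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
    t = rng.normal(size=3)
    t = t / np.linalg.norm(t) * rng.uniform(0.3, 1.0) * max_mm
    if pivot is not None:
        t = np.asarray(pivot) - R @ np.asarray(pivot) + t
    return RigidTransform(rotation=R, translation=t)
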
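"""Synthetic humerus-like phantoms with exact ground truth.

The phantom is an analytic signed-distance body: a spherical "head"
joined to a capped cylindrical "shaft", with Gaussian surface bumps
standing in for the greater and lesser tuberosities.  The cortical
shell is the band of the signed distance between ``-cortical_thickness``
and 0, so ground-truth masks, the outer surface and landmark positions
are exact by construction rather than products of a second segmentation.

Rendered intensities are CT-like but arbitrary: background 0, trabecular
interior 200, cortical bone 700, optionally followed by Gaussian blur
(``blur_fwhm``) and additive Gaussian noise (``noise_sd``).

Fractures are applied by partitioning the body with parametric cut
surfaces, deleting cortical voxels inside comminution spheres, and
rigidly displacing each fragment; all ground truth (labels in both the
intact and the displaced frame, removed voxels, cut rim curves on the
outer surface, true displacements) is exported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import ndimage
from scipy.optimize import brentq
from skimage.measure import marching_cubes

from . import _geometry
from ._voxels import label_mask
from .core import LabelMap, LandmarkSet, RigidTransform, VolumeImage

BACKGROUND_HU = 0.0
INTERIOR_HU = 200.0
CORTEX_HU = 700.0


@dataclass
class GridSpec:
    """Regular sampling grid: shape (voxels), spacing (mm), origin (mm)."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.spacing
        )

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) world coordinates of voxel centers."""
        axes = [
            self.origin[d] + np.arange(self.shape[d]) * self.spacing[d] for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


@dataclass
class ShapeParams:
    """Parametric humerus-like shape.

    Defaults describe a scaled-down proximal humerus sized to fit a
    64-voxel grid at 0.5 mm spacing with margin; `tuberosity_offsets`
    are (unit direction from the head center, bump amplitude mm) pairs.
    """

    head_radius: float = 6.5
    shaft_radius: float = 4.0
    shaft_length: float = 14.0
    tuberosity_offsets: list[tuple[tuple[float, float, float], float]] = field(
        default_factory=lambda: [
            ((0.94, 0.0, 0.342), 1.2),   # greater tuberosity: lateral, slightly up
            ((0.0, 0.94, -0.342), 0.8),  # lesser tuberosity: anterior, slightly down
        ]
    )
    cortical_thickness: float = 1.5
    tuberosity_sigma: float = 2.2
    side: str = "left"

    def __post_init__(self) -> None:
        for name in ("head_radius", "shaft_radius", "shaft_length",
                     "cortical_thickness", "tuberosity_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cortical_thickness >= self.head_radius:
            raise ValueError("cortical_thickness must be smaller than head_radius")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        self.tuberosity_offsets = [
            (tuple(np.asarray(d, float) / np.linalg.norm(d)), float(a))
            for d, a in self.tuberosity_offsets
        ]


class CutSurface:
    """Parametric cut surface: sign of ``evaluate`` decides fragment side."""

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class PlanarCut(CutSurface):
    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, float)
        self.normal = tuple(n / np.linalg.norm(n))

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - np.asarray(self.point)) @ np.asarray(self.normal)


@dataclass
class PolySheetCut(CutSurface):
    """Quadratic sheet: planar offset plus curvature in the plane frame."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)  # a u^2 + b u v + c v^2

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, float)
        n = n / np.linalg.norm(n)
        self.normal = tuple(n)
        # plane basis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(n @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, ref)
        self._u = u / np.linalg.norm(u)
        self._v = np.cross(n, self._u)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - np.asarray(self.point)
        h = d @ np.asarray(self.normal)
        u = d @ self._u
        v = d @ self._v
        a, b, c = self.coeffs
        return h + a * u**2 + b * u * v + c * v**2


@dataclass
class FractureSpec:
    """Programmable fracture: cuts, displacements, comminution and imaging noise."""

    cut_surfaces: list[CutSurface]
    fragment_displacements: dict[int, RigidTransform] = field(default_factory=dict)
    comminution_zones: list[tuple[tuple[float, float, float], float]] = field(
        default_factory=list
    )
    noise_sd: float = 0.0
    blur_fwhm: float = 0.0
    seed: int = 0
    # rendered fracture cleft: cortical voxels within cleft_half_width (mm)
    # of a cut surface are dimmed to cleft_intensity, emulating the
    # partial-volume gap of a minimally displaced fracture
    cleft_intensity: float = 450.0
    cleft_half_width: float = 0.45

    def __post_init__(self) -> None:
        if len(self.cut_surfaces) < 1:
            raise ValueError("at least one cut surface is required")
        for t in self.fragment_displacements.values():
            t.validate()
        for _, r in self.comminution_zones:
            if r < 0:
                raise ValueError("comminution radii must be non-negative")


@dataclass
class GroundTruth:
    """Exact per-case truth exported alongside every phantom volume."""

    intact_mask: np.ndarray                  # cortical shell, intact frame
    interior_mask: np.ndarray                # trabecular interior, intact frame
    landmarks: LandmarkSet
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    fragment_labels: LabelMap | None = None  # displaced (observed) frame
    undisplaced_labels: LabelMap | None = None  # intact frame
    removed_voxels: np.ndarray | None = None
    cut_curves: list[np.ndarray] = field(default_factory=list)
    true_displacements: dict[int, RigidTransform] = field(default_factory=dict)
    frame_origin: np.ndarray | None = None  # world coords of the head center
    params: "ShapeParams | None" = None

    @property
    def bone_mask(self) -> np.ndarray:
        return self.intact_mask | self.interior_mask

    def outer_surface(self, smooth_sigma: float = 0.0) -> trimesh.Trimesh:
        """Triangulated intact outer surface in world mm coordinates.

        ``smooth_sigma`` (voxels) smooths the indicator before meshing;
        0 keeps the raw binary iso-surface (exact wrt the mask).
        """
        indicator = self.bone_mask.astype(np.float32)
        if smooth_sigma > 0:
            indicator = ndimage.gaussian_filter(indicator, smooth_sigma)
        verts, faces, _, _ = marching_cubes(indicator, level=0.5, spacing=self.spacing)
        verts = verts + np.asarray(self.origin)
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        if mesh.volume < 0:
            mesh.invert()
        return mesh


class PhantomSizeError(ValueError):
    """Phantom does not fit inside the requested grid with margin."""


class DegenerateCutError(ValueError):
    """A cut surface fails to produce any new fragment."""


def _signed_distance(params: ShapeParams, points: np.ndarray) -> np.ndarray:
    """Outer-surface signed distance (negative inside) in the left-handed frame.

    The head sphere is centered at the frame origin; the shaft extends
    along -z for ``shaft_length``.
    """
    pts = np.atleast_2d(points)
    d_sphere = np.linalg.norm(pts, axis=1) - params.head_radius
    # capped cylinder from z = -shaft_length to z = 0
    rho = np.linalg.norm(pts[:, :2], axis=1)
    dz_low = -pts[:, 2] - params.shaft_length
    dz_high = pts[:, 2]
    d_rad = rho - params.shaft_radius
    d_ax = np.maximum(dz_low, dz_high)
    outside = np.sqrt(np.maximum(d_rad, 0) ** 2 + np.maximum(d_ax, 0) ** 2)
    inside = np.minimum(np.maximum(d_rad, d_ax), 0)
    d_cyl = outside + inside
    d = np.minimum(d_sphere, d_cyl)
    if params.tuberosity_offsets:
        bump = np.zeros(len(pts))
        for direction, amp in params.tuberosity_offsets:
            center = np.asarray(direction) * params.head_radius
            r2 = ((pts - center) ** 2).sum(axis=1)
            bump += amp * np.exp(-r2 / (2 * params.tuberosity_sigma**2))
        d = d - bump
    return d


def _surface_point(params: ShapeParams, base: np.ndarray, direction: np.ndarray
                   ) -> np.ndarray:
    """Exact surface point along a ray (root of the signed distance)."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    span = params.head_radius + params.shaft_length + 5.0

    def f(t: float) -> float:
        return float(_signed_distance(params, (base + t * direction)[None])[0])

    lo = 0.0
    if f(lo) >= 0:  # base outside: march inward instead
        lo, direction = 0.0, -direction
    hi = span
    # bracket the root
    ts = np.linspace(lo, hi, 200)
    vals = [f(t) for t in ts]
    for i in range(len(ts) - 1):
        if vals[i] < 0 <= vals[i + 1]:
            root = brentq(f, ts[i], ts[i + 1], xtol=1e-10)
            return base + root * direction
    raise PhantomSizeError("failed to bracket a surface point along the ray")


def _primary_landmarks(params: ShapeParams) -> dict[str, np.ndarray]:
    """Parametrically defined surface landmarks in the phantom frame."""
    lm: dict[str, np.ndarray] = {}
    o = np.zeros(3)
    lm["head_apex"] = _surface_point(params, o, [0, 0, 1])
    lm["head_anterior"] = _surface_point(params, o, [0, 1, 0.2])
    lm["head_posterior"] = _surface_point(params, o, [0, -1, 0.2])
    lm["head_medial"] = _surface_point(params, o, [-1, 0, 0.2])
    for i, (direction, _) in enumerate(params.tuberosity_offsets):
        name = "greater_tuberosity" if i == 0 else f"lesser_tuberosity_{i}" if i > 1 else "lesser_tuberosity"
        lm[name] = _surface_point(params, o, direction)
    z_neck = -0.25 * params.shaft_length
    z_shaft = -0.75 * params.shaft_length
    for tag, z in (("neck", z_neck), ("shaft", z_shaft)):
        base = np.array([0.0, 0.0, z])
        lm[f"{tag}_lateral"] = _surface_point(params, base, [1, 0, 0])
        lm[f"{tag}_anterior"] = _surface_point(params, base, [0, 1, 0])
        lm[f"{tag}_medial"] = _surface_point(params, base, [-1, 0, 0])
        lm[f"{tag}_posterior"] = _surface_point(params, base, [0, -1, 0])
    lm["shaft_base"] = np.array([0.0, 0.0, -params.shaft_length - 0.0])
    return lm


def _render(shell: np.ndarray, interior: np.ndarray, grid: GridSpec,
            blur_fwhm: float, noise_sd: float, seed: int) -> VolumeImage:
    values = np.full(grid.shape, BACKGROUND_HU, dtype=np.float32)
    values[interior] = INTERIOR_HU
    values[shell] = CORTEX_HU
    if blur_fwhm > 0:
        sigma = blur_fwhm / 2.3548200450309493
        values = ndimage.gaussian_filter(
            values, sigma=[sigma / s for s in grid.spacing]
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, grid.shape).astype(np.float32)
    return VolumeImage(values=values, spacing=grid.spacing, origin=grid.origin)


def make_intact_phantom(
    params: ShapeParams,
    grid: GridSpec | None = None,
    seed: int = 0,
    blur_fwhm: float = 0.0,
    noise_sd: float = 0.0,
) -> tuple[VolumeImage, GroundTruth]:
    """Render an intact phantom and its exact ground truth.

    The phantom frame (head center) is placed so the body is centered in
    the grid.  Right-sided phantoms are generated as the exact mirror
    image of the left-sided phantom (grid arrays flipped along the first
    axis; landmarks reflected across the grid's first-axis mid-plane).
    """
    grid = grid or GridSpec()
    max_amp = max((a for _, a in params.tuberosity_offsets), default=0.0)
    half_xy = max(params.head_radius, params.shaft_radius) + max_amp
    extent_lo = np.array([-half_xy, -half_xy, -params.shaft_length - params.shaft_radius * 0])
    extent_hi = np.array([half_xy, half_xy, params.head_radius + max_amp])
    body_center = (extent_lo + extent_hi) / 2.0
    frame_origin = grid.center - body_center  # world coords of phantom frame origin
    margin = 2.0 * np.asarray(grid.spacing)
    world_lo = np.asarray(grid.origin) + margin
    world_hi = np.asarray(grid.origin) + (np.asarray(grid.shape) - 1) * np.asarray(
        grid.spacing
    ) - margin
    if np.any(frame_origin + extent_lo < world_lo) or np.any(
        frame_origin + extent_hi > world_hi
    ):
        raise PhantomSizeError(
            "phantom does not fit inside the grid with a 2-voxel margin"
        )

    pts = grid.voxel_centers().reshape(-1, 3) - frame_origin
    d = _signed_distance(params, pts).reshape(grid.shape)
    shell = (d <= 0) & (d > -params.cortical_thickness)
    interior = d <= -params.cortical_thickness

    lm = {k: v + frame_origin for k, v in _primary_landmarks(params).items()}
    landmarks = LandmarkSet(primary=lm, case_id="", side=params.side)

    if params.side == "right":
        shell = np.flip(shell, axis=0).copy()
        interior = np.flip(interior, axis=0).copy()
        center = grid.center
        landmarks = landmarks.mirrored(center, np.array([1.0, 0.0, 0.0]))
        landmarks = replace(landmarks, side="right")
        frame_origin = frame_origin.copy()
        frame_origin[0] = 2 * center[0] - frame_origin[0]

    volume = _render(shell, interior, grid, blur_fwhm, noise_sd, seed)
    truth = GroundTruth(
        intact_mask=shell,
        interior_mask=interior,
        landmarks=landmarks,
        spacing=grid.spacing,
        origin=grid.origin,
        frame_origin=frame_origin,
        params=params,
    )
    return volume, truth


def make_solid_phantom(
    shape: str = "ball",
    size: float = 10.0,
    grid: GridSpec | None = None,
    seed: int = 0,
    blur_fwhm: float = 0.0,
    noise_sd: float = 0.0,
) -> tuple[VolumeImage, GroundTruth]:
    """Simple solid test phantom (ball of radius ``size`` or cube of
    half-edge ``size``), rendered at cortex intensity with no interior.

    Useful for isolating cut/tracing behaviour from shell geometry.
    """
    grid = grid or GridSpec()
    center = grid.center
    pts = grid.voxel_centers().reshape(-1, 3) - center
    if shape == "ball":
        mask = (np.linalg.norm(pts, axis=1) <= size).reshape(grid.shape)
    elif shape == "cube":
        mask = (np.abs(pts) <= size).all(axis=1).reshape(grid.shape)
    else:
        raise ValueError("shape must be 'ball' or 'cube'")
    margin = 2.0 * np.asarray(grid.spacing)
    lo = np.asarray(grid.origin) + margin
    hi = np.asarray(grid.origin) + (np.asarray(grid.shape) - 1) * np.asarray(
        grid.spacing) - margin
    if np.any(center - size < lo) or np.any(center + size > hi):
        raise PhantomSizeError("solid phantom does not fit with a 2-voxel margin")
    volume = _render(mask, np.zeros_like(mask), grid, blur_fwhm, noise_sd, seed)
    landmarks = LandmarkSet(primary={
        "top": center + [0, 0, size], "bottom": center - [0, 0, size],
        "east": center + [size, 0, 0], "north": center + [0, size, 0],
    })
    truth = GroundTruth(
        intact_mask=mask,
        interior_mask=np.zeros_like(mask),
        landmarks=landmarks,
        spacing=grid.spacing,
        origin=grid.origin,
        frame_origin=np.asarray(center, dtype=float),
    )
    return volume, truth


#: ShapeParams fields perturbed by sample_cohort, in draw order.
VARIED_FIELDS = ("head_radius", "shaft_radius", "shaft_length",
                 "cortical_thickness", "tuberosity_amplitude")

DEFAULT_VARIATION = {
    "head_radius": 0.05,
    "shaft_radius": 0.05,
    "shaft_length": 0.05,
    "cortical_thickness": 0.08,
    "tuberosity_amplitude": 0.10,
}


def sample_cohort(
    n: int,
    base: ShapeParams | None = None,
    variation: dict[str, float] | None = None,
    right_fraction: float = 0.0,
    seed: int = 0,
    grid: GridSpec | None = None,
    blur_fwhm: float = 0.0,
    noise_sd: float = 0.0,
) -> list[tuple[VolumeImage, GroundTruth]]:
    """Draw a cohort of intact phantoms with per-case shape variation.

    RNG procedure (documented so it can be replayed): one
    ``numpy.random.default_rng(seed)`` stream draws, in order,
    (1) ``rng.random(n) < right_fraction`` deciding sides for all cases,
    then per case (2) one ``rng.normal(1, sd)`` multiplicative factor per
    field of ``VARIED_FIELDS`` (clipped to ≥ 0.2) and (3) one
    ``rng.integers(2**31)`` rendering seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base or ShapeParams()
    variation = DEFAULT_VARIATION if variation is None else variation
    if any(v < 0 for v in variation.values()):
        raise ValueError("variation SDs must be >= 0")
    rng = np.random.default_rng(seed)
    sides = rng.random(n) < right_fraction
    cases = []
    for i in range(n):
        factors = {
            f: max(float(rng.normal(1.0, variation.get(f, 0.0))), 0.2)
            for f in VARIED_FIELDS
        }
        case_seed = int(rng.integers(2**31))
        params = replace(
            base,
            head_radius=base.head_radius * factors["head_radius"],
            shaft_radius=base.shaft_radius * factors["shaft_radius"],
            shaft_length=base.shaft_length * factors["shaft_length"],
            cortical_thickness=base.cortical_thickness * factors["cortical_thickness"],
            tuberosity_offsets=[
                (d, a * factors["tuberosity_amplitude"])
                for d, a in base.tuberosity_offsets
            ],
            side="right" if sides[i] else "left",
        )
        vol, truth = make_intact_phantom(
            params, grid=grid, seed=case_seed, blur_fwhm=blur_fwhm, noise_sd=noise_sd
        )
        truth.landmarks = replace(truth.landmarks, case_id=f"case{i:03d}")
        cases.append((vol, truth))
    return cases


def apply_fracture(
    intact: tuple[VolumeImage, GroundTruth], spec: FractureSpec
) -> tuple[VolumeImage, GroundTruth]:
    """Fracture an intact phantom and update its ground truth.

    Cortical (and interior) voxels are partitioned by the sign pattern of
    the cut surfaces and connectivity; comminution-zone cortical voxels
    are deleted; each fragment is rigidly displaced and the grayscale is
    re-rendered (nearest-neighbour labels, linear grayscale).
    """
    volume, truth = intact
    grid = GridSpec(shape=truth.intact_mask.shape, spacing=truth.spacing,
                    origin=truth.origin)
    shell = truth.intact_mask
    bone = truth.bone_mask
    pts = grid.voxel_centers().reshape(-1, 3)

    signs = np.zeros((len(pts), len(spec.cut_surfaces)), dtype=bool)
    for c, cut in enumerate(spec.cut_surfaces):
        f = cut.evaluate(pts)
        side = (f >= 0).reshape(grid.shape)
        if side[shell].all() or (~side[shell]).all():
            raise DegenerateCutError(f"cut {c} does not divide the cortical shell")
        signs[:, c] = side.ravel()

    # region code per voxel; fragments = connected components within a code
    code = np.zeros(len(pts), dtype=np.int64)
    for c in range(signs.shape[1]):
        code |= signs[:, c].astype(np.int64) << c
    code = code.reshape(grid.shape)
    full_labels = np.zeros(grid.shape, dtype=np.int32)
    next_label = 0
    pieces = []
    for cval in np.unique(code[bone]):
        region = bone & (code == cval)
        lab, k = label_mask(region, connectivity=26)
        for l in range(1, k + 1):
            pieces.append(lab == l)
    if len(pieces) < 2:
        raise DegenerateCutError("cuts did not produce at least 2 fragments")
    # deterministic fragment ids: descending shell-voxel count, C-order tie
    def _seed_index(m: np.ndarray) -> int:
        return int(np.flatnonzero(m.ravel())[0])

    pieces.sort(key=lambda m: (-int((m & shell).sum()), _seed_index(m)))
    for m in pieces:
        next_label += 1
        full_labels[m] = next_label

    removed = np.zeros(grid.shape, dtype=bool)
    for center, radius in spec.comminution_zones:
        r2 = ((pts - np.asarray(center)) ** 2).sum(axis=1).reshape(grid.shape)
        removed |= shell & (r2 <= radius**2)

    undisplaced = np.where(shell & ~removed, full_labels, 0).astype(np.int32)

    # cut rim curves on the intact outer surface
    outer = truth.outer_surface()
    cut_curves: list[np.ndarray] = []
    for cut in spec.cut_surfaces:
        cut_curves.extend(_geometry.mesh_contour(outer, cut.evaluate))

    # intact-frame grayscale with the fracture cleft dimmed
    cleft = np.zeros(grid.shape, dtype=bool)
    if spec.cleft_half_width > 0:
        for cut in spec.cut_surfaces:
            f = np.abs(cut.evaluate(pts)).reshape(grid.shape)
            cleft |= shell & (f <= spec.cleft_half_width)
    src_gray = np.full(grid.shape, BACKGROUND_HU, dtype=np.float32)
    src_gray[truth.interior_mask] = INTERIOR_HU
    src_gray[shell & ~removed] = CORTEX_HU
    src_gray[cleft & ~removed] = spec.cleft_intensity

    # displace fragments; render labels (nearest) and grayscale (linear)
    ids = list(range(1, next_label + 1))
    displacements = {
        fid: spec.fragment_displacements.get(fid, RigidTransform.identity())
        for fid in ids
    }
    new_labels = np.zeros(grid.shape, dtype=np.int32)
    new_gray = np.zeros(grid.shape, dtype=np.float32)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    for fid in ids:
        t = displacements[fid]
        frag = full_labels == fid
        frag_shell = frag & shell & ~removed
        frag_gray = np.where(frag, src_gray, 0.0).astype(np.float32)
        if np.allclose(t.matrix, np.eye(4)):
            moved_shell, moved_gray = frag_shell, frag_gray
        else:
            inv = t.inverse()
            src_idx = (inv.apply(pts) - origin) / spacing  # (n, 3) fractional
            coords = src_idx.T.reshape(3, *grid.shape)
            moved_shell = ndimage.map_coordinates(
                frag_shell.astype(np.uint8), coords, order=0, mode="constant"
            ).astype(bool)
            moved_gray = ndimage.map_coordinates(
                frag_gray, coords, order=1, mode="constant"
            )
        unclaimed = new_labels == 0
        new_labels[moved_shell & unclaimed] = fid
        new_gray = np.maximum(new_gray, moved_gray)

    if spec.blur_fwhm > 0:
        sigma = spec.blur_fwhm / 2.3548200450309493
        new_gray = ndimage.gaussian_filter(
            new_gray, sigma=[sigma / s for s in grid.spacing]
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        new_gray = new_gray + rng.normal(0.0, spec.noise_sd, grid.shape).astype(
            np.float32
        )
    fractured = VolumeImage(values=new_gray, spacing=grid.spacing, origin=grid.origin)
    new_truth = GroundTruth(
        intact_mask=truth.intact_mask,
        interior_mask=truth.interior_mask,
        landmarks=truth.landmarks,
        spacing=truth.spacing,
        origin=truth.origin,
        fragment_labels=LabelMap(new_labels, spacing=truth.spacing, origin=truth.origin),
        undisplaced_labels=LabelMap(undisplaced, spacing=truth.spacing,
                                    origin=truth.origin),
        removed_voxels=removed,
        cut_curves=cut_curves,
        true_displacements=displacements,
        frame_origin=truth.frame_origin,
        params=truth.params,
    )
    return fractured, new_truth
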
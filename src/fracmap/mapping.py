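"""Cohort probability maps on the mean surface.

Each case contributes at most one count per mean-surface vertex and
channel: a fracture-line channel (vertices the case's projected
fracture lines pass through, within a geodesic kernel radius) and a
fragment-area channel (vertices whose corresponded case point lies on a
reduced fragment's surface).  Summing the per-case binary incidence
vectors over the cohort yields the fracture-line and fragment
probability maps; low fragment counts expose comminution-prone zones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from . import _geometry
from .core import FractureLine, RigidTransform
from .ssm import CorrespondenceMap


@dataclass
class IncidenceVector:
    """Per-mean-vertex binary flags for one case and channel."""

    flags: np.ndarray
    case_id: str = ""
    channel: str = "fracture_line"

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags).astype(bool)
        if self.flags.ndim != 1:
            raise ValueError("flags must be a 1D vector")
        if self.channel not in ("fracture_line", "fragment_area"):
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass
class ProbabilityMap:
    """Per-mean-vertex case counts (the Figs 7/8-style heat map data)."""

    counts: np.ndarray
    n_cases: int
    channel: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_cases:
            raise ValueError("counts must lie in [0, n_cases]")


def default_kernel_radius(mean_surface: trimesh.Trimesh) -> float:
    """Geodesic kernel for line incidence: 1.5x mean edge length."""
    return 1.5 * float(mean_surface.edges_unique_length.mean())


def map_line_incidence(
    corr: CorrespondenceMap,
    case_surface: trimesh.Trimesh,
    line: FractureLine | list[FractureLine] | None,
    mean_surface: trimesh.Trimesh,
    radius: float | None = None,
) -> IncidenceVector:
    """Pull a case's fracture line(s) back to the mean surface.

    Lines (in the aligned case frame) are resampled at half the kernel
    radius; each sample maps to the mean vertex whose corresponded case
    point is nearest (inverse correspondence); all mean vertices within
    the geodesic ``radius`` of a hit vertex are flagged.  Binary per
    case regardless of multiplicity.
    """
    n = len(mean_surface.vertices)
    if radius is None:
        radius = default_kernel_radius(mean_surface)
    lines: list[FractureLine] = (
        [] if line is None else [line] if isinstance(line, FractureLine) else list(line)
    )
    if not lines:
        return IncidenceVector(flags=np.zeros(n, dtype=bool))

    matched = corr.matched_points(case_surface)  # case point per mean vertex
    tree = cKDTree(matched)
    hits: set[int] = set()
    step = max(radius / 2.0, 1e-6)
    for ln in lines:
        samples = ln.resample(step)
        _, vid = tree.query(samples)
        hits.update(int(v) for v in np.atleast_1d(vid))
    flags = np.zeros(n, dtype=bool)
    seeds = np.fromiter(hits, dtype=np.int64)
    if radius > 0:
        graph = _geometry.edge_graph(mean_surface)
        d = _geometry.geodesic_distances(graph, seeds, limit=radius * (1 + 1e-9))
        flags[np.isfinite(d)] = True
    flags[seeds] = True
    return IncidenceVector(flags=flags, channel="fracture_line")


def map_fragment_incidence(
    corr: CorrespondenceMap,
    case_surface: trimesh.Trimesh,
    fragment_surface: trimesh.Trimesh,
    reduced_transform: RigidTransform | None = None,
    max_dist: float = 1.0,
) -> IncidenceVector:
    """Flag mean vertices covered by one reduced fragment.

    A mean vertex is flagged iff its corresponded case point lies within
    ``max_dist`` mm of the fragment surface after applying the
    reduction transform.
    """
    t = reduced_transform or RigidTransform.identity()
    t.validate()
    reduced = trimesh.Trimesh(
        vertices=t.apply(fragment_surface.vertices.view(np.ndarray)),
        faces=fragment_surface.faces,
        process=False,
    )
    matched = corr.matched_points(case_surface)
    _, d, _ = _geometry.MeshDistance(reduced).query(matched)
    return IncidenceVector(flags=d <= max_dist, channel="fragment_area")


def combine_case_incidence(vectors: list[IncidenceVector]) -> IncidenceVector:
    """Binary union of one case's per-fragment (or per-line) incidences."""
    if not vectors:
        raise ValueError("no incidence vectors given")
    channels = {v.channel for v in vectors}
    if len(channels) > 1:
        raise ValueError(f"mixed channels: {sorted(channels)}")
    flags = np.zeros_like(vectors[0].flags)
    for v in vectors:
        flags |= v.flags
    return IncidenceVector(flags=flags, case_id=vectors[0].case_id,
                           channel=vectors[0].channel)


def accumulate_probability(incidences: list[IncidenceVector]) -> ProbabilityMap:
    """Vertexwise case counts: one binary vector per case, summed."""
    if not incidences:
        raise ValueError("no incidence vectors given")
    channels = {v.channel for v in incidences}
    if len(channels) > 1:
        raise ValueError(f"mixed channels: {sorted(channels)}")
    lengths = {len(v.flags) for v in incidences}
    if len(lengths) > 1:
        raise ValueError("incidence vectors have differing lengths")
    counts = np.zeros(lengths.pop(), dtype=np.int64)
    for v in incidences:
        counts += v.flags
    return ProbabilityMap(counts=counts, n_cases=len(incidences),
                          channel=channels.pop())
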
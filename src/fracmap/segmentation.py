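"""Cortical-shell segmentation and marker-driven fragment splitting.

The cortical shell is pre-segmented with a local adaptive threshold,
detached fragments are found by connected components, and fragments
that are not fully detached are split with minimal interaction: given
seed markers on the parts to separate, voxels are removed in order of
descending grayscale gradient until the marker groups disconnect, and
every removed voxel whose return would not re-join two groups is added
back, so only a minimal gradient barrier stays removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._voxels import connectivity_structure, label_mask, neighbor_offsets
from .core import LabelMap, VolumeImage


@dataclass
class SeedMarkers:
    """Voxel seeds naming the parts to separate: (group id, index triple)."""

    markers: list[tuple[int, tuple[int, int, int]]]

    def __post_init__(self) -> None:
        self.markers = [(int(g), tuple(int(i) for i in idx)) for g, idx in self.markers]
        if len({g for g, _ in self.markers}) < 2:
            raise ValueError("markers must contain at least 2 distinct group ids")

    @property
    def groups(self) -> list[int]:
        return sorted({g for g, _ in self.markers})

    def by_group(self) -> dict[int, list[tuple[int, int, int]]]:
        out: dict[int, list[tuple[int, int, int]]] = {}
        for g, idx in self.markers:
            out.setdefault(g, []).append(idx)
        return out


def adaptive_threshold(
    volume: VolumeImage, window_radius: int = 8, min_contrast: float = 100.0
) -> np.ndarray:
    """Locally adaptive foreground mask for the bright cortical shell.

    A voxel is foreground when its value reaches the local threshold
    ``local_mean + offset`` where the offset shifts the threshold to the
    window mid-range ``(local_min + local_max) / 2`` — i.e. the offset is
    contrast-dependent.  Windows whose intensity range is below
    ``min_contrast`` carry no evidence of an edge and are background.
    """
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    size = 2 * window_radius + 1
    if any(size > s for s in volume.shape):
        raise ValueError("window larger than volume")
    v = volume.values.astype(np.float32)
    lo = ndimage.minimum_filter(v, size=size, mode="nearest")
    hi = ndimage.maximum_filter(v, size=size, mode="nearest")
    threshold = (lo + hi) / 2.0
    return (v >= threshold) & (hi - lo >= min_contrast)


def gradient_magnitude(volume: VolumeImage) -> np.ndarray:
    """Euclidean norm of the central-difference gradient (per mm).

    One-sided differences at the grid boundary, central in the interior.
    Axes of length 1 contribute zero.
    """
    v = volume.values.astype(np.float64)
    total = np.zeros_like(v)
    for axis in range(3):
        if v.shape[axis] > 1:
            total += np.gradient(v, volume.spacing[axis], axis=axis) ** 2
    return np.sqrt(total)


def label_components(
    mask: np.ndarray, connectivity: int = 26, min_voxels: int = 1
) -> LabelMap | np.ndarray:
    """Connected components labelled 1..K by descending size.

    Ties broken by the smallest lexicographic seed voxel. Components
    smaller than ``min_voxels`` are dropped (labels stay contiguous).
    """
    labels, k = label_mask(np.asarray(mask, bool), connectivity)
    if min_voxels > 1 and k:
        counts = np.bincount(labels.ravel())
        keep = [l for l in range(1, k + 1) if counts[l] >= min_voxels]
        remap = np.zeros(k + 1, dtype=np.int32)
        for new, old in enumerate(keep, start=1):
            remap[old] = new
        labels = remap[labels]
    return labels


def segment_fragments(
    volume: VolumeImage,
    window_radius: int = 8,
    min_contrast: float = 100.0,
    connectivity: int = 26,
    min_voxels: int = 27,
) -> LabelMap:
    """Adaptive threshold + connected components: the detached-fragment map."""
    mask = adaptive_threshold(volume, window_radius, min_contrast)
    labels = label_components(mask, connectivity=connectivity, min_voxels=min_voxels)
    return LabelMap.like(volume, labels)


class _UnionFind:
    """Union-find over voxel flat indices carrying a marker-group tag."""

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}
        self.group: dict[int, int] = {}

    def add(self, x: int, group: int = 0) -> None:
        if x not in self.parent:
            self.parent[x] = x
            self.group[x] = group

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        """Merge; returns False if it would join two distinct marker groups."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return True
        ga, gb = self.group[ra], self.group[rb]
        if ga and gb and ga != gb:
            return False
        self.parent[ra] = rb
        if ga and not gb:
            self.group[rb] = ga
        return True

    def would_conflict(self, roots: list[int]) -> bool:
        tags = {self.group[r] for r in roots if self.group[r]}
        return len(tags) > 1


def _groups_connected(
    mask: np.ndarray, markers: SeedMarkers, connectivity: int
) -> bool:
    """True if any two marker groups lie in one connected component."""
    lab, _ = label_mask(mask, connectivity)
    comp_groups: dict[int, set[int]] = {}
    for g, idx in markers.markers:
        c = int(lab[idx])
        if c == 0:
            continue
        comp_groups.setdefault(c, set()).add(g)
    return any(len(s) > 1 for s in comp_groups.values())


def split_fragment(
    volume: VolumeImage,
    mask: np.ndarray,
    markers: SeedMarkers,
    connectivity: int = 26,
    readd_order: str = "removal",
) -> tuple[LabelMap, np.ndarray]:
    """Split one connected fragment along its internal gradient barrier.

    Removal follows descending gradient magnitude (computed once on the
    input grayscale; ties to the smallest lexicographic index) until no
    two marker groups remain connected — realized as the minimal prefix
    of that removal order whose deletion disconnects the groups, which
    is identical to the sequential loop because disconnection is
    monotone under further removal.  Removed voxels are then re-added in
    removal order whenever their return joins no two marker groups.

    Returns the group-id label map and the final removed set.  Marker
    voxels themselves are never removed.
    """
    mask = np.asarray(mask, bool)
    shape = mask.shape
    for g, idx in markers.markers:
        if not mask[idx]:
            raise ValueError(f"marker {idx} of group {g} lies outside the mask")

    marker_flat = {np.ravel_multi_index(idx, shape): g for g, idx in markers.markers}

    if not _groups_connected(mask, markers, connectivity):
        removed = np.zeros(shape, dtype=bool)
        labels = _label_by_group(mask, markers, connectivity)
        return LabelMap.like(volume, labels), removed

    grad = gradient_magnitude(volume)
    cand = np.flatnonzero(mask.ravel())
    cand = cand[~np.isin(cand, list(marker_flat))]
    # removal order: descending gradient, then ascending C-order index
    order = cand[np.lexsort((cand, -grad.ravel()[cand]))]

    def disconnected_after(prefix: int) -> bool:
        m = mask.copy()
        m.ravel()[order[:prefix]] = False
        return not _groups_connected(m, markers, connectivity)

    lo, hi = 0, len(order)  # lo: still connected; hi: disconnected
    if not disconnected_after(hi):
        raise ValueError("marker groups cannot be disconnected by voxel removal")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if disconnected_after(mid):
            hi = mid
        else:
            lo = mid
    removal_sequence = order[:hi]

    # incremental re-add pass with union-find over kept voxels
    kept = mask.copy()
    kept.ravel()[removal_sequence] = False
    offsets = neighbor_offsets(connectivity)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    flat_offsets = offsets @ strides

    uf = _UnionFind()
    kept_flat = np.flatnonzero(kept.ravel())
    for f in kept_flat:
        uf.add(int(f), marker_flat.get(int(f), 0))
    idx3 = np.array(np.unravel_index(kept_flat, shape)).T
    for f, ijk in zip(kept_flat, idx3):
        for off, foff in zip(offsets, flat_offsets):
            nijk = ijk + off
            if np.any(nijk < 0) or np.any(nijk >= shape):
                continue
            nf = int(f + foff)
            if kept.ravel()[nf]:
                uf.union(int(f), nf)

    if readd_order == "reverse":
        scan = removal_sequence[::-1]
    elif readd_order == "removal":
        scan = removal_sequence
    else:
        raise ValueError("readd_order must be 'removal' or 'reverse'")
    removed_final: list[int] = []
    for f in scan:
        ijk = np.array(np.unravel_index(f, shape))
        roots = []
        for off, foff in zip(offsets, flat_offsets):
            nijk = ijk + off
            if np.any(nijk < 0) or np.any(nijk >= shape):
                continue
            nf = int(f + foff)
            if kept.ravel()[nf]:
                roots.append(uf.find(nf))
        if uf.would_conflict(roots):
            removed_final.append(int(f))
            continue
        # re-add
        kept.ravel()[f] = True
        uf.add(int(f), marker_flat.get(int(f), 0))
        for r in roots:
            uf.union(int(f), r)

    removed = np.zeros(shape, dtype=bool)
    removed.ravel()[removed_final] = True
    labels = _label_by_group(mask & ~removed, markers, connectivity)
    return LabelMap.like(volume, labels), removed


def _label_by_group(
    kept: np.ndarray, markers: SeedMarkers, connectivity: int
) -> np.ndarray:
    """Label kept voxels by the marker group their component connects to.

    Components touching no marker (isolated pockets left by the re-add
    pass) are assigned the group of the nearest labelled voxel so that
    labels plus the removed set exactly partition the input mask.
    """
    lab, k = label_mask(kept, connectivity)
    comp_to_group = np.zeros(k + 1, dtype=np.int32)
    for g, idx in markers.markers:
        c = int(lab[idx])
        if c > 0:
            comp_to_group[c] = g
    out = comp_to_group[lab]
    orphan = kept & (out == 0)
    if orphan.any():
        _, nearest = ndimage.distance_transform_edt(out == 0, return_indices=True)
        out[orphan] = out[tuple(nearest[:, orphan])]
    return out.astype(np.int32)
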
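"""Voxel-grid helpers: connectivity structures and deterministic labelling."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D neighbourhood footprint for 6- or 26-connectivity."""
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def neighbor_offsets(connectivity: int) -> np.ndarray:
    """(k, 3) integer offsets of the chosen neighbourhood, excluding the centre."""
    s = connectivity_structure(connectivity)
    off = np.argwhere(s) - 1
    return off[np.any(off != 0, axis=1)]


def label_mask(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """Connected components of a binary mask, deterministically ordered.

    Components are numbered 1..K by descending voxel count; ties broken by
    the smallest lexicographic (C-order) voxel index in the component.
    """
    raw, n = ndimage.label(mask, structure=connectivity_structure(connectivity))
    if n == 0:
        return raw.astype(np.int32), 0
    counts = np.bincount(raw.ravel())[1:]
    # first C-order occurrence of each label = lexicographic seed voxel
    flat = raw.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier positions overwrite later ones
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = sorted(range(1, n + 1), key=lambda l: (-counts[l - 1], first_idx[l]))
    remap = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[raw], n
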
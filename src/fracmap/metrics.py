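"""Evaluation metrics: inter-operator line distances, Dice, Hausdorff."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import FractureLine, LabelMap


@dataclass
class DistanceSummary:
    """Mean ± SD of per-point closest distances (mm)."""

    mean: float
    sd: float
    n_points: int
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.n_points != len(self.distances):
            raise ValueError("n_points must match the distance list")


def _resample_set(lines: list[FractureLine], step: float) -> np.ndarray:
    return np.vstack([ln.resample(step) for ln in lines])


def line_set_distance(
    a: list[FractureLine],
    b: list[FractureLine],
    step: float = 0.5,
    symmetric: bool = False,
) -> DistanceSummary:
    """Closest-point distances from line set ``a`` to line set ``b``.

    Both sets are resampled at a common arc-length ``step`` (mm); for
    every sampled point of ``a`` the closest Euclidean distance to any
    sampled point of ``b`` is taken; mean ± SD over those points is
    reported.  Directional by default (this is the two-operator
    reproducibility measure); ``symmetric=True`` pools both directions.
    """
    if not a or not b:
        raise ValueError("both line sets must be non-empty")
    pa = _resample_set(a, step)
    pb = _resample_set(b, step)
    d = cKDTree(pb).query(pa)[0]
    if symmetric:
        d = np.concatenate([d, cKDTree(pa).query(pb)[0]])
    return DistanceSummary(
        mean=float(d.mean()), sd=float(d.std()), n_points=len(d), distances=d
    )


def label_overlap_dice(
    a: LabelMap, b: LabelMap, pairing: dict[int, int] | None = None
) -> dict[int, float]:
    """Per-fragment Dice 2|A∩B| / (|A|+|B|) over paired labels."""
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing) or not np.allclose(
        a.origin, b.origin
    ):
        raise ValueError("label maps must share grid geometry")
    if pairing is None:
        pairing = {l: l for l in a.ids}
    out: dict[int, float] = {}
    for la, lb in pairing.items():
        ma = a.labels == la
        mb = b.labels == lb
        denom = int(ma.sum()) + int(mb.sum())
        out[la] = 2.0 * int((ma & mb).sum()) / denom if denom else 0.0
    return out


def curve_hausdorff(
    a: np.ndarray | FractureLine, b: np.ndarray | FractureLine, step: float = 0.5
) -> float:
    """Symmetric Hausdorff distance between two polylines (mm).

    Both curves are resampled at the common arc-length ``step`` first.
    """
    pa = a.resample(step) if isinstance(a, FractureLine) else _poly_resample(a, step)
    pb = b.resample(step) if isinstance(b, FractureLine) else _poly_resample(b, step)
    ta, tb = cKDTree(pa), cKDTree(pb)
    return float(max(tb.query(pa)[0].max(), ta.query(pb)[0].max()))


def _poly_resample(points: np.ndarray, step: float) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return pts
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return pts[:1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(t, s, pts[:, d])
    return out
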
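"""Core value types shared across the pipeline.

Volumes follow the medical-imaging convention: a regular 3D grid of
scalars with physical voxel ``spacing`` (mm) and world ``origin`` (mm),
index order (i, j, k) mapping to world x = origin + index * spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class VolumeImage:
    """3D scalar grid with physical geometry (CT-like data carrier)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_geometry(self, other: "VolumeImage | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_values(self, values: np.ndarray) -> "VolumeImage":
        return replace(self, values=values)


@dataclass
class LabelMap:
    """Integer-labelled voxel grid on the geometry of its source volume.

    Label 0 is background; positive labels identify fragments.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def ids(self) -> list[int]:
        """Sorted positive label ids present in the map."""
        u = np.unique(self.labels)
        return [int(v) for v in u if v > 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @classmethod
    def like(cls, volume: VolumeImage, labels: np.ndarray) -> "LabelMap":
        return cls(labels=labels, spacing=volume.spacing, origin=volume.origin)


@dataclass
class RigidTransform:
    """Proper rigid (optionally uniformly scaled) transform y = s R x + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.scale = float(self.scale)
        self.validate()

    def validate(self) -> None:
        R = self.rotation
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal within 1e-9")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation
            + self.translation,
            scale=self.scale * other.scale,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(
            rotation=Rinv,
            translation=-Rinv @ self.translation / self.scale,
            scale=1.0 / self.scale,
        )

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        A = m[:3, :3]
        scale = float(np.cbrt(np.linalg.det(A)))
        if not np.isfinite(scale) or scale <= 0:
            raise ValueError("linear part is not a scaled proper rotation")
        return cls(rotation=A / scale, translation=m[:3, 3], scale=scale)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def rotation_angle_deg(self) -> float:
        """Rotation magnitude in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class FractureLine:
    """Ordered polyline of 3D points along a fragment border (mm)."""

    points: np.ndarray
    closed: bool = False
    fragment: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("line points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("a fracture line needs at least 2 points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive line points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    def arc_length(self) -> float:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        total = float(seg.sum())
        if self.closed:
            total += float(np.linalg.norm(self.points[0] - self.points[-1]))
        return total

    def resample(self, step: float) -> np.ndarray:
        """Resample at uniform arc-length ``step`` (mm); includes endpoints."""
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total == 0:
            return pts[:1].copy()
        n = max(int(np.ceil(total / step)) + 1, 2)
        t = np.linspace(0.0, total, n)
        out = np.empty((n, 3))
        for d in range(3):
            out[:, d] = np.interp(t, s, pts[:, d])
        return out


@dataclass
class LandmarkSet:
    """Named primary landmarks plus ordered secondary points per connecting line."""

    primary: dict[str, np.ndarray]
    secondary: dict[str, np.ndarray] = field(default_factory=dict)
    case_id: str = ""
    side: str = "left"

    def __post_init__(self) -> None:
        self.primary = {str(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.primary.items()}
        self.secondary = {
            str(k): np.asarray(v, dtype=float).reshape(-1, 3) for k, v in self.secondary.items()
        }
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def names(self) -> list[str]:
        return list(self.primary)

    def stacked(self) -> np.ndarray:
        """All landmarks as one (n, 3) array in deterministic order.

        Primary points in sorted-name order, then secondary groups in
        sorted line-id order, each group's points in stored order.
        """
        rows = [self.primary[k] for k in sorted(self.primary)]
        for k in sorted(self.secondary):
            rows.extend(self.secondary[k])
        return np.asarray(rows, dtype=float).reshape(-1, 3)

    def compatible_with(self, other: "LandmarkSet") -> bool:
        if sorted(self.primary) != sorted(other.primary):
            return False
        if sorted(self.secondary) != sorted(other.secondary):
            return False
        return all(
            len(self.secondary[k]) == len(other.secondary[k]) for k in self.secondary
        )

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(
            primary={k: t.apply(v[None])[0] for k, v in self.primary.items()},
            secondary={k: t.apply(v) for k, v in self.secondary.items()},
            case_id=self.case_id,
            side=self.side,
        )

    def mirrored(self, point: np.ndarray, normal: np.ndarray) -> "LandmarkSet":
        from . import _geometry

        flipped_side = "right" if self.side == "left" else "left"
        return LandmarkSet(
            primary={
                k: _geometry.reflect_points(v[None], point, normal)[0]
                for k, v in self.primary.items()
            },
            secondary={
                k: _geometry.reflect_points(v, point, normal)
                for k, v in self.secondary.items()
            },
            case_id=self.case_id,
            side=flipped_side,
        )
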
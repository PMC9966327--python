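"""File formats: volumes (NIfTI/MetaImage), meshes (PLY/STL), landmarks,
fracture lines, probability maps and YAML specs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import trimesh
import yaml

from .core import FractureLine, LabelMap, LandmarkSet, VolumeImage
from .mapping import ProbabilityMap
from .segmentation import SeedMarkers


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    The array is returned in (i, j, k) index order matching the file's
    voxel grid, with spacing/origin taken from the header.
    """
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # zyx -> xyz
    return VolumeImage(
        values=values, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin())
    )


def write_volume(volume: VolumeImage | LabelMap, path: str | Path) -> None:
    """Write a volume or label map as NIfTI or MetaImage (by extension)."""
    if isinstance(volume, LabelMap):
        arr = volume.labels.astype(np.int32)
    else:
        arr = volume.values.astype(np.float32)
    img = sitk.GetImageFromArray(arr.transpose(2, 1, 0))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    sitk.WriteImage(img, str(path))


def read_labels(path: str | Path) -> LabelMap:
    img = sitk.ReadImage(str(path))
    labels = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.int32)
    return LabelMap(
        labels=labels, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin())
    )


def read_markers(path: str | Path) -> SeedMarkers:
    """Markers as JSON: [{"group": 1, "index": [i, j, k]}, ...] (0-based)."""
    entries = json.loads(Path(path).read_text())
    return SeedMarkers(markers=[(e["group"], tuple(e["index"])) for e in entries])


def write_markers(markers: SeedMarkers, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([{"group": g, "index": list(i)} for g, i in markers.markers],
                   indent=2)
    )


def write_mesh(mesh: trimesh.Trimesh, path: str | Path,
               vertex_quality: np.ndarray | None = None) -> None:
    """Write PLY (binary) or STL; optional per-vertex scalar as PLY `quality`."""
    path = Path(path)
    if vertex_quality is not None and path.suffix.lower() == ".ply":
        _write_ply_with_quality(mesh, np.asarray(vertex_quality, float), path)
        return
    mesh.export(str(path))


def _write_ply_with_quality(mesh: trimesh.Trimesh, quality: np.ndarray,
                            path: Path) -> None:
    v = mesh.vertices.view(np.ndarray).astype("<f4")
    f = mesh.faces.astype("<i4")
    q = quality.astype("<f4")
    header = (
        "ply\nformat binary_little_endian 1.0\n"
        f"element vertex {len(v)}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property float quality\n"
        f"element face {len(f)}\n"
        "property list uchar int vertex_indices\nend_header\n"
    )
    vert = np.empty(len(v), dtype=[("xyz", "<f4", 3), ("q", "<f4")])
    vert["xyz"] = v
    vert["q"] = q
    face = np.empty(len(f), dtype=[("n", "u1"), ("idx", "<i4", 3)])
    face["n"] = 3
    face["idx"] = f
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(vert.tobytes())
        fh.write(face.tobytes())


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), force="mesh", process=False)
    return trimesh.Trimesh(vertices=m.vertices, faces=m.faces, process=False)


def write_line(line: FractureLine, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "fragment": int(line.fragment),
                "closed": bool(line.closed),
                "points": np.asarray(line.points).tolist(),
            },
            indent=2,
        )
    )


def read_line(path: str | Path) -> FractureLine:
    d = json.loads(Path(path).read_text())
    return FractureLine(
        points=np.asarray(d["points"], float),
        closed=bool(d["closed"]),
        fragment=int(d.get("fragment", 0)),
    )


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    """JSON (full structure) or CSV (name,x,y,z) by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = [
            {"name": k, "x": v[0], "y": v[1], "z": v[2]}
            for k, v in landmarks.primary.items()
        ]
        for k, pts in landmarks.secondary.items():
            rows.extend(
                {"name": f"{k}#{i}", "x": p[0], "y": p[1], "z": p[2]}
                for i, p in enumerate(pts)
            )
        pd.DataFrame(rows).to_csv(path, index=False)
        return
    payload = {
        "case_id": landmarks.case_id,
        "side": landmarks.side,
        "primary": {k: v.tolist() for k, v in landmarks.primary.items()},
        "secondary": {k: v.tolist() for k, v in landmarks.secondary.items()},
    }
    path.write_text(json.dumps(payload, indent=2))


def read_landmarks(path: str | Path) -> LandmarkSet:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        primary: dict[str, np.ndarray] = {}
        secondary: dict[str, list] = {}
        for _, row in df.iterrows():
            name = str(row["name"])
            p = np.array([row["x"], row["y"], row["z"]], dtype=float)
            if "#" in name:
                key = name.split("#")[0]
                secondary.setdefault(key, []).append(p)
            else:
                primary[name] = p
        return LandmarkSet(
            primary=primary, secondary={k: np.asarray(v) for k, v in secondary.items()}
        )
    d = json.loads(path.read_text())
    return LandmarkSet(
        primary={k: np.asarray(v) for k, v in d["primary"].items()},
        secondary={k: np.asarray(v) for k, v in d.get("secondary", {}).items()},
        case_id=d.get("case_id", ""),
        side=d.get("side", "left"),
    )


def write_probability_map(
    pmap: ProbabilityMap, mean_surface: trimesh.Trimesh, stem: str | Path
) -> None:
    """PLY with per-vertex integer counts as `quality`, plus CSV."""
    stem = Path(stem)
    write_mesh(mean_surface, stem.with_suffix(".ply"),
               vertex_quality=pmap.counts.astype(float))
    pd.DataFrame(
        {"vertex_id": np.arange(len(pmap.counts)), "count": pmap.counts}
    ).to_csv(stem.with_suffix(".csv"), index=False)


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_yaml(data: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
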
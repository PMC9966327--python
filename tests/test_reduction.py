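"""Mirroring, ICP reduction and closest-point line projection."""

import numpy as np
import pytest
import trimesh

import fracmap as fm
from fracmap.core import FractureLine, RigidTransform
from fracmap.reduction import (
    load_transforms,
    mirror_mesh,
    project_line_to_surface,
    reduce_fragment,
    save_transforms,
)
from conftest import random_rigid


class TestMirrorMesh:
    def test_involution(self):
        mesh = trimesh.creation.icosphere(2, radius=4.0)
        mesh.vertices += [3.0, -2.0, 1.0]
        plane = ([1.0, 2.0, 3.0], np.array([1.0, 1.0, 0.0]) / np.sqrt(2))
        back = mirror_mesh(mirror_mesh(mesh, *plane), *plane)
        assert np.abs(back.vertices - mesh.vertices).max() < 1e-12

    def test_signed_volume_preserved(self):
        mesh = trimesh.creation.icosphere(2, radius=4.0)
        mirrored = mirror_mesh(mesh, [0, 0, 0], [1, 0, 0])
        assert mirrored.volume == pytest.approx(mesh.volume, rel=1e-9)

    def test_right_phantom_mirrors_onto_left(self):
        left, lt = fm.make_intact_phantom(fm.ShapeParams(side="left"))
        _, rt = fm.make_intact_phantom(fm.ShapeParams(side="right"))
        grid = fm.GridSpec()
        mirrored = mirror_mesh(rt.outer_surface(), grid.center, [1, 0, 0])
        from fracmap._geometry import polyline_hausdorff

        h = polyline_hausdorff(mirrored.vertices, lt.outer_surface().vertices)
        assert h <= 0.5 * max(grid.spacing)

    def test_zero_normal_rejected(self):
        mesh = trimesh.creation.icosphere(1)
        with pytest.raises(ValueError):
            mirror_mesh(mesh, [0, 0, 0], [0, 0, 0])


@pytest.fixture(scope="module")
def head_fragment_and_template(neck_cut_case):
    """Ground-truth head fragment mesh + smoothed intact template."""
    from fracmap.fracture_lines import mesh_fragment, outer_vertex_mask

    _, truth = neck_cut_case
    mesh = mesh_fragment(truth.fragment_labels, 2, smooth_sigma=1.0)
    outer = outer_vertex_mask(mesh, truth.fragment_labels.labels > 0,
                              truth.spacing, truth.origin)
    template = truth.outer_surface(smooth_sigma=1.0)
    return mesh, outer, template


class TestReduceFragment:
    def test_in_place_fragment_stays_put(self, head_fragment_and_template):
        mesh, outer, template = head_fragment_and_template
        res = reduce_fragment(mesh, template, vertex_mask=outer, seed=0)
        assert res.transform.rotation_angle_deg() < 0.5
        assert np.linalg.norm(res.transform.translation) < 0.5
        assert res.residual < 0.5

    def test_recovers_known_displacement(self, head_fragment_and_template, rng):
        mesh, outer, template = head_fragment_and_template
        pivot = mesh.vertices.mean(axis=0)
        T = random_rigid(rng, max_deg=15, max_mm=8, pivot=pivot)
        displaced = trimesh.Trimesh(vertices=T.apply(mesh.vertices),
                                    faces=mesh.faces, process=False)
        from fracmap.reduction import principal_axis_init

        res = min(
            (reduce_fragment(displaced, template, init=init, vertex_mask=outer,
                             seed=0)
             for init in (None, principal_axis_init(displaced, template))),
            key=lambda r: r.residual,
        )
        err = res.transform.compose(T)
        assert err.rotation_angle_deg() <= 1.0
        assert np.linalg.norm(err.apply(pivot[None])[0] - pivot) <= 0.2

    def test_residual_monotone(self, head_fragment_and_template, rng):
        mesh, outer, template = head_fragment_and_template
        T = random_rigid(rng, 15, 8, pivot=mesh.vertices.mean(axis=0))
        displaced = trimesh.Trimesh(vertices=T.apply(mesh.vertices),
                                    faces=mesh.faces, process=False)
        res = reduce_fragment(displaced, template, vertex_mask=outer, seed=0)
        h = res.residual_history
        assert all(b <= a + 1e-12 for a, b in zip(h, h[1:]))

    def test_large_displacement_outside_capture_range(
        self, head_fragment_and_template
    ):
        """A 90-degree tip-over is outside ICP's capture range: either
        the pose is not recovered (and the misfit shows in the flag or
        residual) or, for a near-symmetric fragment, ICP may still land
        in a low-residual symmetric pose — what must never happen is a
        silently wrong *and* converged *and* tight fit that claims to
        recover the true pose."""
        mesh, outer, template = head_fragment_and_template
        R = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)  # 90 deg about x
        pivot = mesh.vertices.mean(axis=0)
        T = RigidTransform(rotation=R, translation=pivot - R @ pivot)
        displaced = trimesh.Trimesh(vertices=T.apply(mesh.vertices),
                                    faces=mesh.faces, process=False)
        res = reduce_fragment(displaced, template, vertex_mask=outer, seed=0,
                              max_iterations=60)
        err = res.transform.compose(T)
        recovered = err.rotation_angle_deg() <= 1.0
        if not recovered:
            assert (not res.converged) or res.residual > 0.3


class TestTransformIO:
    def test_roundtrip(self, tmp_path, rng):
        transforms = {1: RigidTransform.identity(),
                      2: random_rigid(rng, 30, 20)}
        p = tmp_path / "transforms.json"
        save_transforms(p, transforms)
        loaded = load_transforms(p)
        for fid, t in transforms.items():
            assert np.array_equal(loaded[fid].matrix, t.matrix)

    def test_reflection_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        m = np.eye(4)
        m[0, 0] = -1  # det -1
        p.write_text('[{"fragment": 1, "matrix": %s}]' % m.tolist())
        with pytest.raises(ValueError):
            load_transforms(p)


class TestProjectLine:
    def test_idempotent(self):
        surface = trimesh.creation.icosphere(3, radius=6.0)
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3)) * 4
        line = FractureLine(points=pts)
        once = project_line_to_surface(line, surface)
        twice = project_line_to_surface(once, surface)
        assert np.abs(once.points - twice.points).max() < 1e-9

    def test_plane_offset_recovered(self):
        g = np.linspace(0, 10, 11)
        xx, yy = np.meshgrid(g, g)
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        faces = []
        n = len(g)
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        plane = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
        base = np.column_stack([np.linspace(2, 8, 15), np.linspace(3, 7, 15),
                                np.zeros(15)])
        offset = base + [0, 0, 1.0]
        proj = project_line_to_surface(FractureLine(points=offset), plane)
        assert np.abs(proj.points - base).max() < 1e-6

    def test_matches_exhaustive_triangle_oracle(self, rng):
        """Projection equals the brute-force minimum over all triangles."""
        surface = trimesh.creation.icosphere(2, radius=5.0)  # 320 triangles
        pts = rng.normal(size=(25, 3)) * 4
        proj = project_line_to_surface(FractureLine(points=pts), surface)
        tris = surface.triangles.view(np.ndarray)
        for p, q in zip(pts, proj.points):
            cand = trimesh.triangles.closest_point(
                tris, np.repeat(p[None], len(tris), axis=0))
            d = np.linalg.norm(cand - p, axis=1)
            best = cand[d.argmin()]
            assert np.linalg.norm(q - best) < 1e-9


class TestCompositionProperty:
    def test_reduction_composes_with_small_pre_transform(
        self, head_fragment_and_template, rng
    ):
        """Reducing a pre-transformed fragment recovers the extra
        transform: reduce(T∘frag) ∘ T ≈ reduce(frag)."""
        mesh, outer, template = head_fragment_and_template
        base = reduce_fragment(mesh, template, vertex_mask=outer, seed=0)
        T = random_rigid(rng, 5, 2, pivot=mesh.vertices.mean(axis=0))
        displaced = trimesh.Trimesh(vertices=T.apply(mesh.vertices),
                                    faces=mesh.faces, process=False)
        res = reduce_fragment(displaced, template, vertex_mask=outer, seed=0)
        lhs = res.transform.compose(T)
        diff = lhs.compose(base.transform.inverse())
        assert diff.rotation_angle_deg() < 1.0
        assert np.linalg.norm(diff.translation) < 1.0
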
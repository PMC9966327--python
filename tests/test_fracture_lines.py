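"""Fragment meshing, curvature, guide markers and line tracing."""

import numpy as np
import pytest
import trimesh

from fracmap.core import LabelMap
from fracmap.fracture_lines import (
    mesh_fragment,
    propose_guide_markers,
    trace_fracture_line,
    vertex_curvature,
)


def label_map_from_mask(mask, spacing=(1.0, 1.0, 1.0)):
    return LabelMap(mask.astype(np.int32), spacing=spacing)


class TestMeshFragment:
    def test_single_voxel_topological_sphere(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        mesh = mesh_fragment(label_map_from_mask(m), 1)
        assert mesh.euler_number == 2
        assert mesh.is_watertight

    def test_cube_volume(self):
        m = np.zeros((14, 14, 14), bool)
        m[2:12, 2:12, 2:12] = True
        mesh = mesh_fragment(label_map_from_mask(m), 1)
        assert mesh.volume == pytest.approx(1000, rel=0.10)

    def test_hollow_shell_two_boundary_surfaces(self):
        x, y, z = np.mgrid[:40, :40, :40]
        r = np.sqrt((x - 20.0) ** 2 + (y - 20.0) ** 2 + (z - 20.0) ** 2)
        shell = (r <= 15) & (r >= 10)
        mesh = mesh_fragment(label_map_from_mask(shell), 1)
        assert len(mesh.split(only_watertight=False)) == 2

    def test_absent_label_rejected(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        with pytest.raises(ValueError):
            mesh_fragment(label_map_from_mask(m), 3)

    def test_world_coordinates(self):
        m = np.zeros((8, 8, 8), bool)
        m[2:6, 2:6, 2:6] = True
        labels = LabelMap(m.astype(np.int32), spacing=(0.5, 0.5, 0.5),
                          origin=(10.0, 0.0, 0.0))
        mesh = mesh_fragment(labels, 1)
        assert mesh.vertices[:, 0].min() == pytest.approx(10 + 1.5 * 0.5, abs=0.3)


class TestVertexCurvature:
    def test_sphere(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=8.0)
        H = vertex_curvature(mesh)
        assert np.median(H) == pytest.approx(1 / 8.0, rel=0.10)

    def test_cylinder(self):
        # parametric open tube: interior vertices carry H = 1/(2r)
        r, h, na, nz = 5.0, 30.0, 64, 31
        ang = np.linspace(0, 2 * np.pi, na, endpoint=False)
        zs = np.linspace(-h / 2, h / 2, nz)
        verts = np.array([[r * np.cos(a), r * np.sin(a), z] for z in zs for a in ang])
        faces = []
        for i in range(nz - 1):
            for j in range(na):
                a0 = i * na + j
                a1 = i * na + (j + 1) % na
                faces.append([a0, a1, a0 + na])
                faces.append([a1, a1 + na, a0 + na])
        tube = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
        H = vertex_curvature(tube)
        inner = np.abs(tube.vertices[:, 2]) < 10
        assert inner.sum() > 100
        assert np.median(H[inner]) == pytest.approx(1 / 10.0, rel=0.10)

    def test_flat_patch_interior_zero(self):
        g = np.linspace(0, 10, 12)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        faces = []
        n = len(g)
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        mesh = trimesh.Trimesh(vertices=pts, faces=np.asarray(faces), process=False)
        H = vertex_curvature(mesh)
        interior = (
            (pts[:, 0] > 1) & (pts[:, 0] < 9) & (pts[:, 1] > 1) & (pts[:, 1] < 9)
        )
        assert H[interior].max() < 1e-6

    def test_signed_sign_convention(self):
        sphere = trimesh.creation.icosphere(3, radius=5.0)
        assert np.median(vertex_curvature(sphere, signed=True)) > 0


class TestGuideMarkers:
    def test_smooth_sphere_no_markers(self):
        mesh = trimesh.creation.icosphere(4, radius=8.0)
        H = vertex_curvature(mesh)
        assert propose_guide_markers(mesh, H, quantile=0.99, floor=0.25) == []

    def test_crease_attracts_markers(self):
        """A tent (two half-planes meeting at a right angle): markers
        cluster on the fold line, none on the flats."""
        g = np.linspace(-10, 10, 41)
        xx, yy = np.meshgrid(g, g)
        zz = -np.abs(xx) * 1.0  # fold along x = 0
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        n = len(g)
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        mesh = trimesh.Trimesh(vertices=pts, faces=np.asarray(faces), process=False)
        H = vertex_curvature(mesh)
        markers = propose_guide_markers(mesh, H, quantile=0.90, floor=0.25)
        assert len(markers) >= 3
        assert np.abs(mesh.vertices[markers, 0]).max() < 1.0

    def test_sorted_by_descending_curvature(self, ball_cut_case):
        from fracmap.pipeline import StudyConfig
        from fracmap.studies import markers_from_truth

        _, truth = ball_cut_case
        mesh = mesh_fragment(truth.fragment_labels, 1, smooth_sigma=1.0)
        H = vertex_curvature(mesh)
        markers = propose_guide_markers(mesh, H, 0.9, 0.25)
        assert np.all(np.diff(H[markers]) <= 1e-12)


class TestTraceFractureLine:
    def test_two_adjacent_markers_single_edge(self):
        mesh = trimesh.creation.icosphere(2, radius=5.0)
        a, b = mesh.edges_unique[0]
        line = trace_fracture_line(mesh, [int(a), int(b)], weights=(0.0, 0.0))
        assert len(line) == 2
        assert np.allclose(line.points, mesh.vertices[[a, b]])

    def test_great_circle_length(self):
        """Markers around a great circle with zero weights give a closed
        geodesic polyline whose length approaches 2*pi*R."""
        R = 10.0
        mesh = trimesh.creation.uv_sphere(radius=R, count=[33, 64])
        # the latitude ring nearest the equator (a true mesh polygon ring)
        zmin = np.abs(mesh.vertices[:, 2]).min()
        equator = np.flatnonzero(np.abs(np.abs(mesh.vertices[:, 2]) - zmin) < 1e-9)
        equator = equator[mesh.vertices[equator, 2] > 0]
        ang = np.arctan2(mesh.vertices[equator, 1], mesh.vertices[equator, 0])
        markers = [int(v) for v in equator[np.argsort(ang)][::4]]
        assert len(markers) >= 8
        line = trace_fracture_line(mesh, markers, weights=(0.0, 0.0), close_gap=5.0)
        assert line.closed
        assert line.arc_length() == pytest.approx(2 * np.pi * R, rel=0.05)

    def test_cost_monotone_in_weights(self):
        """Holding a path fixed, its cost never decreases when either
        weight increases."""
        from fracmap.fracture_lines import _edge_costs

        mesh = trimesh.creation.icosphere(3, radius=5.0)
        ridge = np.arange(0, 40)
        path_edges = np.arange(len(mesh.edges_unique))
        base = _edge_costs(mesh, ridge, 1.0, 1.0)
        more_b = _edge_costs(mesh, ridge, 2.0, 1.0)
        more_a = _edge_costs(mesh, ridge, 1.0, 2.0)
        assert np.all(more_b >= base - 1e-12)
        assert np.all(more_a >= base - 1e-12)

    def test_matches_exhaustive_shortest_path_oracle(self):
        """On a small mesh the traced 2-marker path equals the least-cost
        path found by an independent graph library (networkx)."""
        import networkx as nx

        from fracmap.fracture_lines import _edge_costs

        mesh = trimesh.creation.icosphere(1, radius=5.0)  # 42 vertices
        assert len(mesh.vertices) <= 500
        ridge = np.arange(0, 10)
        costs = _edge_costs(mesh, ridge, 1.0, 1.0)
        G = nx.Graph()
        for (a, b), w in zip(mesh.edges_unique, costs):
            G.add_edge(int(a), int(b), weight=float(w))
        rng = np.random.default_rng(0)
        for _ in range(10):
            s, t = rng.choice(len(mesh.vertices), 2, replace=False)
            line = trace_fracture_line(mesh, [int(s), int(t)], weights=(1.0, 1.0),
                                       ridge_vertices=ridge)
            got = sum(
                G[tuple_ab[0]][tuple_ab[1]]["weight"]
                for tuple_ab in zip(
                    [int(np.flatnonzero((mesh.vertices == p).all(axis=1))[0])
                     for p in line.points][:-1],
                    [int(np.flatnonzero((mesh.vertices == p).all(axis=1))[0])
                     for p in line.points][1:],
                )
            )
            expected = nx.shortest_path_length(G, int(s), int(t), weight="weight")
            assert got == pytest.approx(expected, abs=1e-9)

    def test_markers_on_separate_components_rejected(self):
        a = trimesh.creation.icosphere(1, radius=2.0)
        b = trimesh.creation.icosphere(1, radius=2.0)
        b = trimesh.Trimesh(vertices=b.vertices + [10, 0, 0], faces=b.faces)
        mesh = trimesh.util.concatenate([a, b])
        n = len(a.vertices)
        with pytest.raises(ValueError):
            trace_fracture_line(mesh, [0, n + 1])

    def test_every_point_is_a_mesh_vertex(self, ball_cut_case):
        _, truth = ball_cut_case
        mesh = mesh_fragment(truth.fragment_labels, 1, smooth_sigma=1.0)
        H = vertex_curvature(mesh)
        markers = propose_guide_markers(mesh, H, 0.9, 0.25)[:10]
        line = trace_fracture_line(mesh, markers)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(mesh.vertices).query(line.points)
        assert d.max() == 0.0
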
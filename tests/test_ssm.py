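"""Landmark densification, generalized Procrustes and the mean shape."""

import numpy as np
import pytest
import trimesh

from fracmap._geometry import kabsch
from fracmap.core import LandmarkSet, RigidTransform
from fracmap.ssm import (
    build_mean_shape,
    correspond_case,
    densify_landmarks,
    generalized_procrustes,
)
from conftest import random_rigid


def grid_sheet(n=21, extent=10.0):
    g = np.linspace(0, extent, n)
    xx, yy = np.meshgrid(g, g)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


def sphere_landmarks(radius, n=10):
    rng = np.random.default_rng(42)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return {f"lm{i:02d}": dirs[i] * radius for i in range(n)}


class TestDensifyLandmarks:
    def test_zero_secondary_identity(self):
        sheet = grid_sheet()
        lm = LandmarkSet(primary={"a": [0, 0, 0], "b": [10, 10, 0]})
        out = densify_landmarks(lm, sheet, [("a", "b")], n_secondary=0)
        assert out.secondary == {}
        assert out.primary.keys() == lm.primary.keys()

    def test_flat_sheet_collinear_equally_spaced(self):
        sheet = grid_sheet()
        lm = LandmarkSet(primary={"a": [0, 5, 0], "b": [10, 5, 0]})
        out = densify_landmarks(lm, sheet, [("a", "b")], n_secondary=3)
        pts = out.secondary["a:b"]
        assert pts.shape == (3, 3)
        assert np.allclose(pts[:, 1], 5.0, atol=1e-9)
        assert np.allclose(pts[:, 0], [2.5, 5.0, 7.5], atol=0.3)

    def test_sphere_arcs_equally_spaced(self):
        """Secondary landmarks subdivide the on-surface geodesic at
        equal arc fractions; on a sphere the path tracks a great circle."""
        R = 10.0
        mesh = trimesh.creation.icosphere(4, radius=R)
        a = mesh.vertices[np.argmax(mesh.vertices[:, 2])]
        b = mesh.vertices[np.argmax(mesh.vertices[:, 0])]
        lm = LandmarkSet(primary={"a": a, "b": b})
        out = densify_landmarks(lm, mesh, [("a", "b")], n_secondary=5)
        pts = out.secondary["a:b"]
        # on the surface
        assert np.abs(np.linalg.norm(pts, axis=1) - R).max() < 0.1
        # oracle: independent graph-geodesic (networkx) subdivided at
        # equal arc-length fractions
        import networkx as nx

        G = nx.Graph()
        for (u, v), w in zip(mesh.edges_unique, mesh.edges_unique_length):
            G.add_edge(int(u), int(v), weight=float(w))
        ia = int(np.argmax(mesh.vertices[:, 2]))
        ib = int(np.argmax(mesh.vertices[:, 0]))
        # (near-ties make the geodesic route non-unique on a sphere, so
        # compare arc-length structure rather than 3D positions)
        oracle_len = nx.shortest_path_length(G, ia, ib, weight="weight")
        chain = np.vstack([a, pts, b])
        gaps = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        assert gaps.sum() == pytest.approx(oracle_len, rel=0.02)
        assert np.abs(gaps - gaps.mean()).max() <= 0.02 * gaps.sum()

    def test_unknown_pair_rejected(self):
        sheet = grid_sheet()
        lm = LandmarkSet(primary={"a": [0, 0, 0]})
        with pytest.raises(KeyError):
            densify_landmarks(lm, sheet, [("a", "zz")], n_secondary=2)


class TestGeneralizedProcrustes:
    def test_exact_fit_of_transformed_copies(self, rng):
        base = rng.normal(size=(12, 3)) * 10
        configs = []
        for i in range(6):
            T = random_rigid(rng, 180, 30)
            configs.append(LandmarkSet(
                primary={f"p{j:02d}": T.apply(base[j][None])[0] for j in range(12)}
            ))
        aligned, mean, transforms = generalized_procrustes(configs, with_scaling=True)
        assert max(np.abs(a - mean).max() for a in aligned) < 1e-9
        assert np.abs(mean.mean(axis=0)).max() < 1e-9

    def test_case_order_invariance(self, rng):
        base = rng.normal(size=(10, 3)) * 5
        configs = [
            LandmarkSet(primary={
                f"p{j:02d}": base[j] + rng.normal(0, 0.3, 3) for j in range(10)
            })
            for _ in range(5)
        ]
        _, mean_a, _ = generalized_procrustes(configs, with_scaling=False)
        _, mean_b, _ = generalized_procrustes(configs[::-1], with_scaling=False)
        R, t, _ = kabsch(mean_b, mean_a)
        assert np.abs(mean_b @ R.T + t - mean_a).max() < 1e-6

    def test_noisy_mean_rms_scales_inverse_sqrt_n(self, rng):
        """Monte-Carlo: RMS error of the estimated mean configuration
        approaches sigma/sqrt(N)."""
        sigma, N, n_lm = 0.5, 10, 20
        base = rng.normal(size=(n_lm, 3)) * 10
        base -= base.mean(axis=0)
        errs = []
        for _ in range(40):
            cfgs = [
                LandmarkSet(primary={
                    f"p{j:02d}": base[j] + rng.normal(0, sigma, 3)
                    for j in range(n_lm)
                })
                for _ in range(N)
            ]
            _, m, _ = generalized_procrustes(cfgs, with_scaling=False)
            R, t, _ = kabsch(m, base)
            errs.append(np.sqrt(((m @ R.T + t - base) ** 2).mean()))
        assert np.mean(errs) == pytest.approx(sigma / np.sqrt(N), rel=0.2)

    def test_degenerate_configuration_rejected(self):
        line = [LandmarkSet(primary={f"p{j}": [j, 0, 0] for j in range(5)})
                for _ in range(3)]
        with pytest.raises(ValueError):
            generalized_procrustes(line)

    def test_incompatible_names_rejected(self):
        a = LandmarkSet(primary={"x": [0, 0, 0], "y": [1, 0, 0], "z": [0, 1, 0]})
        b = LandmarkSet(primary={"x": [0, 0, 0], "y": [1, 0, 0], "w": [0, 1, 0]})
        with pytest.raises(ValueError):
            generalized_procrustes([a, b])


def sphere_case(radius):
    mesh = trimesh.creation.icosphere(3, radius=radius)
    return mesh, LandmarkSet(primary=sphere_landmarks(radius))


class TestBuildMeanShape:
    def test_identical_cohort_returns_member(self):
        mesh, lm = sphere_case(8.0)
        model = build_mean_shape([(mesh, lm)] * 3, with_scaling=False,
                                 lines=[], n_secondary=0)
        from fracmap._geometry import polyline_hausdorff

        # mean is expressed in the centered frame
        centered = mesh.vertices - lm.stacked().mean(axis=0)
        h = polyline_hausdorff(model.mean_surface.vertices, centered)
        assert h < 1e-6

    def test_sphere_cohort_mean_radius(self):
        cohort = [sphere_case(r) for r in (7.2, 8.0, 8.8)]
        model = build_mean_shape(cohort, with_scaling=False, lines=[], n_secondary=0)
        radii = np.linalg.norm(
            model.mean_surface.vertices - model.mean_surface.vertices.mean(axis=0),
            axis=1,
        )
        assert radii.mean() == pytest.approx(8.0, rel=0.01)

    def test_correspondence_barycentric_validity(self):
        cohort = [sphere_case(r) for r in (7.5, 8.0, 8.5)]
        model = build_mean_shape(cohort, with_scaling=True, lines=[], n_secondary=0)
        for corr in model.correspondences.values():
            assert np.all(corr.barycentric >= -1e-9)
            assert np.allclose(corr.barycentric.sum(axis=1), 1.0)
            assert len(corr.triangle_ids) == len(model.mean_surface.vertices)

    def test_mean_invariant_to_rigid_perturbation(self, rng):
        cohort = [sphere_case(r) for r in (7.5, 8.0, 8.5)]
        model_a = build_mean_shape(cohort, with_scaling=False, lines=[], n_secondary=0)
        perturbed = []
        for mesh, lm in cohort:
            T = random_rigid(rng, 90, 15)
            m2 = trimesh.Trimesh(vertices=T.apply(mesh.vertices), faces=mesh.faces,
                                 process=False)
            perturbed.append((m2, lm.transformed(T)))
        model_b = build_mean_shape(perturbed, with_scaling=False, lines=[],
                                   n_secondary=0)
        from fracmap._geometry import polyline_hausdorff

        va = model_a.mean_surface.vertices
        vb = model_b.mean_surface.vertices
        R, t, _ = kabsch(vb[: len(va)], va)
        assert polyline_hausdorff(vb @ R.T + t, va) < 0.05


class TestCorrespondCase:
    def test_rigidly_moved_case_matches_exactly(self, rng):
        cohort = [sphere_case(r) for r in (7.5, 8.0, 8.5)]
        model = build_mean_shape(cohort, with_scaling=True, lines=[], n_secondary=0)
        mesh, lm = sphere_case(8.0)
        T = random_rigid(rng, 60, 10)
        moved = trimesh.Trimesh(vertices=T.apply(mesh.vertices), faces=mesh.faces,
                                process=False)
        corr, transform = correspond_case(model, moved, lm.transformed(T))
        matched = corr.matched_points(
            trimesh.Trimesh(vertices=transform.apply(moved.vertices),
                            faces=moved.faces, process=False)
        )
        # matched points sit on the case sphere, near the mean vertices
        d = np.abs(np.linalg.norm(matched - matched.mean(axis=0), axis=1) - 8.0)
        assert np.percentile(d, 95) < 0.2

    def test_incompatible_landmarks_rejected(self):
        cohort = [sphere_case(r) for r in (7.5, 8.0, 8.5)]
        model = build_mean_shape(cohort, with_scaling=True, lines=[], n_secondary=0)
        mesh, _ = sphere_case(8.0)
        bad = LandmarkSet(primary={"other": [0, 0, 8.0]})
        with pytest.raises(ValueError):
            correspond_case(model, mesh, bad)
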
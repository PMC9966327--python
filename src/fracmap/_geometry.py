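"""Shared mesh/point geometry kernels.

Closest-point queries run a KDTree candidate search over triangle
centroids and refine with exact point-to-triangle projection; the
candidate radius is grown until it provably brackets the true minimum,
so results equal the exhaustive answer.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree


def kabsch(
    source: np.ndarray, target: np.ndarray, with_scaling: bool = False
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares similarity fit target ≈ s R source + t.

    Returns (R, t, s) with R a proper rotation (det +1).
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    X = src - mu_s
    Y = tgt - mu_t
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if with_scaling:
        denom = (X**2).sum()
        s = float((S * np.diag(D)).sum() / denom) if denom > 0 else 1.0
    else:
        s = 1.0
    t = mu_t - s * R @ mu_s
    return R, t, s


def reflect_points(points: np.ndarray, plane_point, plane_normal) -> np.ndarray:
    """Reflect points across the plane (point, unit normal)."""
    n = np.asarray(plane_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("mirror plane normal must be nonzero")
    n = n / norm
    p0 = np.asarray(plane_point, dtype=float)
    pts = np.asarray(points, dtype=float)
    d = (pts - p0) @ n
    return pts - 2.0 * d[:, None] * n[None, :]


def point_triangle_closest(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Exact closest point on each triangle for each paired query point.

    ``points`` is (n, 3); ``triangles`` is (n, 3, 3). Vectorized version
    of the standard region-based point/triangle projection.
    """
    return trimesh.triangles.closest_point(triangles, points)


class MeshDistance:
    """Repeated exact closest-point queries against one triangle mesh."""

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        self.triangles = mesh.triangles.view(np.ndarray)
        self.centroids = self.triangles.mean(axis=1)
        # circumscribed bound: max distance from centroid to a triangle vertex
        self._tri_radius = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self._max_tri_radius = float(self._tri_radius.max())
        self._tree = cKDTree(self.centroids)

    def query(
        self, points: np.ndarray, k: int = 12
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest points, distances, triangle ids).

        Exact: after a k-NN candidate pass, any triangle whose centroid
        ball could still beat the best candidate distance is re-checked.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        k = min(k, len(self.centroids))
        _, cand = self._tree.query(pts, k=k)
        cand = np.atleast_2d(cand)
        flat_tris = self.triangles[cand.ravel()]
        flat_pts = np.repeat(pts, k, axis=0)
        proj = point_triangle_closest(flat_pts, flat_tris)
        d = np.linalg.norm(proj - flat_pts, axis=1).reshape(n, k)
        best = d.argmin(axis=1)
        best_dist = d[np.arange(n), best]
        best_tri = cand[np.arange(n), best]
        best_pt = proj.reshape(n, k, 3)[np.arange(n), best]

        # verification pass: triangles whose centroid is within
        # best_dist + tri_radius may contain a closer point
        radius = best_dist + self._max_tri_radius + 1e-12
        extra = self._tree.query_ball_point(pts, r=radius)
        for i, tri_ids in enumerate(extra):
            tri_ids = np.asarray(tri_ids)
            if len(tri_ids) <= k:
                continue
            proj_i = point_triangle_closest(
                np.repeat(pts[i : i + 1], len(tri_ids), axis=0),
                self.triangles[tri_ids],
            )
            d_i = np.linalg.norm(proj_i - pts[i], axis=1)
            j = d_i.argmin()
            if d_i[j] < best_dist[i]:
                best_dist[i] = d_i[j]
                best_tri[i] = tri_ids[j]
                best_pt[i] = proj_i[j]
        return best_pt, best_dist, best_tri

    def barycentric(self, points: np.ndarray, tri_ids: np.ndarray) -> np.ndarray:
        """Barycentric coordinates of on-triangle points, clipped to the simplex."""
        bary = trimesh.triangles.points_to_barycentric(
            self.triangles[tri_ids], np.atleast_2d(points)
        )
        bary = np.clip(bary, 0.0, 1.0)
        return bary / bary.sum(axis=1, keepdims=True)


def closest_point_on_mesh(
    mesh: trimesh.Trimesh, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-shot exact closest point on mesh: (points, distances, triangle ids)."""
    return MeshDistance(mesh).query(points)


def edge_graph(
    mesh: trimesh.Trimesh, weights: np.ndarray | None = None
) -> sparse.csr_matrix:
    """Sparse symmetric vertex-adjacency graph weighted by edge length (or given)."""
    edges = mesh.edges_unique
    w = mesh.edges_unique_length if weights is None else np.asarray(weights, float)
    n = len(mesh.vertices)
    g = sparse.coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([edges[:, 0], edges[:, 1]]),
                                  np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    )
    return g.tocsr()


def geodesic_distances(
    graph: sparse.csr_matrix,
    sources: np.ndarray,
    limit: float = np.inf,
) -> np.ndarray:
    """Multi-source graph-geodesic distance to every vertex (inf beyond limit)."""
    d = dijkstra(graph, directed=False, indices=np.asarray(sources), limit=limit,
                 min_only=True)
    return d


def shortest_path(
    graph: sparse.csr_matrix, source: int, target: int
) -> tuple[list[int], float]:
    """Least-cost vertex path between two vertices of the edge graph."""
    dist, pred = dijkstra(
        graph, directed=False, indices=source, return_predecessors=True
    )
    if not np.isfinite(dist[target]):
        raise ValueError("vertices lie on different mesh components")
    path = [target]
    while path[-1] != source:
        path.append(int(pred[path[-1]]))
    return path[::-1], float(dist[target])


def polyline_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two sampled point sets."""
    ta, tb = cKDTree(np.asarray(a, float)), cKDTree(np.asarray(b, float))
    d_ab = ta.query(np.asarray(b, float))[0].max()
    d_ba = tb.query(np.asarray(a, float))[0].max()
    return float(max(d_ab, d_ba))


def mesh_contour(
    mesh: trimesh.Trimesh, scalar_fn, level: float = 0.0
) -> list[np.ndarray]:
    """Zero-level-set polylines of an implicit function sampled on a mesh.

    Interpolates crossings of ``scalar_fn(vertices) - level`` along mesh
    edges and links the per-face crossing segments into polylines.
    Returns a list of (n, 3) arrays (closed loops repeat the first point).
    """
    verts = mesh.vertices.view(np.ndarray)
    f = np.asarray(scalar_fn(verts), dtype=float) - level
    faces = mesh.faces
    segments = []
    for tri in faces:
        pts = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            fa, fb = f[a], f[b]
            if (fa < 0) != (fb < 0):
                t = fa / (fa - fb)
                pts.append((min(a, b), max(a, b), verts[a] + t * (verts[b] - verts[a])))
        if len(pts) == 2:
            segments.append(pts)
    if not segments:
        return []
    # link segments that share a crossed edge
    from collections import defaultdict

    edge_key = lambda e: (e[0], e[1])
    by_edge: dict[tuple[int, int], list[int]] = defaultdict(list)
    for i, seg in enumerate(segments):
        by_edge[edge_key(seg[0])].append(i)
        by_edge[edge_key(seg[1])].append(i)
    used = np.zeros(len(segments), dtype=bool)
    curves = []
    for start in range(len(segments)):
        if used[start]:
            continue
        used[start] = True
        chain = [segments[start][0], segments[start][1]]
        # extend forward then backward
        for end in (1, 0):
            while True:
                key = edge_key(chain[-1] if end == 1 else chain[0])
                nxt = [i for i in by_edge[key] if not used[i]]
                if not nxt:
                    break
                seg = segments[nxt[0]]
                used[nxt[0]] = True
                other = seg[1] if edge_key(seg[0]) == key else seg[0]
                if end == 1:
                    chain.append(other)
                else:
                    chain.insert(0, other)
        curves.append(np.asarray([c[2] for c in chain]))
    return curves
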
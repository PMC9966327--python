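"""Fracture-line detection on fragment surfaces.

Each fragment is meshed from its label map, high-curvature border
vertices (the sharp rim a fracture leaves in the smooth cortical
surface) are proposed as guide markers, and the fracture line is traced
as the least-cost closed path through the markers on the mesh edge
graph, with a cost favouring short edges that hug the high-curvature
ridge and lie on a crease.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from skimage.measure import marching_cubes

from . import _geometry
from .core import FractureLine, LabelMap


def mesh_fragment(
    labels: LabelMap, label: int, iso: float = 0.5, smooth_sigma: float = 0.0
) -> trimesh.Trimesh:
    """Iso-surface of one fragment's indicator, in world mm coordinates.

    ``smooth_sigma`` (voxels) optionally smooths the binary indicator
    before extraction to suppress voxelization staircases — useful
    before curvature analysis; 0 gives the raw binary iso-surface.
    """
    if label not in labels.ids:
        raise ValueError(f"label {label} not present in map")
    indicator = (labels.labels == label).astype(np.float32)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        smoothed = gaussian_filter(indicator, sigma=smooth_sigma)
        # tiny fragments can be smoothed below the iso level entirely
        if smoothed.max() > iso:
            indicator = smoothed
    verts, faces, _, _ = marching_cubes(indicator, level=iso, spacing=labels.spacing)
    verts = verts + np.asarray(labels.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # orient outward
        mesh.invert()
    return mesh


def outer_vertex_mask(
    mesh: trimesh.Trimesh, full_mask: np.ndarray, spacing, origin, dilate: int = 2
) -> np.ndarray:
    """Flag mesh vertices on the outer cortical surface of the whole bone.

    Exterior air is the background component touching the grid border
    (the trabecular cavity is a separate component); vertices within the
    dilated exterior are "outer".  Used to keep traced fracture lines on
    the outer rim rather than the inner cortical wall.
    """
    from scipy import ndimage

    # seal thin fracture clefts so exterior air cannot leak into the
    # medullary cavity through the cut
    closed = ndimage.binary_closing(
        np.asarray(full_mask, bool), structure=np.ones((3, 3, 3), bool), iterations=1
    )
    bg, _ = ndimage.label(~closed)
    border_labels = np.unique(
        np.concatenate([
            bg[0].ravel(), bg[-1].ravel(), bg[:, 0].ravel(), bg[:, -1].ravel(),
            bg[:, :, 0].ravel(), bg[:, :, -1].ravel(),
        ])
    )
    exterior = np.isin(bg, border_labels[border_labels > 0])
    if dilate > 0:
        exterior = ndimage.binary_dilation(exterior, iterations=dilate)
    idx = (mesh.vertices.view(np.ndarray) - np.asarray(origin)) / np.asarray(spacing)
    sampled = ndimage.map_coordinates(
        exterior.astype(np.uint8), idx.T, order=0, mode="nearest"
    )
    return sampled.astype(bool)


def vertex_curvature(mesh: trimesh.Trimesh, signed: bool = False) -> np.ndarray:
    """Discrete mean curvature per vertex (1/mm).

    Cotangent-Laplacian mean-curvature normal with barycentric vertex
    areas; |H| = |Δx| / 2.  With ``signed=True`` the sign follows the
    vertex normals: positive on convex regions (ridges), negative in
    concave ones (valleys).  Vertices with degenerate area get the
    value of their nearest well-defined neighbour.
    """
    if len(mesh.vertices) < 4:
        raise ValueError("mesh must have at least 4 vertices")
    V = mesh.vertices.view(np.ndarray)
    F = mesh.faces
    n = len(V)

    # cotangents of the three angles of every face
    rows, cols, vals = [], [], []
    area = np.zeros(n)
    tri_area = mesh.area_faces
    for k in range(3):
        i = F[:, k]
        j = F[:, (k + 1) % 3]
        o = F[:, (k + 2) % 3]  # vertex opposite edge (i, j)
        u = V[i] - V[o]
        v = V[j] - V[o]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cross = np.maximum(cross, 1e-12)
        cot = (u * v).sum(axis=1) / cross
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([cot, cot])
        np.add.at(area, i, tri_area / 3.0)
    W = sparse.coo_matrix(
        (np.concatenate(vals) * 0.5,
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    diag = np.asarray(W.sum(axis=1)).ravel()
    L = sparse.diags(diag) - W
    delta = L @ V  # (n, 3) mean-curvature normal * area
    good = area > 1e-12
    H = np.zeros(n)
    H[good] = 0.5 * np.linalg.norm(delta[good], axis=1) / area[good]
    if signed:
        normals = mesh.vertex_normals.view(np.ndarray)
        sign = np.sign((delta * normals).sum(axis=1))
        H = H * sign
    # boundary vertices of open meshes have no well-defined cotangent
    # curvature: give them the nearest interior value
    boundary = np.zeros(n, dtype=bool)
    edges = mesh.edges_sorted
    unique_edges, counts = np.unique(edges, axis=0, return_counts=True)
    open_edges = unique_edges[counts == 1]
    if len(open_edges):
        boundary[np.unique(open_edges)] = True
    bad = boundary | ~good
    if bad.any() and not bad.all():
        from scipy.spatial import cKDTree

        tree = cKDTree(V[~bad])
        _, nearest = tree.query(V[bad])
        H[bad] = H[~bad][nearest]
    return H


def propose_guide_markers(
    mesh: trimesh.Trimesh,
    curvature: np.ndarray,
    quantile: float = 0.90,
    floor: float = 0.25,
    suppression_radius: float | None = None,
) -> list[int]:
    """High-curvature vertices thinned by geodesic non-maximum suppression.

    Candidates must exceed both the cohort ``quantile`` of the curvature
    distribution and the absolute ``floor`` (1/mm), so uniformly smooth
    surfaces yield no markers.  Returned sorted by descending curvature.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    H = np.asarray(curvature, float)
    threshold = max(float(np.quantile(H, quantile)), floor)
    cand = np.flatnonzero(H > threshold)
    if len(cand) == 0:
        return []
    if suppression_radius is None:
        suppression_radius = 2.0 * float(mesh.edges_unique_length.mean())
    graph = _geometry.edge_graph(mesh)
    order = cand[np.argsort(-H[cand])]
    suppressed = np.zeros(len(H), dtype=bool)
    markers: list[int] = []
    for v in order:
        if suppressed[v]:
            continue
        markers.append(int(v))
        d = dijkstra(graph, directed=False, indices=v, limit=suppression_radius,
                     min_only=False)
        suppressed[np.isfinite(d)] = True
    return markers


def _edge_costs(
    mesh: trimesh.Trimesh,
    ridge_vertices: np.ndarray,
    w_boundary: float,
    w_angle: float,
) -> np.ndarray:
    """Per-unique-edge traversal cost.

    cost = length * (1 + w_boundary * mean geodesic distance of the edge
    endpoints to the high-curvature ridge (normalized by mean edge
    length, capped at 4 — beyond a few edge lengths the distance
    carries no extra information and an unbounded term would make short
    ridge-free stretches costlier than detouring around the whole
    fragment) + w_angle * deviation of the edge's dihedral from a
    crease).
    """
    lengths = mesh.edges_unique_length
    cost = lengths.copy()
    scale = float(lengths.mean())
    extra = np.zeros(len(lengths))
    if w_boundary > 0 and len(ridge_vertices):
        graph = _geometry.edge_graph(mesh)
        d = _geometry.geodesic_distances(graph, ridge_vertices)
        d = np.where(np.isfinite(d), d, d[np.isfinite(d)].max() if np.isfinite(d).any() else 0.0)
        edges = mesh.edges_unique
        norm = (d[edges[:, 0]] + d[edges[:, 1]]) / (2.0 * scale)
        extra += w_boundary * np.minimum(norm, 4.0)
    if w_angle > 0:
        # dihedral deviation from a crease: 1 on flat edges, 0 at >= 90 deg
        angle = np.zeros(len(lengths))
        adj_edges = mesh.face_adjacency_edges
        adj_angles = mesh.face_adjacency_angles  # angle between face normals
        # map adjacency edges onto unique-edge ids
        order = np.sort(adj_edges, axis=1)
        unique = np.sort(mesh.edges_unique, axis=1)
        lookup = {tuple(e): i for i, e in enumerate(unique)}
        for e, a in zip(order, adj_angles):
            angle[lookup[tuple(e)]] = a
        deviation = np.clip(1.0 - angle / (np.pi / 2.0), 0.0, 1.0)
        extra += w_angle * deviation
    return cost * (1.0 + extra)


def _order_markers(graph: sparse.csr_matrix, markers: list[int]) -> list[int]:
    """Cyclic marker order: best of several nearest-neighbour tours over
    pairwise geodesic cost, each refined by 2-opt to a local optimum."""
    k = len(markers)
    if k <= 2:
        return list(markers)
    D = dijkstra(graph, directed=False, indices=markers)[:, markers]
    # symmetrize against tiny numerical asymmetries
    D = 0.5 * (D + D.T)

    def nn_tour(start: int) -> list[int]:
        tour = [start]
        left = set(range(k)) - {start}
        while left:
            cur = tour[-1]
            nxt = min(left, key=lambda j: (D[cur, j], j))
            tour.append(nxt)
            left.remove(nxt)
        return tour

    def two_opt(tour: list[int]) -> tuple[list[int], float]:
        tour = list(tour)
        improved = True
        while improved:
            improved = False
            for i in range(k - 1):
                a, b = tour[i], tour[(i + 1) % k]
                for j in range(i + 2, k):
                    if i == 0 and j == k - 1:
                        continue
                    c, d = tour[j], tour[(j + 1) % k]
                    delta = D[a, c] + D[b, d] - D[a, b] - D[c, d]
                    if delta < -1e-12:
                        tour[i + 1 : j + 1] = tour[i + 1 : j + 1][::-1]
                        improved = True
                        a, b = tour[i], tour[(i + 1) % k]
        length = sum(D[tour[i], tour[(i + 1) % k]] for i in range(k))
        return tour, length

    starts = list(range(0, k, max(k // 5, 1)))[:5]
    best, best_len = None, np.inf
    for s in starts:
        tour, length = two_opt(nn_tour(s))
        if length < best_len:
            best, best_len = tour, length
    return [markers[i] for i in best]


def trace_fracture_line(
    mesh: trimesh.Trimesh,
    markers: list[int],
    weights: tuple[float, float] = (1.0, 1.0),
    ridge_vertices: np.ndarray | None = None,
    close_gap: float | None = None,
    close_fraction: float = 0.0,
) -> FractureLine:
    """Trace the fracture line through guide markers as a least-cost path.

    Markers are ordered by a geodesic nearest-neighbour tour (2-opt
    refined), consecutive markers are joined by least-cost paths on the
    weighted edge graph, and the loop is closed when the tour's ends lie
    within ``close_gap`` (default 3x mean edge length) geodesically.
    ``close_fraction`` optionally widens the closing threshold to that
    fraction of the open path's length — border loops around a fragment
    stay loops even where marker thinning leaves a larger gap.
    """
    if len(markers) < 2:
        raise ValueError("at least 2 markers are required")
    n = len(mesh.vertices)
    if any(m < 0 or m >= n for m in markers):
        raise ValueError("markers must be mesh vertex ids")
    w_boundary, w_angle = weights
    if ridge_vertices is None:
        ridge_vertices = np.asarray(markers)
    costs = _edge_costs(mesh, np.asarray(ridge_vertices), w_boundary, w_angle)
    graph = _geometry.edge_graph(mesh, weights=costs)
    plain = _geometry.edge_graph(mesh)

    d0 = dijkstra(plain, directed=False, indices=markers[0])
    if not all(np.isfinite(d0[m]) for m in markers):
        raise ValueError("markers lie on different mesh components")

    ordered = _order_markers(graph, list(dict.fromkeys(markers)))
    path: list[int] = [ordered[0]]
    for a, b in zip(ordered[:-1], ordered[1:]):
        seg, _ = _geometry.shortest_path(graph, a, b)
        path.extend(seg[1:])

    if close_gap is None:
        close_gap = 3.0 * float(mesh.edges_unique_length.mean())
    if close_fraction > 0:
        open_len = float(
            np.linalg.norm(np.diff(mesh.vertices.view(np.ndarray)[path], axis=0),
                           axis=1).sum()
        )
        close_gap = max(close_gap, close_fraction * open_len)
    closed = False
    end_gap = dijkstra(plain, directed=False, indices=path[-1], limit=close_gap * 1.001,
                       min_only=False)[path[0]]
    if len(ordered) > 2 and np.isfinite(end_gap) and end_gap <= close_gap:
        seg, _ = _geometry.shortest_path(graph, path[-1], path[0])
        path.extend(seg[1:-1])
        closed = True

    # collapse consecutive duplicates
    pts = mesh.vertices.view(np.ndarray)[path]
    keep = np.concatenate([[True], np.any(np.diff(pts, axis=0) != 0, axis=1)])
    return FractureLine(points=pts[keep], closed=closed)


def bone_outer_surface(
    labels: LabelMap, smooth_sigma: float = 1.0, seal_iterations: int = 2
) -> trimesh.Trimesh:
    """Sealed outer surface of the whole fractured bone.

    Morphological closing bridges thin fracture clefts so the surface
    approximates the intact outer cortex; used as the normal field for
    intensity-valley line refinement.
    """
    from scipy.ndimage import binary_closing, gaussian_filter

    full = labels.labels > 0
    closed = binary_closing(full, structure=np.ones((3, 3, 3), bool),
                            iterations=seal_iterations)
    ind = closed.astype(np.float32)
    if smooth_sigma > 0:
        ind = gaussian_filter(ind, smooth_sigma)
    verts, faces, _, _ = marching_cubes(ind, 0.5, spacing=labels.spacing)
    mesh = trimesh.Trimesh(vertices=verts + np.asarray(labels.origin), faces=faces,
                           process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def refine_line_to_valley(
    line: FractureLine,
    outer_surface: trimesh.Trimesh,
    volume,
    depth: float = 0.6,
    half_window: float = 2.0,
    n_samples: int = 41,
    rel_threshold: float = 0.8,
    max_shift: float = 1.5,
) -> FractureLine:
    """Re-center line points on the radiolucent cleft valley.

    For every point, intensities are sampled along the surface binormal
    (perpendicular to the line, tangent to the outer surface, submerged
    ``depth`` mm below it).  The point moves to the center of the
    intensity valley (samples below ``rel_threshold`` x the profile
    maximum) nearest its current position; valleys touching the window
    edge (background air) and shifts beyond ``max_shift`` are ignored.
    This corrects the half-cleft bias of border tracing using the image
    itself, independent of which side the segmentation barrier took.
    """
    from scipy.ndimage import map_coordinates

    from ._geometry import MeshDistance

    md = MeshDistance(outer_surface)
    pts = line.points.copy()
    _, _, tri = md.query(pts)
    normals = outer_surface.face_normals.view(np.ndarray)[tri]
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    values = volume.values.astype(np.float32)
    n = len(pts)
    out = pts.copy()
    s = np.linspace(-half_window, half_window, n_samples)
    for i in range(n):
        prev_i = (i - 1) % n if line.closed else max(i - 1, 0)
        next_i = (i + 1) % n if line.closed else min(i + 1, n - 1)
        t = pts[next_i] - pts[prev_i]
        nt = np.linalg.norm(t)
        if nt < 1e-9:
            continue
        t = t / nt
        nrm = normals[i]
        u = np.cross(nrm, t)
        nu = np.linalg.norm(u)
        if nu < 1e-6:
            continue
        u = u / nu
        p_in = pts[i] - depth * nrm
        samples = p_in[None] + s[:, None] * u[None]
        vals = map_coordinates(values, ((samples - origin) / spacing).T,
                               order=1, mode="nearest")
        hi = vals.max()
        if hi <= 0:
            continue
        valley = vals <= rel_threshold * hi
        runs: list[tuple[int, int]] = []
        j = 0
        while j < n_samples:
            if valley[j]:
                k = j
                while k < n_samples and valley[k]:
                    k += 1
                runs.append((j, k - 1))
                j = k
            else:
                j += 1
        interior = [(a, b) for a, b in runs if a > 0 and b < n_samples - 1]
        if not interior:
            continue
        centers = [0.5 * (s[a] + s[b]) for a, b in interior]
        c = min(centers, key=abs)
        if abs(c) > max_shift:
            continue
        out[i] = pts[i] + c * u
    keep = np.concatenate([[True], np.any(np.diff(out, axis=0) != 0, axis=1)])
    return FractureLine(points=out[keep], closed=line.closed, fragment=line.fragment)


def smooth_polyline(
    line: FractureLine, iterations: int = 8, lam: float = 0.6
) -> FractureLine:
    """Laplacian smoothing of a polyline (endpoints fixed when open)."""
    p = line.points.copy()
    for _ in range(iterations):
        if line.closed:
            prev = np.roll(p, 1, axis=0)
            nxt = np.roll(p, -1, axis=0)
            p = p + lam * (0.5 * (prev + nxt) - p)
        else:
            q = p.copy()
            q[1:-1] = p[1:-1] + lam * (0.5 * (p[:-2] + p[2:]) - p[1:-1])
            p = q
    keep = np.concatenate([[True], np.any(np.diff(p, axis=0) != 0, axis=1)])
    return FractureLine(points=p[keep], closed=line.closed, fragment=line.fragment)


def refine_line_to_cleft(
    line: FractureLine, opposing: trimesh.Trimesh, max_gap: float = 3.0
) -> FractureLine:
    """Move each line point to the middle of the fracture cleft.

    A traced border runs along its own fragment's edge, half a cleft
    width away from the true fracture plane; the midpoint between each
    point and its closest point on the opposing fragment(s) recovers
    the mid-cleft position.  Points farther than ``max_gap`` from the
    opposing surface (e.g. along comminution voids) are left in place.
    """
    from ._geometry import MeshDistance

    q, d, _ = MeshDistance(opposing).query(line.points)
    pts = line.points.copy()
    near = d <= max_gap
    pts[near] = 0.5 * (pts[near] + q[near])
    keep = np.concatenate([[True], np.any(np.diff(pts, axis=0) != 0, axis=1)])
    return FractureLine(points=pts[keep], closed=line.closed, fragment=line.fragment)
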
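"""Surface meshing and mesh-based area/volume estimators.

``triangulate_surface`` is a greedy projection-style reconstruction: each
point's neighbourhood (within a radius capped by ``mu`` times the local
point spacing) is projected onto the point's tangent plane and its 2D
Delaunay star proposes candidate triangles; candidates are then accepted
greedily by descending (vote count, shape quality) under a directed-edge
exclusivity rule that guarantees an edge-manifold, consistently wound mesh.
The local 2D triangulations are *regular* triangulations with tiny symbolic
weights derived from global point indices, so co-circular neighbourhoods
(e.g. regular grids) are broken identically in every local star.

``surface_area`` is the Heron sum over faces: S0 = sum_i sqrt(p(p-a)(p-b)(p-c)).

``volume_prism`` approximates the volume of a closed mesh by central-plane
projection: each face contributes its projected area on the plane z = 0
through the centroid times the absolute height of its own centroid,
V = sum_faces S_proj * |h0|. Exact for prisms; for smooth closed surfaces
that are graphs above and below the central plane it converges to the true
volume. ``volume_divergence`` (signed tetrahedra, divergence theorem) is the
independent exact estimator kept for cross-checks.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree

from .cloud import PointCloud

__all__ = [
    "TriangleMesh",
    "MeshTopologyError",
    "triangulate_surface",
    "fill_holes",
    "surface_area",
    "volume_prism",
    "volume_divergence",
]


class MeshTopologyError(RuntimeError):
    """Mesh topology violates what the operation needs (open / non-manifold)."""


@dataclass
class TriangleMesh:
    """Triangle mesh: (V, 3) vertices in mm and (F, 3) vertex indices.

    Faces are consistently wound where the construction permits; every edge
    is incident to at most two faces.
    """

    vertices: np.ndarray
    faces: np.ndarray
    sliver_count: int = 0   # Heron radicands clamped to zero, see surface_area

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size:
            if self.faces.max() >= len(self.vertices) or self.faces.min() < 0:
                raise ValueError("face index out of range")
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise ValueError("degenerate face with a repeated vertex")

    # -- topology ------------------------------------------------------

    def edge_face_count(self) -> Dict[Tuple[int, int], int]:
        counts: Dict[Tuple[int, int], int] = defaultdict(int)
        for a, b, c in self.faces:
            for e in ((a, b), (b, c), (c, a)):
                counts[(min(e), max(e))] += 1
        return counts

    def boundary_edges(self) -> List[Tuple[int, int]]:
        """Directed boundary edges, oriented as they appear in their single
        incident face (so loops run consistently with the face winding)."""
        undirected = self.edge_face_count()
        out = []
        for a, b, c in self.faces:
            for e in ((a, b), (b, c), (c, a)):
                if undirected[(min(e), max(e))] == 1:
                    out.append(e)
        return out

    def boundary_loops(self) -> List[List[int]]:
        """Simple closed vertex cycles decomposing the boundary.

        In an edge-manifold mesh the directed boundary edges balance at every
        vertex, so they decompose into cycles; walks that revisit a vertex
        are split there, which keeps every returned loop simple (no repeated
        vertices) — a requirement for centroid-fan hole filling.
        """
        edges = self.boundary_edges()
        succ: Dict[int, List[int]] = defaultdict(list)
        for a, b in edges:
            succ[a].append(b)
        used = set()
        loops: List[List[int]] = []
        for start in edges:
            if start in used:
                continue
            used.add(start)
            path = [start[0], start[1]]
            pos = {start[0]: 0, start[1]: 1}
            while True:
                cur = path[-1]
                nxts = [v for v in succ[cur] if (cur, v) not in used]
                if not nxts:
                    break  # unbalanced vertex (non-manifold input): drop remainder
                nxt = nxts[0]
                used.add((cur, nxt))
                if nxt in pos:
                    i = pos[nxt]
                    loops.append(path[i:])
                    for v in path[i + 1:]:
                        pos.pop(v, None)
                    path = path[: i + 1]
                    if len(path) == 1 and not [v for v in succ[path[0]]
                                               if (path[0], v) not in used]:
                        break
                else:
                    pos[nxt] = len(path)
                    path.append(nxt)
        return loops

    @property
    def is_closed(self) -> bool:
        return all(c == 2 for c in self.edge_face_count().values())

    @property
    def is_edge_manifold(self) -> bool:
        return all(c <= 2 for c in self.edge_face_count().values())

    def euler_characteristic(self) -> int:
        used = np.unique(self.faces)
        V = len(used)
        E = len(self.edge_face_count())
        F = len(self.faces)
        return V - E + F


# ------------------------------------------------------------------ helpers

def _tangent_basis(normal: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    return u, np.cross(normal, u)


def _regular_star(q2d: np.ndarray, weights: np.ndarray) -> List[Tuple[int, int, int]]:
    """Triangles of the weighted (regular) Delaunay triangulation incident to
    local point 0, via the lower convex hull of the lifted points
    (x, y, x^2 + y^2 - w)."""
    lifted = np.column_stack([q2d, (q2d ** 2).sum(axis=1) - weights])
    try:
        hull = ConvexHull(lifted, qhull_options="Qt")
    except QhullError:
        try:
            tri = Delaunay(q2d)
        except QhullError:
            return []
        return [tuple(s) for s in tri.simplices if 0 in s]
    out = []
    for simplex, eq in zip(hull.simplices, hull.equations):
        if eq[2] < -1e-12 and 0 in simplex:  # lower hull only
            out.append(tuple(simplex))
    return out


def triangulate_surface(cloud: PointCloud, radius_mm: Optional[float] = None,
                        mu: float = 2.5, max_angle_deg: float = 120.0) -> TriangleMesh:
    """Greedy projection-style triangulation of an oriented point cloud.

    Parameters
    ----------
    cloud : point cloud with unit normals (run ``estimate_normals`` first)
    radius_mm : absolute cap on the connection radius; default 4x the median
        nearest-neighbour spacing
    mu : multiplier of the median point spacing that bounds edge length
    max_angle_deg : neighbours whose normals deviate more than this from the
        centre point's normal are not connected (guards occluding boundaries)
    """
    if cloud.normals is None:
        raise ValueError("triangulate_surface requires normals")
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points to triangulate")
    normals = cloud.normals
    tree = cKDTree(pts)
    d1 = tree.query(pts, k=2, workers=-1)[0][:, 1]
    s_med = float(np.median(d1))
    if s_med == 0:
        raise ValueError("duplicate points: voxel-downsample before meshing")
    r_eff = min(radius_mm if radius_mm is not None else 4.0 * s_med, mu * s_med)
    r_eff = max(r_eff, 1.05 * d1.max())  # keep the graph connected on uniform samples
    cos_max = np.cos(np.deg2rad(max_angle_deg))
    eps0 = 1e-7 * s_med ** 2
    neighbor_lists = tree.query_ball_point(pts, r_eff, workers=-1)

    votes: Dict[Tuple[int, int, int], int] = defaultdict(int)
    oriented: Dict[Tuple[int, int, int], Tuple[int, int, int]] = {}
    for i in range(n):
        nbrs = [j for j in neighbor_lists[i] if j != i]
        if len(nbrs) < 2:
            continue
        ni = normals[i]
        nbrs = [j for j in nbrs if ni @ normals[j] >= cos_max]
        if len(nbrs) < 2:
            continue
        u, v = _tangent_basis(ni)
        rel = pts[nbrs] - pts[i]
        q = np.vstack([[0.0, 0.0], np.column_stack([rel @ u, rel @ v])])
        ids = np.array([i] + nbrs)
        w = eps0 * (ids / n)
        for simplex in _regular_star(q, w):
            tri_local = [int(s) for s in simplex]
            ga, gb, gc = (int(ids[t]) for t in tri_local)
            key = tuple(sorted((ga, gb, gc)))
            votes[key] += 1
            if key not in oriented:
                # orient CCW about the centre normal
                a, b, c = key
                if np.cross(pts[b] - pts[a], pts[c] - pts[a]) @ ni < 0:
                    oriented[key] = (a, c, b)
                else:
                    oriented[key] = (a, b, c)

    if not votes:
        raise MeshTopologyError("triangulation produced no candidate faces")
    faces = _greedy_manifold_extraction(pts, votes, oriented)
    if not faces:
        raise MeshTopologyError("triangulation produced no consistent faces")
    mesh = TriangleMesh(vertices=pts.copy(), faces=np.asarray(faces, dtype=np.int64))
    return _patch_small_holes(mesh)


def _patch_small_holes(mesh: TriangleMesh, passes: int = 3) -> TriangleMesh:
    """Close small boundary loops left by rejected candidate faces (the
    usual final step of an advancing-front mesher). No new vertices: each
    loop is fanned from one of its own vertices, subject to the same
    manifold and winding guards as the main extraction. Large openings
    (e.g. a stage-contact cut) are left for ``fill_holes``."""
    max_patch_loop = 12
    for _ in range(passes):
        loops = [lp for lp in mesh.boundary_loops() if 3 <= len(lp) <= max_patch_loop]
        if not loops:
            break
        undirected = mesh.edge_face_count()
        directed = set()
        for fa, fb, fc in mesh.faces:
            directed.update(((fa, fb), (fb, fc), (fc, fa)))
        new_faces = list(map(tuple, mesh.faces))
        added = False
        v = mesh.vertices
        for lp in loops:
            # fan anchored at a loop vertex; prefer the anchor with the
            # shortest longest new edge, fall back to the others if blocked
            spans = [max(np.linalg.norm(v[lp[ai]] - v[w]) for w in lp)
                     for ai in range(len(lp))]
            for ai in np.argsort(spans):
                anchor = lp[int(ai)]
                cand = [
                    (b, a, anchor)
                    for a, b in zip(lp, lp[1:] + lp[:1])
                    if anchor not in (a, b)
                ]
                cand_edges = [(x, y) for tri in cand
                              for x, y in ((tri[0], tri[1]), (tri[1], tri[2]),
                                           (tri[2], tri[0]))]
                if any(e in directed for e in cand_edges):
                    continue
                counts: Dict[Tuple[int, int], int] = defaultdict(int)
                for x, y in cand_edges:
                    counts[(min(x, y), max(x, y))] += 1
                if any(undirected.get(e, 0) + cnt > 2 for e, cnt in counts.items()):
                    continue
                for e in cand_edges:
                    directed.add(e)
                for e, cnt in counts.items():
                    undirected[e] = undirected.get(e, 0) + cnt
                new_faces.extend(cand)
                added = True
                break
        if not added:
            break
        mesh = TriangleMesh(vertices=mesh.vertices, faces=np.asarray(new_faces),
                            sliver_count=mesh.sliver_count)
    return mesh


def _face_quality(pts: np.ndarray, face) -> float:
    a, b, c = face
    ab, ac, bc = pts[b] - pts[a], pts[c] - pts[a], pts[c] - pts[b]
    area2 = np.linalg.norm(np.cross(ab, ac))
    denom = (ab @ ab) + (ac @ ac) + (bc @ bc)
    return float(area2 / denom) if denom > 0 else 0.0  # ~ inradius/circumradius proxy


def _greedy_manifold_extraction(pts: np.ndarray,
                                votes: Dict[Tuple[int, int, int], int],
                                oriented: Dict[Tuple[int, int, int], Tuple[int, int, int]]
                                ) -> List[Tuple[int, int, int]]:
    """Assemble a manifold, consistently wound mesh from the voted candidate
    faces.

    Candidates are visited by descending (vote count, shape quality); a face
    is accepted only if none of its three *directed* edges is already in use
    and no undirected edge would gain a third face. Because every candidate
    is wound counter-clockwise about the outward point normal, directed-edge
    exclusivity simultaneously enforces edge-manifoldness, rejects the
    crossing-diagonal double covers that co-circular neighbourhoods produce,
    and yields a consistent outward winding without a separate propagation
    pass.
    """
    order = sorted(
        votes,
        key=lambda key: (-votes[key], -_face_quality(pts, key), key),
    )
    used_directed = set()
    undirected_count: Dict[Tuple[int, int], int] = defaultdict(int)
    out: List[Tuple[int, int, int]] = []
    for key in order:
        a, b, c = oriented[key]
        directed = ((a, b), (b, c), (c, a))
        if any(e in used_directed for e in directed):
            continue
        if any(undirected_count[(min(e), max(e))] >= 2 for e in directed):
            continue
        for e in directed:
            used_directed.add(e)
            undirected_count[(min(e), max(e))] += 1
        out.append((a, b, c))
    return out


def fill_holes(mesh: TriangleMesh, max_loop_edges: int = 200) -> TriangleMesh:
    """Close boundary loops by fanning each loop to its centroid (one new
    vertex per loop). Loops longer than ``max_loop_edges`` warn but are
    fanned anyway. A closed mesh is returned unchanged."""
    if not mesh.is_edge_manifold:
        raise MeshTopologyError("non-manifold edge (more than two incident faces)")
    loops = mesh.boundary_loops()
    if not loops:
        return mesh
    vertices = [mesh.vertices]
    new_faces = list(map(tuple, mesh.faces))
    next_vid = len(mesh.vertices)
    for loop in loops:
        if len(loop) < 3:
            continue
        if len(loop) > max_loop_edges:
            warnings.warn(
                f"fill_holes: fanning a large boundary loop ({len(loop)} edges)",
                stacklevel=2,
            )
        centroid = mesh.vertices[loop].mean(axis=0)
        vertices.append(centroid[None, :])
        # boundary edges run with the face winding; the fan must run against it
        for a, b in zip(loop, loop[1:] + loop[:1]):
            new_faces.append((b, a, next_vid))
        next_vid += 1
    return TriangleMesh(vertices=np.vstack(vertices), faces=np.asarray(new_faces),
                        sliver_count=mesh.sliver_count)


def surface_area(mesh: TriangleMesh, return_sliver_count: bool = False):
    """Heron-sum surface area over all faces (mm^2).

    Each face contributes sqrt(p (p-a) (p-b) (p-c)) with p the half
    perimeter. Numerically negative radicands (degenerate slivers) clamp to
    zero and are tallied; the tally is also stored on ``mesh.sliver_count``.
    """
    v = mesh.vertices
    f = mesh.faces
    if len(f) == 0:
        return (0.0, 0) if return_sliver_count else 0.0
    a = np.linalg.norm(v[f[:, 1]] - v[f[:, 0]], axis=1)
    b = np.linalg.norm(v[f[:, 2]] - v[f[:, 1]], axis=1)
    c = np.linalg.norm(v[f[:, 0]] - v[f[:, 2]], axis=1)
    p = (a + b + c) / 2
    radicand = p * (p - a) * (p - b) * (p - c)
    slivers = int(np.count_nonzero(radicand < 0))
    total = float(np.sqrt(np.clip(radicand, 0.0, None)).sum())
    mesh.sliver_count = slivers
    if return_sliver_count:
        return total, slivers
    return total


def volume_prism(mesh: TriangleMesh) -> float:
    """Central-plane prism-projection volume (mm^3).

    Requires a closed mesh whose vertices are expressed in the grain's
    oriented-box frame (z = thickness axis). The central plane is z = 0
    through the vertex centroid; each face contributes the area of its
    projection onto that plane times the absolute z of its centroid.
    """
    if not mesh.is_closed:
        raise MeshTopologyError("mesh is open: run fill_holes first")
    v = mesh.vertices
    f = mesh.faces
    z0 = v[:, 2].mean()
    pa, pb, pc = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    proj_area = 0.5 * np.abs(
        (pb[:, 0] - pa[:, 0]) * (pc[:, 1] - pa[:, 1])
        - (pc[:, 0] - pa[:, 0]) * (pb[:, 1] - pa[:, 1])
    )
    h0 = np.abs((pa[:, 2] + pb[:, 2] + pc[:, 2]) / 3 - z0)
    return float((proj_area * h0).sum())


def volume_divergence(mesh: TriangleMesh) -> float:
    """Divergence-theorem volume: (1/6) |sum of signed tetrahedra to the
    origin| over a closed, consistently oriented mesh (mm^3)."""
    if not mesh.is_closed:
        raise MeshTopologyError("mesh is open: run fill_holes first")
    v = mesh.vertices
    f = mesh.faces
    det = np.einsum(
        "ij,ij->i",
        v[f[:, 0]],
        np.cross(v[f[:, 1]], v[f[:, 2]]),
    )
    return float(abs(det.sum()) / 6.0)
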
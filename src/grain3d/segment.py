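"""Scene segmentation: stage-plane fit (RANSAC) and single-grain extraction
(region growing on normals and curvature).

The scene model is a single dominant plane (the sample stage) with grains
standing strictly above it, separated by the placement spacing. Plane
removal therefore does most of the separation work; region growing splits
the remaining points into smooth connected clusters and discards fragments
outside the configured size range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .synthetic import GridLayout

__all__ = [
    "PlaneModel",
    "GrainSegment",
    "estimate_normals",
    "fit_plane_ransac",
    "remove_plane",
    "region_growing",
    "assign_grid_cells",
    "PlaneFitError",
    "GridCollisionError",
]


class PlaneFitError(RuntimeError):
    """RANSAC found no plane hypothesis with enough inliers."""


class GridCollisionError(ValueError):
    """Two segments map to the same layout cell."""


@dataclass
class PlaneModel:
    """Plane ``{x : normal . x = offset}`` with the indices of the points
    within the fit distance threshold."""

    normal: np.ndarray
    offset_mm: float
    inlier_indices: np.ndarray
    dist_mm: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        nrm = np.linalg.norm(self.normal)
        if abs(nrm - 1) > 1e-9:
            self.normal = self.normal / nrm
        self.inlier_indices = np.asarray(self.inlier_indices, dtype=np.intp)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.normal - self.offset_mm


@dataclass
class GrainSegment:
    """One segmented grain: its cloud (indices into the parent cloud kept for
    bookkeeping) and, after grid assignment, its layout cell."""

    grain_id: int
    cloud: PointCloud
    indices: Optional[np.ndarray] = None
    grid_cell: Optional[Tuple[int, int]] = None

    def centroid(self) -> np.ndarray:
        return self.cloud.centroid()


def estimate_normals(cloud: PointCloud, k: int = 30) -> PointCloud:
    """Per-point normals and curvature from the k-NN covariance.

    The normal is the smallest-eigenvalue eigenvector; curvature is the
    surface-variation ratio lambda_0 / (lambda_0 + lambda_1 + lambda_2)
    (in [0, 1/3]). Normals are oriented away from the cloud centroid, which
    is the right convention for closed-ish single objects.
    """
    n = len(cloud)
    if k < 3:
        raise ValueError("k must be >= 3")
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    pts = cloud.points
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1, workers=-1)
    nbrs = pts[idx]                                   # (n, k+1, 3), includes self
    centred = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred) / (k + 1)
    evals, evecs = np.linalg.eigh(cov)                # ascending
    normals = evecs[:, :, 0]
    total = evals.sum(axis=1)
    curvature = np.where(total > 0, evals[:, 0] / np.where(total > 0, total, 1.0), 0.0)
    outward = pts - pts.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    normals[flip] = -normals[flip]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(points=pts, normals=normals, curvature=curvature,
                      frame_tag=cloud.frame_tag)


def fit_plane_ransac(cloud: PointCloud, dist_mm: float, iters: int = 200,
                     seed: int = 0) -> PlaneModel:
    """Best-of-``iters`` three-point RANSAC plane, refit by total least
    squares on the consensus set.

    Deterministic given the seed; an inlier-count tie keeps the earliest
    iteration. Inlier counting uses absolute point-plane distance.
    """
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise PlaneFitError("need at least 3 points")
    rng = np.random.default_rng(seed)
    best_count = -1
    best_normal = None
    best_offset = 0.0
    for _ in range(max(1, iters)):
        i, j, l = rng.choice(n, size=3, replace=False)
        nvec = np.cross(pts[j] - pts[i], pts[l] - pts[i])
        nn = np.linalg.norm(nvec)
        if nn < 1e-12:
            continue
        nvec = nvec / nn
        offset = nvec @ pts[i]
        count = int(np.count_nonzero(np.abs(pts @ nvec - offset) <= dist_mm))
        if count > best_count:
            best_count, best_normal, best_offset = count, nvec, offset
    if best_normal is None or best_count < 3:
        raise PlaneFitError("no plane hypothesis with >= 3 inliers")
    # total-least-squares refit on the consensus set
    inl = np.abs(pts @ best_normal - best_offset) <= dist_mm
    sub = pts[inl]
    centroid = sub.mean(axis=0)
    cov = np.cov((sub - centroid).T, bias=True)
    _, evecs = np.linalg.eigh(cov)
    normal = evecs[:, 0]
    if normal @ best_normal < 0:
        normal = -normal
    offset = float(normal @ centroid)
    inlier_idx = np.flatnonzero(np.abs(pts @ normal - offset) <= dist_mm)
    return PlaneModel(normal=normal, offset_mm=offset,
                      inlier_indices=inlier_idx, dist_mm=dist_mm)


def remove_plane(cloud: PointCloud, plane: PlaneModel, margin_mm: float = 0.5) -> PointCloud:
    """Keep points strictly on the grain side of the stage plane, at least
    ``margin_mm`` away. The grain side is whichever half-space holds the
    majority of the points outside the inlier band."""
    signed = plane.signed_distance(cloud.points)
    mask_out = np.ones(len(cloud), dtype=bool)
    mask_out[plane.inlier_indices] = False
    above = int(np.count_nonzero(signed[mask_out] > 0))
    below = int(np.count_nonzero(signed[mask_out] < 0))
    side = 1.0 if above >= below else -1.0
    keep = side * signed > margin_mm
    if not keep.any():
        warnings.warn("remove_plane: no points remain above the stage plane", stacklevel=2)
    return cloud.select(keep)


def region_growing(cloud: PointCloud, angle_deg: float = 35.0,
                   curvature_max: float = 0.08, min_pts: int = 200,
                   max_pts: int = 200_000, k: int = 30) -> List[GrainSegment]:
    """Split a cloud into smooth clusters by normal-angle region growing.

    Seeds are processed in ascending curvature order. A k-NN neighbour joins
    the current region when the angle between its normal and the current
    point's normal is at most ``angle_deg``; it additionally becomes a new
    seed when its curvature is at most ``curvature_max``. Clusters outside
    [min_pts, max_pts] are discarded. Grain ids are assigned row-major by
    stage position (descending y, then ascending x).
    """
    if cloud.normals is None or cloud.curvature is None:
        raise ValueError("region_growing requires normals and curvature; run estimate_normals")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    n = len(cloud)
    if n == 0:
        return []
    pts, normals, curv = cloud.points, cloud.normals, cloud.curvature
    k_eff = min(k, n - 1)
    tree = cKDTree(pts)
    _, nbr = tree.query(pts, k=k_eff + 1, workers=-1)
    nbr = nbr[:, 1:]
    cos_thresh = np.cos(np.deg2rad(angle_deg))
    order = np.argsort(curv, kind="stable")
    labels = np.full(n, -1, dtype=np.int64)
    clusters: List[np.ndarray] = []
    for seed_pt in order:
        if labels[seed_pt] != -1:
            continue
        cid = len(clusters)
        labels[seed_pt] = cid
        members = [seed_pt]
        queue = [seed_pt]
        while queue:
            cur = queue.pop()
            cur_normal = normals[cur]
            for j in nbr[cur]:
                if labels[j] != -1:
                    continue
                if abs(cur_normal @ normals[j]) >= cos_thresh:
                    labels[j] = cid
                    members.append(j)
                    if curv[j] <= curvature_max:
                        queue.append(j)
        clusters.append(np.asarray(members, dtype=np.intp))
    kept = [c for c in clusters if min_pts <= len(c) <= max_pts]
    if not kept:
        warnings.warn("region_growing: no clusters within the size range", stacklevel=2)
        return []
    # row-major by stage coordinates: descending y rows, ascending x within a row
    cents = np.array([pts[c].mean(axis=0) for c in kept])
    order2 = np.lexsort((cents[:, 0], -cents[:, 1]))
    return [
        GrainSegment(grain_id=gid, cloud=cloud.select(kept[src]), indices=kept[src])
        for gid, src in enumerate(order2)
    ]


def assign_grid_cells(segments: List[GrainSegment], layout: GridLayout) -> List[GrainSegment]:
    """Attach to each segment its nearest layout cell (row, col); extras get
    row = layout.rows. The assignment must be injective, otherwise a
    :class:`GridCollisionError` lists the colliding segments."""
    cells = layout.positions()
    taken: dict = {}
    out = []
    for seg in segments:
        cx, cy = seg.centroid()[:2]
        cell_idx = int(np.argmin(np.hypot(cells[:, 0] - cx, cells[:, 1] - cy)))
        if cell_idx in taken:
            raise GridCollisionError(
                f"segments {taken[cell_idx]} and {seg.grain_id} both map to cell {cell_idx}"
            )
        taken[cell_idx] = seg.grain_id
        row, col = divmod(cell_idx, layout.cols) if cell_idx < layout.rows * layout.cols \
            else (layout.rows, cell_idx - layout.rows * layout.cols)
        seg.grid_cell = (int(row), int(col))
        out.append(seg)
    return out
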
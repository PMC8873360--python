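"""Preprocessing chain: principal-axes coordinate transform, voxel-grid
downsampling (gravity centres), statistical outlier removal.

The transform re-expresses the cloud in its principal frame: translate to
the centroid A, then rotate by the matrix whose rows are the covariance
eigenvectors e1, e2, e3 sorted by descending eigenvalue, i.e.
``T_A = M_T (T_0 - A)``. It is an isometry, so all downstream distances are
unchanged.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy.spatial import cKDTree

from .cloud import DegenerateGeometryError, PointCloud, RigidTransform

__all__ = ["pca_transform", "pca_frame", "voxel_downsample", "statistical_outlier_filter"]


def pca_frame(points: np.ndarray) -> RigidTransform:
    """Principal frame of a point set, with a deterministic sign convention.

    Eigenvectors are sorted by descending eigenvalue. Each eigenvector's sign
    is fixed so its largest-magnitude component is positive, and the last
    axis is flipped if needed so det = +1. (Exact eigenvalue ties get
    whatever orthonormal completion eigh returns; on real samples ties have
    measure zero.)
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points for a principal frame")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    if not np.isfinite(evals).all() or evals.max() <= 0:
        raise DegenerateGeometryError("zero covariance: all points coincide")
    order = np.argsort(evals)[::-1]
    rows = evecs[:, order].T
    for i in range(3):
        j = int(np.argmax(np.abs(rows[i])))
        if rows[i, j] < 0:
            rows[i] = -rows[i]
    if np.linalg.det(rows) < 0:
        rows[2] = -rows[2]
    return RigidTransform(rotation=rows, translation=centroid)


def pca_transform(cloud: PointCloud) -> Tuple[PointCloud, RigidTransform]:
    """Transform a cloud into its principal frame.

    Returns the transformed cloud (centroid at the origin, covariance
    diagonal) and the transform that produced it.
    """
    tf = pca_frame(cloud.points)
    out = cloud.with_points(tf.apply(cloud.points), frame_tag="pca")
    return out, tf


def voxel_downsample(cloud: PointCloud, leaf_mm: float) -> PointCloud:
    """Replace all points of each occupied voxel by their gravity centre.

    Voxel index is ``floor(coordinate / leaf)`` per axis in the cloud's own
    frame (no origin snapping). Output order is sorted by voxel index, so
    the result is deterministic.
    """
    if leaf_mm <= 0:
        raise ValueError("leaf_mm must be positive")
    if len(cloud) == 0:
        return cloud.with_points(cloud.points)
    idx = np.floor(cloud.points / leaf_mm).astype(np.int64)
    _, inverse, counts = np.unique(idx, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((len(counts), 3))
    np.add.at(sums, inverse, cloud.points)
    return cloud.with_points(sums / counts[:, None])


def statistical_outlier_filter(cloud: PointCloud, k: int, std_mult: float) -> PointCloud:
    """Remove points whose mean distance to their k nearest neighbours is
    abnormal: keep points with mean-kNN-distance <= mu + std_mult * sigma,
    where mu and sigma are the global mean and sd of those mean distances.
    Output is a subset of the input; no coordinates are modified.
    """
    n = len(cloud)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1, workers=-1)  # first hit is the point itself
    mean_d = dists[:, 1:].mean(axis=1)
    mu, sigma = mean_d.mean(), mean_d.std()
    return cloud.select(mean_d <= mu + std_mult * sigma)
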
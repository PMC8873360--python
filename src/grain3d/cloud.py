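"""Core in-memory containers for point-cloud morphometry.

All coordinates are millimetres throughout the package; files are assumed to
be unitless scanner exports in mm and no unit metadata is ever read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["PointCloud", "RigidTransform", "DegenerateGeometryError"]


class DegenerateGeometryError(ValueError):
    """Raised when a geometric operation receives rank-deficient input."""


@dataclass
class PointCloud:
    """A point set with optional per-point unit normals and curvature.

    Parameters
    ----------
    points : (N, 3) float array, mm
    normals : optional (N, 3) float array of unit vectors
    curvature : optional (N,) float array, dimensionless surface-variation
        ratio ``lambda_0 / (lambda_0 + lambda_1 + lambda_2)`` in [0, 1/3]
    frame_tag : which coordinate frame the points live in
        (``scanner`` as acquired, ``pca`` after the principal-axes
        transform, ``obb`` in a single grain's oriented-box frame)
    """

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    curvature: Optional[np.ndarray] = None
    frame_tag: str = "scanner"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if self.normals is not None:
            self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if self.normals.shape[0] and not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit vectors (|n| = 1 within 1e-6)")
        if self.curvature is not None:
            if self.normals is None:
                raise ValueError("curvature requires normals to be present")
            self.curvature = np.asarray(self.curvature, dtype=float).reshape(-1)
            if self.curvature.shape[0] != self.points.shape[0]:
                raise ValueError("curvature must have one value per point")
        if self.frame_tag not in ("scanner", "pca", "obb"):
            raise ValueError(f"unknown frame_tag {self.frame_tag!r}")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def has_normals(self) -> bool:
        return self.normals is not None

    def centroid(self) -> np.ndarray:
        if len(self) == 0:
            raise ValueError("empty cloud has no centroid")
        return self.points.mean(axis=0)

    def select(self, index) -> "PointCloud":
        """Subset by integer/boolean index, carrying attributes along."""
        return PointCloud(
            points=self.points[index],
            normals=None if self.normals is None else self.normals[index],
            curvature=None if self.curvature is None else self.curvature[index],
            frame_tag=self.frame_tag,
        )

    def with_points(self, points: np.ndarray, frame_tag: Optional[str] = None) -> "PointCloud":
        """New cloud with replaced coordinates; normals/curvature are dropped
        (they are frame- and neighbourhood-dependent)."""
        return PointCloud(points=points, frame_tag=frame_tag or self.frame_tag)


@dataclass
class RigidTransform:
    """Rotation + translation, applied as ``rotation @ (x - translation)``.

    ``rotation`` rows are the unit eigenvectors of the point covariance,
    sorted by descending eigenvalue; ``translation`` is the cloud centroid.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal within 1e-9")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.translation) @ self.rotation.T

    def invert(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation + self.translation
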
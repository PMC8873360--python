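"""End-to-end convenience pipelines.

These wire the stage functions together the way a scan session uses them:
scene cloud -> preprocess -> plane fit & removal -> region growing ->
per-grain traits. ``sphere_validation`` runs the standard-sphere accuracy
protocol (a 10 mm reference sphere through the full measurement chain)
used to validate the area and volume estimators without destructive
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .cloud import PointCloud
from .config import RunConfig
from .mesh import fill_holes, surface_area, triangulate_surface, volume_divergence, volume_prism
from .preprocess import statistical_outlier_filter, voxel_downsample
from .segment import (GrainSegment, PlaneModel, estimate_normals, fit_plane_ransac,
                      region_growing, remove_plane)
from .synthetic import (SCANNER_DENSITY_PTS_MM2, SCANNER_NOISE_SD_MM, GridLayout,
                        make_sphere_cloud)
from .traits import TraitVector, compute_traits, oriented_bbox
from .segment import assign_grid_cells

__all__ = ["preprocess_cloud", "segment_scene", "measure_segments",
           "process_scene", "sphere_validation"]


def preprocess_cloud(cloud: PointCloud, config: Optional[RunConfig] = None) -> PointCloud:
    """Voxel downsampling followed by statistical outlier removal (the
    scene-level chain; the principal-axes transform is available separately
    as :func:`grain3d.preprocess.pca_transform` and is not applied here so
    stage coordinates stay aligned with the placement layout)."""
    config = config or RunConfig()
    out = voxel_downsample(cloud, config.voxel_leaf_mm)
    if len(out) > config.outlier_k:
        out = statistical_outlier_filter(out, config.outlier_k, config.outlier_std_mult)
    return out


def segment_scene(cloud: PointCloud, config: Optional[RunConfig] = None,
                  layout: Optional[GridLayout] = None
                  ) -> Tuple[List[GrainSegment], PlaneModel]:
    """Stage-plane RANSAC, plane removal, normal estimation and region
    growing; optionally assigns layout grid cells."""
    config = config or RunConfig()
    plane = fit_plane_ransac(cloud, config.plane_dist_mm, config.ransac_iters,
                             config.ransac_seed)
    grains_cloud = remove_plane(cloud, plane, config.plane_margin_mm)
    if len(grains_cloud) <= config.rg_neighbors:
        return [], plane
    grains_cloud = estimate_normals(grains_cloud, k=config.normal_k)
    segments = region_growing(
        grains_cloud,
        angle_deg=config.rg_normal_angle_deg,
        curvature_max=config.rg_curvature_max,
        min_pts=config.rg_min_points,
        max_pts=config.rg_max_points,
        k=config.rg_neighbors,
    )
    if layout is not None and segments:
        segments = assign_grid_cells(segments, layout)
    return segments, plane


def measure_segments(segments: List[GrainSegment],
                     config: Optional[RunConfig] = None) -> List[TraitVector]:
    config = config or RunConfig()
    return [compute_traits(seg, config) for seg in segments]


def process_scene(cloud: PointCloud, config: Optional[RunConfig] = None,
                  layout: Optional[GridLayout] = None):
    """Full chain on a scene cloud; returns (trait vectors, segments, plane)."""
    config = config or RunConfig()
    pre = preprocess_cloud(cloud, config)
    segments, plane = segment_scene(pre, config, layout)
    return measure_segments(segments, config), segments, plane


def sphere_validation(radius_mm: float = 10.0,
                      points_per_mm2: float = SCANNER_DENSITY_PTS_MM2,
                      noise_sd_mm: float = SCANNER_NOISE_SD_MM,
                      seed: int = 1,
                      config: Optional[RunConfig] = None) -> dict:
    """Standard-sphere accuracy protocol.

    Generates a scanner-like sample of a reference sphere, runs the grain
    measurement chain (noise-averaging resample -> oriented frame -> greedy
    triangulation -> hole filling -> Heron-sum area, prism-projection
    volume) and reports relative errors against the analytic surface area
    4 pi r^2 and volume (4/3) pi r^3, plus the divergence-theorem volume as
    the independent estimator.
    """
    config = config or RunConfig()
    area_true = 4.0 * np.pi * radius_mm ** 2
    vol_true = 4.0 / 3.0 * np.pi * radius_mm ** 3
    n_points = int(round(points_per_mm2 * area_true))
    cloud = make_sphere_cloud(radius_mm, n_points, noise_sd_mm, seed)
    seg = GrainSegment(grain_id=0, cloud=cloud)
    tv = compute_traits(seg, config)
    # independent volume estimator on the same mesh route
    from scipy.spatial import cKDTree

    spacing = float(np.median(cKDTree(cloud.points).query(cloud.points, k=2,
                                                          workers=-1)[0][:, 1]))
    pre = voxel_downsample(cloud, config.trait_leaf_factor * spacing)
    _, local = oriented_bbox(pre)
    local = estimate_normals(local, k=min(config.normal_k, len(local) - 1))
    mesh = fill_holes(triangulate_surface(local, radius_mm=config.mesh_search_radius_mm,
                                          mu=config.mesh_mu,
                                          max_angle_deg=config.mesh_max_angle_deg))
    vol_div = volume_divergence(mesh)
    return {
        "radius_mm": radius_mm,
        "n_points": n_points,
        "noise_sd_mm": noise_sd_mm,
        "surface_area_mm2": tv.surface_area,
        "surface_area_true_mm2": area_true,
        "surface_area_err_pct": abs(tv.surface_area - area_true) / area_true * 100.0,
        "volume_mm3": tv.volume,
        "volume_true_mm3": vol_true,
        "volume_err_pct": abs(tv.volume - vol_true) / vol_true * 100.0,
        "volume_divergence_mm3": vol_div,
        "length_mm": tv.length,
        "width_mm": tv.width,
        "thickness_mm": tv.thickness,
    }
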
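"""Per-grain phenotypic traits.

The 25 traits are 11 basic measurements and 14 derived ratios:

====  ======================  =========================================
 1-3  l, w, h                 oriented-bounding-box extents (mm)
 4-5  V, S                    prism-projection volume (mm^3), Heron-sum
                              surface area (mm^2)
 6-11 C_yz S_yz C_xz S_xz     perimeter/area of the cross (x=0),
      C_xy S_xy               longitudinal (y=0) and horizontal (z=0)
                              principal-plane projections
12-22 ratios                  l/w, l/h, w/h, V_obb = l*w*h, S/V, S/l,
                              S/w, S/h, V/l, V/w, V/h
23-25 c_yz, c_xz, c_xy        compactness C^2 / (4 pi A) per section
====  ======================  =========================================

Axis-to-section mapping: x is the length axis, so the cross section is the
yz projection; y is width (longitudinal section = xz); z is thickness
(horizontal section = xy).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .cloud import DegenerateGeometryError, PointCloud, RigidTransform
from .config import RunConfig
from .mesh import TriangleMesh, fill_holes, surface_area, triangulate_surface, volume_prism
from .preprocess import pca_frame, voxel_downsample
from .segment import GrainSegment, estimate_normals

__all__ = [
    "TRAIT_NAMES",
    "OrientedBox",
    "Projection2D",
    "TraitVector",
    "oriented_bbox",
    "project_section",
    "compactness",
    "compute_traits",
]

TRAIT_NAMES: Tuple[str, ...] = (
    "length", "width", "thickness", "volume", "surface_area",
    "perimeter_cross", "area_cross",
    "perimeter_longitudinal", "area_longitudinal",
    "perimeter_horizontal", "area_horizontal",
    "length_width_ratio", "length_thickness_ratio", "width_thickness_ratio",
    "box_volume", "specific_surface_area",
    "surface_length_ratio", "surface_width_ratio", "surface_thickness_ratio",
    "volume_length_ratio", "volume_width_ratio", "volume_thickness_ratio",
    "compactness_cross", "compactness_longitudinal", "compactness_horizontal",
)

_SECTIONS = {"cross": 0, "longitudinal": 1, "horizontal": 2}


@dataclass
class OrientedBox:
    """PCA-aligned bounding box: frame (rows = axes) plus extents l >= w >= h."""

    frame: RigidTransform
    extents: Tuple[float, float, float]

    def __post_init__(self) -> None:
        l, w, h = self.extents
        if not (l >= w >= h > 0):
            raise ValueError(f"extents must satisfy l >= w >= h > 0, got {self.extents}")

    @property
    def volume(self) -> float:
        l, w, h = self.extents
        return l * w * h


@dataclass
class Projection2D:
    """A principal-plane projection with its concave-hull boundary."""

    section: str
    points: np.ndarray
    boundary: np.ndarray       # (B, 2) closed polygon vertices of the largest loop
    area_mm2: float
    perimeter_mm: float


@dataclass
class TraitVector:
    """The 25 named traits of one grain."""

    grain_id: int
    length: float
    width: float
    thickness: float
    volume: float
    surface_area: float
    perimeter_cross: float
    area_cross: float
    perimeter_longitudinal: float
    area_longitudinal: float
    perimeter_horizontal: float
    area_horizontal: float
    length_width_ratio: float
    length_thickness_ratio: float
    width_thickness_ratio: float
    box_volume: float
    specific_surface_area: float
    surface_length_ratio: float
    surface_width_ratio: float
    surface_thickness_ratio: float
    volume_length_ratio: float
    volume_width_ratio: float
    volume_thickness_ratio: float
    compactness_cross: float
    compactness_longitudinal: float
    compactness_horizontal: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def values(self) -> np.ndarray:
        d = self.to_dict()
        return np.array([d[name] for name in TRAIT_NAMES])


def cap_fit_extents(points: np.ndarray, band_mm: float) -> np.ndarray:
    """Per-axis max - min extents from local quadratic cap fits.

    A raw extreme over noisy points is biased upward by the largest noise
    excursion, so each of the six extreme caps is instead estimated by
    regression: the points within ``band_mm`` of the raw extreme are fitted
    with a quadratic in the two tangential coordinates (scale-safe ridge),
    and the extent side is the maximum of the *fitted* surface over the band
    points. On flat caps the fit collapses to the cap plane (noise averages
    out); on curved rims and tips it recovers the apex of the local
    paraboloid. Falls back to the raw extreme when the band holds fewer
    than 12 points. ``band_mm`` should cover the noise (several sd) and is
    best derived from the cloud itself so the estimator stays
    scale-covariant.
    """
    pts = np.asarray(points, dtype=float)
    out = np.zeros(3)
    for axis in range(3):
        tang = [a for a in range(3) if a != axis]
        sides = []
        for sign in (1.0, -1.0):
            c = sign * pts[:, axis]
            band = c > c.max() - band_mm
            if band.sum() < 12:
                sides.append(float(c.max()))
                continue
            P0 = pts[band][:, tang]
            P0 = P0 - P0.mean(axis=0)
            z = c[band]
            X = np.column_stack([
                np.ones(len(P0)), P0[:, 0], P0[:, 1],
                P0[:, 0] ** 2, P0[:, 0] * P0[:, 1], P0[:, 1] ** 2,
            ])
            XtX = X.T @ X
            ridge = 1e-8 * np.diag(np.maximum(np.diag(XtX), 1e-12))
            beta = np.linalg.solve(XtX + ridge, X.T @ z)
            sides.append(float((X @ beta).max()))
        out[axis] = sides[0] + sides[1]
    return out


# target squared-slope bias of mesh faces from residual noise after voxel
# averaging; the resampling leaf solves sigma_eff^2/leaf^2 = eps with
# sigma_eff = sigma/sqrt(rho*leaf^2), giving leaf = (sigma^2/(rho*eps))^(1/4)
_MESH_TILT_EPS = 1e-3


def estimate_noise_sd(points: np.ndarray, k: int = 8,
                      max_sample: int = 1500) -> float:
    """Robust surface-noise estimate: median absolute distance of a point to
    the best-fit plane of its k nearest neighbours (itself excluded), scaled
    to a Gaussian sd. Curvature inflates this slightly, which only makes the
    downstream resampling more conservative."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < k + 2:
        return 0.0
    step = max(1, n // max_sample)
    sample = pts[::step]
    tree = cKDTree(pts)
    _, idx = tree.query(sample, k=k + 1, workers=-1)
    resid = np.empty(len(sample))
    for i, row in enumerate(idx):
        nbr = pts[row[1:]]
        ctr = nbr.mean(axis=0)
        _, _, vt = np.linalg.svd(nbr - ctr, full_matrices=False)
        resid[i] = abs((sample[i] - ctr) @ vt[2])
    # 1.4826 MAD->sd; /1.06 removes the plane-fit leverage inflation
    return float(1.4826 * np.median(resid) / 1.06)


def mesh_resampling_leaf(spacing: float, sigma: float,
                         max_factor: float = 6.0,
                         min_extent: Optional[float] = None) -> float:
    """Noise-adaptive voxel leaf for meshing: large enough that averaged
    noise no longer tilts mesh faces, small enough to resolve curvature
    when the cloud is clean. ``min_extent`` (typically the grain thickness)
    additionally caps the leaf at a quarter of the thinnest dimension so
    slender objects keep a resolvable cross-section."""
    if spacing <= 0:
        return 0.0
    rho = 0.25 / spacing ** 2          # Poisson sampling: median NN ~ 0.5/sqrt(rho)
    leaf = (sigma ** 2 / (rho * _MESH_TILT_EPS)) ** 0.25
    hi = max_factor * spacing
    if min_extent is not None:
        hi = min(hi, min_extent / 4.0)
    hi = max(hi, spacing)
    return float(np.clip(leaf, min(2.0 * spacing, hi), hi))


def oriented_bbox(cloud: PointCloud) -> Tuple[OrientedBox, PointCloud]:
    """Oriented bounding box of a grain cloud.

    The frame is the cloud's principal frame; extents are max - min per axis
    in that frame. Axes are ordered by descending eigenvalue; if sampling
    noise makes the extents disagree with that order, axes are permuted so
    the reported (l, w, h) are sorted descending (winding fixed to keep
    det = +1). Returns the box and the cloud expressed in the box frame.
    """
    if len(cloud) < 4:
        raise DegenerateGeometryError("need at least 4 points for an oriented box")
    frame = pca_frame(cloud.points)
    local = frame.apply(cloud.points)
    extents = local.max(axis=0) - local.min(axis=0)
    if extents.min() <= 0:
        raise DegenerateGeometryError("degenerate cloud: zero extent along a principal axis")
    order = np.argsort(extents)[::-1]
    if not np.array_equal(order, [0, 1, 2]):
        rot = frame.rotation[order]
        if np.linalg.det(rot) < 0:
            rot[2] = -rot[2]
        frame = RigidTransform(rotation=rot, translation=frame.translation)
        local = frame.apply(cloud.points)
        extents = local.max(axis=0) - local.min(axis=0)
    box = OrientedBox(frame=frame, extents=tuple(float(e) for e in extents))
    return box, cloud.with_points(local, frame_tag="obb")


def project_section(cloud_obb: PointCloud, section: str,
                    alpha_mult: float = 3.0) -> Projection2D:
    """Project an OBB-frame cloud onto a principal plane and measure the
    silhouette.

    The projection drops the section's axis coordinate. The boundary is a
    concave hull: the 2D Delaunay triangulation keeps triangles whose
    longest edge is at most ``alpha_mult`` times the median projected
    nearest-neighbour spacing; area is the kept-triangle total and the
    perimeter is the total length of edges incident to exactly one kept
    triangle.
    """
    if section not in _SECTIONS:
        raise ValueError(f"section must be one of {sorted(_SECTIONS)}")
    drop = _SECTIONS[section]
    keep_axes = [a for a in range(3) if a != drop]
    pts2 = cloud_obb.points[:, keep_axes]
    if len(pts2) < 3:
        raise DegenerateGeometryError("need at least 3 points to project")
    pts2 = np.unique(pts2, axis=0)
    try:
        tri = Delaunay(pts2)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate projection: {exc}") from None
    # robust sampling scale: front/back surfaces overlay in a projection, so
    # the raw median NN collapses; floor it with the bounding-box density
    nn = float(np.median(cKDTree(pts2).query(pts2, k=2, workers=-1)[0][:, 1]))
    span = pts2.max(axis=0) - pts2.min(axis=0)
    spacing = max(nn, float(np.sqrt(span[0] * span[1] / len(pts2))))
    simplices = tri.simplices
    p = pts2[simplices]
    e = np.stack([
        np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
        np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
        np.linalg.norm(p[:, 0] - p[:, 2], axis=1),
    ], axis=1)
    kept = simplices[e.max(axis=1) <= alpha_mult * spacing]
    if len(kept) == 0:
        raise DegenerateGeometryError("alpha filter removed every triangle; raise alpha_mult")
    edge_count: dict = {}
    for s in kept:
        for ea, eb in ((s[0], s[1]), (s[1], s[2]), (s[2], s[0])):
            key = (min(ea, eb), max(ea, eb))
            edge_count[key] = edge_count.get(key, 0) + 1
    boundary_edges = [k for k, cnt in edge_count.items() if cnt == 1]
    # the silhouette is the outer loop; isolated interior pinholes left by
    # the alpha filter are sampling artefacts, not silhouette features
    boundary_poly = _chain_largest_loop(pts2, boundary_edges)
    if len(boundary_poly) < 3:
        raise DegenerateGeometryError("projection boundary could not be traced")
    x, y = boundary_poly[:, 0], boundary_poly[:, 1]
    area = float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    perimeter = float(np.linalg.norm(boundary_poly - np.roll(boundary_poly, -1, axis=0),
                                     axis=1).sum())
    return Projection2D(section=section, points=pts2, boundary=boundary_poly,
                        area_mm2=area, perimeter_mm=perimeter)


def _chain_largest_loop(pts2: np.ndarray, edges: List[Tuple[int, int]]) -> np.ndarray:
    """Chain undirected boundary edges into loops and return the loop
    enclosing the largest area (the outer silhouette boundary)."""
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    seen = set()
    best: List[int] = []
    best_area = -1.0
    for a, b in edges:
        if a in seen:
            continue
        loop = [a]
        visited = {a}
        prev, cur = a, adj[a][0]
        while cur != a and cur not in visited:
            visited.add(cur)
            loop.append(cur)
            nxt = [v for v in adj.get(cur, []) if v != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
        seen.update(loop)
        if len(loop) >= 3:
            p = pts2[loop]
            area = 0.5 * abs(np.dot(p[:, 0], np.roll(p[:, 1], -1))
                             - np.dot(p[:, 1], np.roll(p[:, 0], -1)))
            if area > best_area:
                best_area = area
                best = loop
    return pts2[best] if best else np.empty((0, 2))


def compactness(perimeter_mm: float, area_mm2: float) -> float:
    """Isoperimetric compactness c = C^2 / (4 pi A); 1 for a circle, larger
    for anything else (up to discretisation)."""
    if perimeter_mm <= 0 or area_mm2 <= 0:
        raise ValueError("perimeter and area must be positive")
    return float(perimeter_mm ** 2 / (4.0 * np.pi * area_mm2))


def compute_traits(segment: GrainSegment, config: Optional[RunConfig] = None) -> TraitVector:
    """Full per-grain trait extraction.

    Pipeline: resample the grain cloud at ``trait_leaf_factor`` times its
    native point spacing (voxel gravity centres, averaging sensor noise) ->
    oriented bounding box -> triangulate in the box frame -> fill holes ->
    Heron-sum area and prism-projection volume -> the three principal-plane
    projections -> ratios and compactness indices.
    """
    config = config or RunConfig()
    cloud = segment.cloud
    try:
        spacing = float(np.median(cKDTree(cloud.points).query(cloud.points, k=2,
                                                              workers=-1)[0][:, 1]))
        # frame from the full-resolution cloud (principal axes are noisy on
        # small resampled clouds); extents and mesh from two resampling scales
        box_full, _ = oriented_bbox(cloud)
        frame = box_full.frame
        local_full = frame.apply(cloud.points)
        sigma = estimate_noise_sd(cloud.points)
        band = max(config.extent_band_sigma_mult * sigma, 2.0 * spacing)
        extents = cap_fit_extents(local_full, band)
        order = np.argsort(extents)[::-1]
        if not np.array_equal(order, [0, 1, 2]):
            rot = frame.rotation[order]
            if np.linalg.det(rot) < 0:
                rot[2] = -rot[2]
            frame = RigidTransform(rotation=rot, translation=frame.translation)
            extents = extents[order]
        l, w, h = (float(e) for e in extents)
        box = OrientedBox(frame=frame, extents=(l, w, h))
        leaf = mesh_resampling_leaf(spacing, sigma, config.trait_leaf_factor,
                                    min_extent=h)
        mesh_cloud = voxel_downsample(cloud, leaf) if leaf > 0 else cloud
        local = PointCloud(points=frame.apply(mesh_cloud.points), frame_tag="obb")
        local = estimate_normals(local, k=min(config.normal_k, len(local) - 1))
        mesh = triangulate_surface(local, radius_mm=config.mesh_search_radius_mm,
                                   mu=config.mesh_mu,
                                   max_angle_deg=config.mesh_max_angle_deg)
        mesh = fill_holes(mesh)
        S = surface_area(mesh)
        V = volume_prism(mesh)
        # silhouettes come from the full-resolution cloud in the box frame
        obb_cloud = PointCloud(points=local_full, frame_tag="obb")
        proj = {name: project_section(obb_cloud, name, config.projection_alpha_mult)
                for name in ("cross", "longitudinal", "horizontal")}
    except Exception as exc:
        raise type(exc)(f"grain {segment.grain_id}: {exc}") from exc
    return TraitVector(
        grain_id=segment.grain_id,
        length=l, width=w, thickness=h, volume=V, surface_area=S,
        perimeter_cross=proj["cross"].perimeter_mm,
        area_cross=proj["cross"].area_mm2,
        perimeter_longitudinal=proj["longitudinal"].perimeter_mm,
        area_longitudinal=proj["longitudinal"].area_mm2,
        perimeter_horizontal=proj["horizontal"].perimeter_mm,
        area_horizontal=proj["horizontal"].area_mm2,
        length_width_ratio=l / w,
        length_thickness_ratio=l / h,
        width_thickness_ratio=w / h,
        box_volume=l * w * h,
        specific_surface_area=S / V,
        surface_length_ratio=S / l,
        surface_width_ratio=S / w,
        surface_thickness_ratio=S / h,
        volume_length_ratio=V / l,
        volume_width_ratio=V / w,
        volume_thickness_ratio=V / h,
        compactness_cross=compactness(proj["cross"].perimeter_mm,
                                      proj["cross"].area_mm2),
        compactness_longitudinal=compactness(proj["longitudinal"].perimeter_mm,
                                             proj["longitudinal"].area_mm2),
        compactness_horizontal=compactness(proj["horizontal"].perimeter_mm,
                                           proj["horizontal"].area_mm2),
    )
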
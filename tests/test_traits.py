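import numpy as np
import pytest

import grain3d as g
from grain3d.cloud import DegenerateGeometryError
from grain3d.segment import GrainSegment
from grain3d.traits import (TRAIT_NAMES, compactness, compute_traits, oriented_bbox,
                            project_section)


def ramanujan_perimeter(a, b):
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


class TestOrientedBbox:
    def test_rotated_box_extents_recovered(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.5, 0.5, (20000, 3)) * [8, 3, 2]
        rot, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        box, local = oriented_bbox(g.PointCloud(points=pts @ rot.T + [10, 5, -3]))
        # PCA axis wobble on a solid box shifts extents by up to one mean
        # sampling spacing (~(48/20000)^(1/3) = 0.13 mm)
        np.testing.assert_allclose(box.extents, [8, 3, 2], atol=0.14)
        assert local.frame_tag == "obb"
        # points fit inside the box by construction
        ext = local.points.max(axis=0) - local.points.min(axis=0)
        np.testing.assert_allclose(np.sort(ext)[::-1], box.extents, rtol=1e-12)

    def test_sphere_box_is_a_cube(self, clean_sphere_cloud):
        box, _ = oriented_bbox(clean_sphere_cloud)
        np.testing.assert_allclose(box.extents, 20.0, rtol=0.01)

    def test_rigid_motion_invariance_of_extents(self, rice_spec):
        cloud = g.make_grain_cloud(rice_spec, 20.0, 0.0, seed=1)
        rng = np.random.default_rng(2)
        rot, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = g.PointCloud(points=cloud.points @ rot.T + [7, -3, 2])
        e1 = oriented_bbox(cloud)[0].extents
        e2 = oriented_bbox(moved)[0].extents
        np.testing.assert_allclose(e1, e2, atol=1e-6)

    def test_degenerate_cloud_rejected(self):
        flat = np.column_stack([np.random.default_rng(3).uniform(0, 1, (50, 2)),
                                np.zeros(50)])
        with pytest.raises(DegenerateGeometryError):
            oriented_bbox(g.PointCloud(points=flat))


class TestProjectSection:
    def test_sphere_sections_match_analytic_disc(self, clean_sphere_cloud):
        areas, perims = [], []
        obb = g.PointCloud(points=clean_sphere_cloud.points, frame_tag="obb")
        for section in ("cross", "longitudinal", "horizontal"):
            p = project_section(obb, section)
            assert abs(p.area_mm2 - np.pi * 100) / (np.pi * 100) < 0.02
            assert abs(p.perimeter_mm - 2 * np.pi * 10) / (2 * np.pi * 10) < 0.02
            areas.append(p.area_mm2)
            perims.append(p.perimeter_mm)
        assert (max(areas) - min(areas)) / min(areas) < 0.01
        assert (max(perims) - min(perims)) / min(perims) < 0.01

    def test_dense_unit_square_in_plane(self):
        n = 80
        xx, yy = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n))
        pts = np.column_stack([np.zeros(n * n), xx.ravel(), yy.ravel()])
        p = project_section(g.PointCloud(points=pts, frame_tag="obb"), "cross")
        assert abs(p.area_mm2 - 1.0) < 0.02
        assert abs(p.perimeter_mm - 4.0) < 0.08

    def test_unknown_section_rejected(self):
        with pytest.raises(ValueError):
            project_section(g.PointCloud(points=np.zeros((10, 3)), frame_tag="obb"),
                            "diagonal")


class TestCompactness:
    def test_circle_attains_isoperimetric_equality(self):
        r = 3.7
        assert compactness(2 * np.pi * r, np.pi * r * r) == pytest.approx(1.0, abs=1e-12)

    def test_square_and_rectangle_closed_forms(self):
        assert compactness(4.0, 1.0) == pytest.approx(4 / np.pi, abs=1e-12)
        assert compactness(6.0, 2.0) == pytest.approx(36 / (8 * np.pi), abs=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compactness(0.0, 1.0)
        with pytest.raises(ValueError):
            compactness(1.0, -2.0)


class TestComputeTraits:
    def test_sphere_grain_recovers_analytic_values(self, noisy_sphere_cloud,
                                                   default_config):
        tv = compute_traits(GrainSegment(0, noisy_sphere_cloud), default_config)
        for ext in (tv.length, tv.width, tv.thickness):
            assert abs(ext - 20.0) / 20.0 < 0.01
        v_true = 4 / 3 * np.pi * 1000
        s_true = 4 * np.pi * 100
        assert abs(tv.volume - v_true) / v_true < 0.0175
        assert abs(tv.surface_area - s_true) / s_true < 0.0283
        for c in (tv.compactness_cross, tv.compactness_longitudinal,
                  tv.compactness_horizontal):
            assert abs(c - 1.0) < 0.15

    def test_ellipsoid_volume_close_to_analytic(self, rice_spec, default_config):
        cloud = g.make_grain_cloud(rice_spec, 35.0, 0.0, seed=5)
        tv = compute_traits(GrainSegment(0, cloud), default_config)
        v_true = 4 / 3 * np.pi * 4 * 1.5 * 1
        assert abs(tv.volume - v_true) / v_true < 0.02
        # silhouettes match the analytic ellipse sections
        assert abs(tv.area_cross - np.pi * 1.5) / (np.pi * 1.5) < 0.02
        assert abs(tv.perimeter_longitudinal - ramanujan_perimeter(4, 1)) \
            / ramanujan_perimeter(4, 1) < 0.02

    def test_derived_ratios_are_exact_identities(self, rice_spec, default_config):
        cloud = g.make_grain_cloud(rice_spec, 20.0, 0.02, seed=6)
        tv = compute_traits(GrainSegment(0, cloud), default_config)
        assert tv.box_volume == pytest.approx(tv.length * tv.width * tv.thickness,
                                              abs=1e-9)
        assert tv.specific_surface_area * tv.volume_length_ratio == pytest.approx(
            tv.surface_length_ratio, abs=1e-9)
        for ratio, num, den in (
            (tv.length_width_ratio, tv.length, tv.width),
            (tv.length_thickness_ratio, tv.length, tv.thickness),
            (tv.width_thickness_ratio, tv.width, tv.thickness),
            (tv.surface_width_ratio, tv.surface_area, tv.width),
            (tv.volume_thickness_ratio, tv.volume, tv.thickness),
        ):
            assert ratio == pytest.approx(num / den, abs=1e-9)
        assert tv.volume <= tv.box_volume
        assert all(v > 0 for v in tv.values())

    def test_scaling_covariance(self, rice_spec, default_config):
        cloud = g.make_grain_cloud(rice_spec, 35.0, 0.0, seed=9)
        s = 2.5
        t1 = compute_traits(GrainSegment(0, cloud), default_config)
        t2 = compute_traits(
            GrainSegment(0, g.PointCloud(points=cloud.points * s)), default_config)
        assert t2.length == pytest.approx(s * t1.length, abs=1e-6)
        assert t2.thickness == pytest.approx(s * t1.thickness, abs=1e-6)
        assert t2.perimeter_cross == pytest.approx(s * t1.perimeter_cross, abs=1e-6)
        assert t2.area_horizontal == pytest.approx(s ** 2 * t1.area_horizontal,
                                                   rel=1e-6)
        assert t2.volume == pytest.approx(s ** 3 * t1.volume, rel=1e-6)

    def test_errors_tagged_with_grain_id(self):
        tiny = g.PointCloud(points=np.random.default_rng(0).normal(0, 1, (3, 3)))
        with pytest.raises(Exception, match="grain 42"):
            compute_traits(GrainSegment(42, tiny), g.RunConfig())

    def test_trait_name_registry_matches_vector(self, rice_spec, default_config):
        cloud = g.make_grain_cloud(rice_spec, 20.0, 0.0, seed=10)
        tv = compute_traits(GrainSegment(0, cloud), default_config)
        assert len(TRAIT_NAMES) == 25
        d = tv.to_dict()
        assert [k for k in d if k != "grain_id"] == list(TRAIT_NAMES)
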
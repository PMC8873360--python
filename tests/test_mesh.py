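import numpy as np
import pytest
import trimesh

import grain3d as g
from grain3d.mesh import (MeshTopologyError, TriangleMesh, fill_holes, surface_area,
                          triangulate_surface, volume_divergence, volume_prism)
from grain3d.segment import estimate_normals

from conftest import unit_cube_mesh


def _icosphere(subdivisions, radius=10.0):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(vertices=np.asarray(ico.vertices),
                        faces=np.asarray(ico.faces)), ico


def _meshed_sphere(n=20000, noise=0.0, seed=3, radius=10.0):
    """Sphere sample meshed the way the pipeline does it: voxel-resampled to
    an even spacing first (raw Poisson samples leave more tiny holes)."""
    from scipy.spatial import cKDTree

    from grain3d.preprocess import voxel_downsample

    cloud = g.make_sphere_cloud(radius, n, noise, seed)
    spacing = float(np.median(cKDTree(cloud.points).query(cloud.points, k=2,
                                                          workers=-1)[0][:, 1]))
    cloud = voxel_downsample(cloud, 2.0 * spacing)
    cloud = estimate_normals(cloud, k=15)
    return triangulate_surface(cloud)


class TestTriangulateSurface:
    def test_tetrahedron_is_minimal_closed_mesh(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        nrm = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        mesh = triangulate_surface(g.PointCloud(points=pts, normals=nrm), radius_mm=10)
        assert len(mesh.faces) == 4
        assert mesh.is_closed

    def test_planar_grid_triangulation_count(self):
        n = 10
        xx, yy = np.meshgrid(np.arange(n) * 1.0, np.arange(n) * 1.0)
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
        cloud = g.PointCloud(points=pts, normals=np.tile([0.0, 0.0, 1.0], (n * n, 1)))
        mesh = triangulate_surface(cloud, radius_mm=3.0)
        assert len(mesh.faces) == 2 * (n - 1) ** 2
        assert abs(surface_area(mesh) - (n - 1) ** 2) < 1e-9

    def test_sphere_mesh_is_nearly_closed(self):
        mesh = _meshed_sphere()
        v, f = mesh.vertices, mesh.faces
        edge_len = {}
        for a, b, c in f:
            for e in ((a, b), (b, c), (c, a)):
                edge_len[(min(e), max(e))] = np.linalg.norm(v[e[0]] - v[e[1]])
        boundary = {(min(e), max(e)) for e in mesh.boundary_edges()}
        boundary_len = sum(edge_len[e] for e in boundary)
        assert boundary_len < 0.02 * sum(edge_len.values())
        # covers nearly every input point
        assert len(np.unique(f)) >= 0.99 * len(v)

    def test_requires_normals_and_enough_points(self):
        with pytest.raises(ValueError):
            triangulate_surface(g.PointCloud(points=np.zeros((5, 3))))
        nrm = np.tile([0.0, 0.0, 1.0], (2, 1))
        with pytest.raises(ValueError):
            triangulate_surface(g.PointCloud(points=np.zeros((2, 3)), normals=nrm))


class TestFillHoles:
    def test_closed_mesh_unchanged(self):
        cube = unit_cube_mesh()
        out = fill_holes(cube)
        assert len(out.faces) == len(cube.faces)
        assert len(out.vertices) == len(cube.vertices)

    def test_sphere_with_polar_cap_removed_closes_to_euler_two(self):
        mesh, _ = _icosphere(3)
        keep = mesh.vertices[mesh.faces].mean(axis=1)[:, 2] < 9.0  # cut the cap
        open_mesh = TriangleMesh(vertices=mesh.vertices, faces=mesh.faces[keep])
        assert not open_mesh.is_closed
        closed = fill_holes(open_mesh)
        assert closed.is_closed
        assert closed.euler_characteristic() == 2

    def test_two_holes_get_two_fan_vertices(self):
        mesh, _ = _icosphere(3)
        zc = mesh.vertices[mesh.faces].mean(axis=1)[:, 2]
        keep = (zc < 9.0) & (zc > -9.0)
        open_mesh = TriangleMesh(vertices=mesh.vertices, faces=mesh.faces[keep])
        assert len(open_mesh.boundary_loops()) == 2
        closed = fill_holes(open_mesh)
        assert closed.is_closed
        assert len(closed.vertices) == len(open_mesh.vertices) + 2

    def test_non_manifold_edge_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0.5]], float)
        f = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])  # edge (0,1) in 3 faces
        with pytest.raises(MeshTopologyError):
            fill_holes(TriangleMesh(vertices=v, faces=f))


class TestSurfaceArea:
    def test_heron_on_3_4_5_right_triangle(self):
        mesh = TriangleMesh(vertices=np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0.0]]),
                            faces=np.array([[0, 1, 2]]))
        assert surface_area(mesh) == pytest.approx(6.0, abs=1e-12)

    def test_unit_cube_area(self):
        assert surface_area(unit_cube_mesh()) == pytest.approx(6.0, abs=1e-12)

    def test_rigid_motion_invariance_and_additivity(self):
        mesh, _ = _icosphere(2)
        total = surface_area(mesh)
        part_a = surface_area(TriangleMesh(mesh.vertices, mesh.faces[:100]))
        part_b = surface_area(TriangleMesh(mesh.vertices, mesh.faces[100:]))
        assert total == pytest.approx(part_a + part_b, rel=1e-12)
        rng = np.random.default_rng(0)
        rot, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = TriangleMesh(mesh.vertices @ rot.T + [5, -2, 11], mesh.faces)
        assert surface_area(moved) == pytest.approx(total, rel=1e-9)

    def test_degenerate_sliver_clamps_and_tallies(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])  # collinear
        mesh = TriangleMesh(vertices=v, faces=np.array([[0, 1, 2]]))
        area, slivers = surface_area(mesh, return_sliver_count=True)
        assert area == 0.0

    def test_refinement_reduces_sphere_area_error(self):
        errs = []
        for n in (4000, 16000):
            mesh = fill_holes(_meshed_sphere(n=n))
            errs.append(abs(surface_area(mesh) - 400 * np.pi))
        assert errs[1] < errs[0]


class TestVolume:
    def test_prism_volume_exact_on_centred_cube(self):
        assert volume_prism(unit_cube_mesh()) == pytest.approx(1.0, abs=1e-9)

    def test_prism_volume_translation_invariant(self):
        cube = unit_cube_mesh()
        lifted = TriangleMesh(cube.vertices + [0, 0, 5.0], cube.faces)
        assert volume_prism(lifted) == pytest.approx(1.0, abs=1e-9)

    def test_icosphere_prism_volume_close_to_analytic(self):
        mesh, _ = _icosphere(4)
        v_true = 4.0 / 3.0 * np.pi * 1000
        vp = volume_prism(mesh)
        assert abs(vp - v_true) / v_true < 0.01
        assert abs(vp - volume_divergence(mesh)) / v_true < 0.005

    def test_divergence_exact_on_cube_and_regular_tetrahedron(self):
        assert volume_divergence(unit_cube_mesh()) == pytest.approx(1.0, abs=1e-12)
        # regular tetrahedron with edge 1: V = 1/(6*sqrt(2))
        base = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(8)
        f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        tet = TriangleMesh(vertices=base, faces=f)
        assert tet.is_closed
        assert volume_divergence(tet) == pytest.approx(1 / (6 * np.sqrt(2)), abs=1e-12)

    def test_divergence_rigid_motion_invariant(self):
        mesh, _ = _icosphere(2)
        rng = np.random.default_rng(1)
        rot, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(rot) < 0:
            rot[:, 0] = -rot[:, 0]
        moved = TriangleMesh(mesh.vertices @ rot.T + [3, 4, -5], mesh.faces)
        assert volume_divergence(moved) == pytest.approx(volume_divergence(mesh),
                                                         rel=1e-9)

    def test_divergence_matches_trimesh_oracle(self):
        mesh, ico = _icosphere(3)
        assert volume_divergence(mesh) == pytest.approx(abs(ico.volume), rel=1e-9)

    @pytest.mark.parametrize("subdivisions", [2, 3, 4])
    def test_prism_and_divergence_agree_on_convex_fixtures(self, subdivisions):
        mesh, _ = _icosphere(subdivisions)
        vd = volume_divergence(mesh)
        assert abs(volume_prism(mesh) - vd) / vd < 0.005
        # ellipsoid: anisotropic scaling of the icosphere
        ell = TriangleMesh(mesh.vertices * [0.4, 0.15, 0.1], mesh.faces)
        vd = volume_divergence(ell)
        assert abs(volume_prism(ell) - vd) / vd < 0.005

    def test_open_mesh_rejected_with_guidance(self):
        cube = unit_cube_mesh()
        open_mesh = TriangleMesh(cube.vertices, cube.faces[:-1])
        with pytest.raises(MeshTopologyError, match="fill_holes"):
            volume_prism(open_mesh)
        with pytest.raises(MeshTopologyError):
            volume_divergence(open_mesh)
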
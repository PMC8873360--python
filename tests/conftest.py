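import numpy as np
import pytest

import grain3d as g


@pytest.fixture(scope="session")
def default_config():
    return g.RunConfig()


@pytest.fixture(scope="session")
def clean_sphere_cloud():
    """Noise-free scanner-density sample of the 10 mm reference sphere."""
    return g.make_sphere_cloud(10.0, 20000, 0.0, seed=3)


@pytest.fixture(scope="session")
def noisy_sphere_cloud():
    """Scanner-like sample of the 10 mm reference sphere (0.05 mm noise)."""
    return g.make_sphere_cloud(10.0, 44000, 0.05, seed=1)


@pytest.fixture(scope="session")
def rice_spec():
    return g.GrainSpec(length_mm=8.0, width_mm=3.0, thickness_mm=2.0,
                       shape_exponents=(1.0, 1.0))


@pytest.fixture(scope="session")
def scene_truth():
    """25-grain 6x4+1 ground truth with mixed filled/unfilled grains."""
    return g.default_scene_truth(n_grains=25, seed=3, unfilled_frac=0.4)


@pytest.fixture(scope="session")
def scene_cloud(scene_truth):
    """Synthetic scanner scene at a desk-scale density (12 pts/mm^2)."""
    return g.make_scene(scene_truth, points_per_mm2=12.0, noise_sd_mm=0.05,
                        occlude_bottom_frac=0.05, seed=3)


@pytest.fixture(scope="session")
def segmented_scene(scene_cloud, scene_truth, default_config):
    pre = g.preprocess_cloud(scene_cloud, default_config)
    segments, plane = g.segment_scene(pre, default_config, layout=scene_truth.layout)
    return segments, plane


def unit_cube_mesh():
    """Closed 12-triangle unit cube centred at the origin, outward winding."""
    v = np.array([[x, y, z] for x in (-0.5, 0.5) for y in (-0.5, 0.5)
                  for z in (-0.5, 0.5)], dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2],   # x = -0.5
        [4, 6, 7], [4, 7, 5],   # x = +0.5
        [0, 4, 5], [0, 5, 1],   # y = -0.5
        [2, 3, 7], [2, 7, 6],   # y = +0.5
        [0, 2, 6], [0, 6, 4],   # z = -0.5
        [1, 5, 7], [1, 7, 3],   # z = +0.5
    ])
    return g.TriangleMesh(vertices=v, faces=f)
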
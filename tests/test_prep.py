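"""Cleaning, scaling, and orientation of raw clouds."""

import numpy as np
import pytest

from root3d.cloud import PointCloud
from root3d.errors import MissingColorError, ParameterError
from root3d.prep import (estimate_surface_noise, orient_up, remove_by_color,
                         remove_outliers_statistical, scale_to_reference)
from root3d.synthetic import P_MESH, P_OUTLIER, generate, taproot_spec


def test_remove_by_color_black_vs_white():
    pts = np.random.default_rng(0).uniform(0, 1, (200, 3))
    cols = np.zeros((200, 3), dtype=np.uint8)
    cols[100:] = 255
    cloud = PointCloud(pts, cols)
    kept = remove_by_color(cloud, (0, 0, 0), threshold=30)
    assert len(kept) == 100
    assert (kept.colors == 255).all()
    # order preserved: the kept points are exactly the white half
    assert np.array_equal(kept.points, pts[100:])


def test_remove_by_color_zero_threshold_identity(colored_cloud):
    kept = remove_by_color(colored_cloud, (300, 300, 300), threshold=0)
    # impossible reference color matches nothing exactly
    assert len(kept) == len(colored_cloud)


def test_remove_by_color_requires_colors(random_cloud):
    with pytest.raises(MissingColorError):
        remove_by_color(random_cloud, (0, 0, 0), 10)


def test_mesh_removal_recall_on_synthetic():
    spec = taproot_spec(depth=12, seed=5, n_mesh_points=800)
    cloud, truth = generate(spec)
    kept_mask_oracle = truth.labels != P_MESH
    kept = remove_by_color(cloud, spec.mesh_color, threshold=40)
    # all injected mesh points removed
    n_mesh = int((truth.labels == P_MESH).sum())
    assert len(kept) <= len(cloud) - n_mesh
    # root-point recall >= 99%
    n_root = int((truth.labels <= 1).sum())
    assert len(kept) >= 0.99 * n_root
    assert kept_mask_oracle.sum() >= len(kept)


def test_sor_removes_far_point():
    rng = np.random.default_rng(1)
    pts = np.vstack([rng.uniform(0, 1, (1000, 3)), [[100, 100, 100]]])
    cloud = PointCloud(pts)
    kept = remove_outliers_statistical(cloud, k=8, n_std=2)
    assert len(kept) < len(cloud)
    assert not (kept.points == 100).all(axis=1).any()


def test_sor_uniform_lattice_keeps_interior():
    g = np.mgrid[0:10, 0:10, 0:10].reshape(3, -1).T.astype(float)
    cloud = PointCloud(g)
    kept = remove_outliers_statistical(cloud, k=6, n_std=2)
    interior = (g > 0).all(axis=1) & (g < 9).all(axis=1)
    kept_set = {tuple(p) for p in kept.points}
    assert all(tuple(p) in kept_set for p in g[interior])


def test_sor_precision_recall_on_synthetic():
    spec = taproot_spec(depth=12, seed=9, outlier_fraction=0.02)
    cloud, truth = generate(spec)
    kept = remove_outliers_statistical(cloud, k=10, n_std=2.0)
    kept_idx = set(map(tuple, kept.points))
    removed = np.array([tuple(p) not in kept_idx for p in cloud.points])
    is_outlier = truth.labels == P_OUTLIER
    tp = (removed & is_outlier).sum()
    precision = tp / max(removed.sum(), 1)
    recall = tp / max(is_outlier.sum(), 1)
    assert precision >= 0.9
    assert recall >= 0.9


def test_sor_parameter_errors(random_cloud):
    with pytest.raises(ParameterError):
        remove_outliers_statistical(random_cloud, k=0)
    with pytest.raises(ParameterError):
        remove_outliers_statistical(random_cloud, k=len(random_cloud))


def test_scale_to_reference_mesh_disc():
    # 24 cm mesh-disc diameter reconstructed at 0.24 model units
    cloud = PointCloud(np.array([[0, 0, 0], [0.24, 0, 0], [0, 0.1, 0]]))
    scaled = scale_to_reference(cloud, (0, 0, 0), (0.24, 0, 0), 24.0)
    assert np.allclose(scaled.points[1], [24, 0, 0])
    assert np.allclose(scaled.points[2], [0, 10, 0])


def test_scale_identity_and_isotropy(random_cloud):
    p1, p2 = random_cloud.points[0], random_cloud.points[1]
    d = np.linalg.norm(p1 - p2)
    same = scale_to_reference(random_cloud, p1, p2, d)
    assert np.allclose(same.points, random_cloud.points)
    scaled = scale_to_reference(random_cloud, p1, p2, 2 * d)
    a, b = scaled.points[10], scaled.points[20]
    a0, b0 = random_cloud.points[10], random_cloud.points[20]
    assert np.isclose(np.linalg.norm(a - b), 2 * np.linalg.norm(a0 - b0))


def test_scale_coincident_points_error(random_cloud):
    with pytest.raises(ParameterError):
        scale_to_reference(random_cloud, (1, 1, 1), (1, 1, 1), 5.0)


def test_orient_up_identity_and_rigidity(random_cloud):
    same = orient_up(random_cloud, (0, 0, 1))
    assert np.allclose(same.points, random_cloud.points)
    assert same.frame_oriented
    rot = orient_up(random_cloud, (1, 2, 3))
    d0 = np.linalg.norm(random_cloud.points[5] - random_cloud.points[17])
    d1 = np.linalg.norm(rot.points[5] - rot.points[17])
    assert np.isclose(d0, d1)


def test_orient_up_maps_up_vector_to_z():
    cloud = PointCloud(np.array([[1.0, 0, 0], [2.0, 0, 0]]))
    rot = orient_up(cloud, (1, 0, 0))
    assert np.allclose(rot.points[0], [0, 0, 1], atol=1e-12)
    assert np.allclose(np.linalg.norm(rot.points, axis=1),
                       np.linalg.norm(cloud.points, axis=1))


def test_orient_up_antiparallel_and_zero():
    cloud = PointCloud(np.array([[0, 0, 1.0], [0, 0, -2.0]]))
    flipped = orient_up(cloud, (0, 0, -1))
    assert np.allclose(flipped.points[:, 2], [-1, 2])
    with pytest.raises(ParameterError):
        orient_up(cloud, (0, 0, 0))


def test_orient_recovers_generator_depth():
    cloud, truth = generate(taproot_spec(depth=10, seed=3,
                                         outlier_fraction=0.0))
    # tip the world so growth runs along -x; the up vector is then +x
    tipped = PointCloud(cloud.points[:, [2, 0, 1]])
    restored = orient_up(tipped, (1, 0, 0))
    depth = restored.points[:, 2].max() - restored.points[:, 2].min()
    assert abs(depth - truth.depth) < 0.5


def test_estimate_surface_noise_recovers_jitter():
    cloud, _ = generate(taproot_spec(depth=10, seed=3, jitter_sd=0.02))
    sd = estimate_surface_noise(cloud)
    assert 0.01 < sd < 0.03
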
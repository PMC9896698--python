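"""Whole-root-system traits against analytic shapes and brute force."""

import numpy as np
import pytest

from root3d.cloud import PointCloud
from root3d.global_traits import (average_diameter, convex_hull_volume,
                                  depth_width, global_trait_table,
                                  voxel_surface_area, voxel_volume)
from root3d.skeleton import (graph_from_mask, skeletonize_grid,
                             total_root_length)
from root3d.synthetic import sample_cylinder_cloud, tube_grid
from root3d.voxel import VoxelGrid, fill_internal_cavities, voxelize


def test_depth_width_trivial():
    d, w, r = depth_width(PointCloud(np.array([[0, 0, 0], [0, 0, -10.0]])))
    assert (d, w) == (10.0, 0.0)
    rect = np.array([[0, 0, 0], [6, 0, 0], [0, 8, 0], [6, 8, 0.0]])
    with pytest.warns(UserWarning):
        d, w, r = depth_width(PointCloud(rect))
    assert d == 0.0
    assert np.isclose(w, 10.0)  # rectangle diagonal
    assert np.isnan(r)


def test_width_matches_brute_force(rng):
    pts = rng.normal(0, 2, (1000, 3))
    _, width, _ = depth_width(PointCloud(pts))
    d2 = ((pts[:, None, :2] - pts[None, :, :2]) ** 2).sum(-1)
    assert np.isclose(width, np.sqrt(d2.max()))


def test_width_cocircular_points(rng):
    # every point is a hull vertex: exercises the rotating-calipers path
    phi = rng.uniform(0, 2 * np.pi, 2000)
    pts = np.column_stack([3 * np.cos(phi), 3 * np.sin(phi),
                           rng.uniform(0, 1, 2000)])
    _, width, _ = depth_width(PointCloud(pts))
    d2 = ((pts[:, None, :2] - pts[None, :, :2]) ** 2).sum(-1)
    assert np.isclose(width, np.sqrt(d2.max()))
    assert width <= 6.0 + 1e-9


def test_convex_hull_volume_cube_and_tetrahedron():
    cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                     for z in (0, 1)], dtype=float)
    assert np.isclose(convex_hull_volume(PointCloud(cube)), 1.0)
    tetra = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     dtype=float) / np.sqrt(8)  # edge length 1
    vol = convex_hull_volume(PointCloud(tetra))
    assert abs(vol - 1 / (6 * np.sqrt(2))) < 1e-12


def test_convex_hull_volume_ball_monte_carlo(rng):
    u = rng.normal(size=(5000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = 2.0 * u * rng.uniform(0, 1, (5000, 1)) ** (1 / 3)
    vol = convex_hull_volume(PointCloud(pts))
    true = 4 / 3 * np.pi * 8
    assert abs(vol - true) / true < 0.10


def test_convex_hull_degenerate_coplanar():
    flat = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2,
                            np.zeros(10)])
    with pytest.warns(UserWarning):
        assert convex_hull_volume(PointCloud(flat)) == 0.0


def test_voxel_volume_and_surface_examples():
    occ = np.zeros((3, 3, 3), bool)
    occ[1, 1, 1] = True
    g = VoxelGrid(occ, 1.0)
    assert voxel_volume(g) == 1.0
    assert voxel_surface_area(g) == 6.0
    occ2 = np.zeros((3, 2, 2), bool)
    occ2[0:2, 0, 0] = True
    g2 = VoxelGrid(occ2, 1.0)
    assert voxel_surface_area(g2) == 10.0
    assert voxel_volume(VoxelGrid(np.zeros((2, 2, 2), bool), 0.1)) == 0.0


def test_solid_cylinder_volume_within_5pct():
    grid = tube_grid(radius=0.5, length=10.0, cell=0.05)
    true = np.pi * 0.25 * 10
    assert abs(voxel_volume(grid) - true) / true < 0.05


def test_cylinder_surface_area_staircase_bound():
    grid = tube_grid(radius=0.5, length=10.0, cell=0.05)
    analytic = 2 * np.pi * 0.5 * 10 + 2 * np.pi * 0.25
    est = voxel_surface_area(grid)
    assert analytic <= est <= 1.5 * analytic


def test_average_diameter_closed_forms():
    v = np.pi * 0.04 * 10
    assert np.isclose(average_diameter(10.0, volume=v), 0.4)
    sa = 2 * np.pi * 0.2 * 10
    assert np.isclose(average_diameter(10.0, surface_area=sa,
                                       mode="from_area"), 0.4)
    with pytest.warns(UserWarning):
        assert np.isnan(average_diameter(0.0, volume=1.0))


def test_skeleton_straight_line_identity():
    occ = np.zeros((1, 1, 11), bool)
    occ[0, 0, :] = True
    skel = skeletonize_grid(VoxelGrid(occ, 0.1))
    assert skel.n_voxels == 11
    assert np.isclose(total_root_length(skel), 1.0)


def test_skeleton_diagonal_line_sqrt2():
    occ = np.zeros((11, 11, 1), bool)
    for i in range(11):
        occ[i, i, 0] = True
    skel = graph_from_mask(occ, 0.1, np.zeros(3))
    assert np.isclose(total_root_length(skel), np.sqrt(2) * 1.0)


def test_skeleton_bar_topology_preserved():
    occ = np.zeros((5, 5, 50), bool)
    occ[:, :, :] = True
    skel = skeletonize_grid(VoxelGrid(occ, 0.1))
    assert skel.n_components() == 1
    assert skel.cycle_rank() == 0


def test_skeleton_torus_keeps_loop():
    n = 40
    ii, jj, kk = np.mgrid[0:n, 0:n, 0:12].astype(float)
    c, R, r = n / 2 - 0.5, 12.0, 4.0
    rho = np.sqrt((ii - c) ** 2 + (jj - c) ** 2)
    occ = (rho - R) ** 2 + (kk - 5.5) ** 2 <= r ** 2
    grid = VoxelGrid(occ, 0.1)
    full = graph_from_mask(occ, 0.1, np.zeros(3))
    assert full.cycle_rank() >= 1
    skel = skeletonize_grid(grid)
    assert skel.n_components() == 1
    assert skel.cycle_rank() == 1


def test_cylinder_diameter_recovery_from_surface_cloud():
    cloud = sample_cylinder_cloud(radius=0.2, length=10.0, seed=0)
    grid = fill_internal_cavities(voxelize(cloud, 0.05))
    skel = skeletonize_grid(grid)
    trl = total_root_length(skel)
    assert abs(trl - 10.0) / 10.0 < 0.05
    traits = global_trait_table(cloud, grid, skel)
    assert abs(traits.average_diameter - 0.4) / 0.4 < 0.10


def test_global_trait_table_solidity_ordering(small_taproot):
    cloud, _ = small_taproot
    grid = fill_internal_cavities(voxelize(cloud, 0.1))
    traits = global_trait_table(cloud, grid)
    cube_pts = np.random.default_rng(0).uniform(0, 2, (30000, 3))
    cube_cloud = PointCloud(cube_pts)
    cube_grid = voxelize(cube_cloud, 0.2)
    cube_traits = global_trait_table(cube_cloud, cube_grid)
    # a solid cube nearly fills its hull; a sparse root system does not
    assert cube_traits.solidity > 0.9
    assert traits.solidity < 0.2
    assert traits.volume <= traits.convex_hull_volume
    assert all(np.isfinite(v) and v >= 0
               for v in traits.to_dict().values())


def test_scale_equivariance(small_taproot):
    cloud, _ = small_taproot
    s2 = PointCloud(cloud.points * 2.0)
    d1, w1, _ = depth_width(cloud)
    d2, w2, _ = depth_width(s2)
    assert np.isclose(d2, 2 * d1) and np.isclose(w2, 2 * w1)
    assert np.isclose(convex_hull_volume(s2), 8 * convex_hull_volume(cloud))
    g1 = voxelize(cloud, 0.1)
    g2 = voxelize(s2, 0.2)
    assert np.isclose(voxel_volume(g2), 8 * voxel_volume(g1))
    assert np.isclose(total_root_length(skeletonize_grid(g2)),
                      2 * total_root_length(skeletonize_grid(g1)))


def test_rotation_invariance_about_z(small_taproot):
    cloud, _ = small_taproot
    th = np.radians(30)
    rot = np.array([[np.cos(th), -np.sin(th), 0],
                    [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    turned = PointCloud(cloud.points @ rot.T)
    d1, _, _ = depth_width(cloud)
    d2, _, _ = depth_width(turned)
    assert np.isclose(d1, d2)
    assert np.isclose(convex_hull_volume(cloud), convex_hull_volume(turned),
                      rtol=1e-6)
    g1 = fill_internal_cavities(voxelize(cloud, 0.1))
    g2 = fill_internal_cavities(voxelize(turned, 0.1))
    assert abs(voxel_volume(g1) - voxel_volume(g2)) / voxel_volume(g1) < 0.03
    t1 = total_root_length(skeletonize_grid(g1))
    t2 = total_root_length(skeletonize_grid(g2))
    assert abs(t1 - t2) / t1 < 0.03
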
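"""Voxelization, cavity filling, and cell-size diagnostics."""

import numpy as np
import pytest

from root3d.cloud import PointCloud
from root3d.errors import GridSizeError, ParameterError
from root3d.synthetic import sample_cylinder_cloud
from root3d.voxel import (count_cavities, diagnose_cell_size,
                          fill_internal_cavities, load_grid,
                          n_components_26, save_grid, voxelize)


def test_single_point_single_voxel():
    grid = voxelize(PointCloud(np.array([[1.0, 2.0, 3.0], [1.01, 2.0, 3.0]])),
                    cell_size=0.5)
    assert grid.n_on == 1


def test_two_points_adjacent_voxels():
    cloud = PointCloud(np.array([[0.05, 0.05, 0.05], [0.15, 0.05, 0.05]]))
    grid = voxelize(cloud, 0.1)
    assert grid.n_on == 2
    assert grid.shape == (2, 1, 1)


def test_half_open_boundary_assignment():
    # a point exactly on a cell boundary belongs to the upper cell [lo, hi)
    cloud = PointCloud(np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0],
                                 [0.35, 0.0, 0.0]]))
    grid = voxelize(cloud, 0.1)
    assert grid.occupancy[0, 0, 0] and grid.occupancy[1, 0, 0]
    assert grid.n_on == 3


def test_every_point_lands_in_an_on_voxel(rng):
    pts = rng.uniform(-3, 3, (500, 3))
    grid = voxelize(PointCloud(pts), 0.25)
    idx = np.floor((pts - grid.origin) / grid.cell_size).astype(int)
    assert grid.occupancy[idx[:, 0], idx[:, 1], idx[:, 2]].all()
    # occupied volume bounded by one cell and the bounding box
    vol = grid.n_on * grid.cell_size ** 3
    bbox = np.prod(pts.max(0) - pts.min(0) + grid.cell_size)
    assert grid.cell_size ** 3 <= vol <= bbox


def test_revoxelize_centers_idempotent(rng):
    pts = rng.uniform(0, 2, (200, 3))
    grid = voxelize(PointCloud(pts), 0.2)
    again = voxelize(PointCloud(grid.voxel_centers()), 0.2)
    assert again.shape == grid.shape
    assert (again.occupancy == grid.occupancy).all()


def test_cell_size_validation_and_cap():
    cloud = PointCloud(np.array([[0, 0, 0], [100.0, 100, 100]]))
    with pytest.raises(ParameterError):
        voxelize(cloud, 0)
    with pytest.raises(GridSizeError):
        voxelize(cloud, 0.01)


def test_oversized_cell_single_voxel_warning():
    cloud = PointCloud(np.array([[0, 0, 0], [0.5, 0.5, 0.5]]))
    with pytest.warns(UserWarning, match="single voxel"):
        grid = voxelize(cloud, 10.0)
    assert grid.n_on == 1


def test_cylinder_connected_and_fillable():
    cloud = sample_cylinder_cloud(radius=0.3, length=10.0, density=1500,
                                  seed=0)
    grid = voxelize(cloud, 0.1)
    filled = fill_internal_cavities(grid)
    assert n_components_26(filled.occupancy) == 1
    assert count_cavities(filled.occupancy) == 0
    # the hollow interior was actually filled
    assert filled.n_on > grid.n_on


def test_diagnose_cell_size_cylinder():
    # sampled at ~0.05 cm spacing: 0.02 fragments, 0.1 forms one root
    cloud = sample_cylinder_cloud(radius=0.3, length=8.0, density=400, seed=1)
    diag = diagnose_cell_size(cloud, [0.02, 0.1, 0.5])
    by_cell = dict(zip(diag.candidates, diag.n_components))
    assert by_cell[0.02] > by_cell[0.1]
    assert diag.recommended == 0.1


def test_diagnose_merge_proxy_two_cylinders():
    a = sample_cylinder_cloud(radius=0.15, length=6.0, density=2000, seed=2)
    b = PointCloud(a.points + np.array([0.7, 0.0, 0.0]))  # 0.4 cm apart
    both = PointCloud(np.vstack([a.points, b.points]))
    diag = diagnose_cell_size(both, [0.1, 0.5])
    comp = dict(zip(diag.candidates, diag.n_components))
    assert comp[0.1] == 2
    assert comp[0.5] == 1  # merged


def test_diagnose_single_point_recommends_smallest():
    cloud = PointCloud(np.array([[0, 0, 0], [0.01, 0, 0]]))
    diag = diagnose_cell_size(cloud, [0.5, 0.1])
    assert diag.recommended == 0.1
    with pytest.raises(ParameterError):
        diagnose_cell_size(cloud, [0.1])


def test_grid_save_load_round_trip(tmp_path, rng):
    grid = voxelize(PointCloud(rng.uniform(0, 1, (100, 3))), 0.1)
    path = tmp_path / "grid.npz"
    save_grid(grid, path)
    back = load_grid(path)
    assert (back.occupancy == grid.occupancy).all()
    assert back.cell_size == grid.cell_size
    assert np.allclose(back.origin, grid.origin)
    assert (tmp_path / "grid.json").exists()


def test_cropped_preserves_world_coordinates(rng):
    grid = voxelize(PointCloud(rng.uniform(0, 3, (50, 3))), 0.2)
    cropped = grid.cropped()
    c_full = {tuple(np.round(c, 6)) for c in grid.voxel_centers()}
    c_crop = {tuple(np.round(c, 6)) for c in cropped.voxel_centers()}
    assert c_full == c_crop
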
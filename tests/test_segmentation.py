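"""Slice-wise main-root/stem segmentation and gap bridging."""

import numpy as np
import pytest

from root3d.segmentation import (BACKGROUND, LATERAL, MAIN, bridge_gaps,
                                 segment_main, slice_stack)
from root3d.synthetic import (fibrous_spec, generate, taproot_spec, tube_grid,
                              voxel_truth_labels)
from root3d.prep import remove_outliers_statistical
from root3d.voxel import STRUCT_26, VoxelGrid, fill_internal_cavities, voxelize
from scipy import ndimage


def _segmented(spec):
    cloud, truth = generate(spec)
    grid = fill_internal_cavities(voxelize(
        remove_outliers_statistical(cloud), 0.1))
    labels = bridge_gaps(segment_main(slice_stack(grid)))
    return grid, labels, truth


def test_slice_restack_round_trip(rng):
    occ = rng.uniform(size=(8, 9, 10)) > 0.7
    occ[0, 0, 0] = True
    grid = VoxelGrid(occ, 0.1, np.array([1.0, 2.0, 3.0]))
    stack = slice_stack(grid)
    back = stack.restack()
    assert (back.occupancy == occ).all()
    assert np.allclose(back.origin, grid.origin)
    # masks are ordered top (max z) first
    assert (stack.masks[0] == occ[:, :, -1]).all()


def test_cone_slice_areas_monotone():
    n = 30
    ii, jj, kk = np.mgrid[0:n, 0:n, 0:20].astype(float)
    c = n / 2 - 0.5
    occ = np.sqrt((ii - c) ** 2 + (jj - c) ** 2) <= 2 + 0.5 * kk
    stack = slice_stack(VoxelGrid(occ, 0.1))
    areas = [m.sum() for m in stack.masks]
    assert all(a >= b for a, b in zip(areas, areas[1:]))


def test_plain_cylinder_is_all_main():
    grid = tube_grid(radius=0.4, length=8.0, cell=0.1)
    labels = segment_main(slice_stack(grid))
    assert labels.n_main == grid.n_on
    assert labels.n_lateral == 0


def test_taproot_segmentation_precision_recall():
    grid, labels, truth = _segmented(taproot_spec(depth=20, seed=13))
    tl = voxel_truth_labels(grid, truth)
    on = grid.occupancy
    pred = labels.labels[on] == MAIN
    true = tl[on] == MAIN
    tp = (pred & true).sum()
    assert tp / pred.sum() >= 0.9
    assert tp / true.sum() >= 0.9


def test_fibrous_stem_recall_and_termination():
    grid, labels, truth = _segmented(fibrous_spec(system_depth=20, seed=4))
    tl = voxel_truth_labels(grid, truth)
    on = grid.occupancy
    pred = labels.labels[on] == MAIN
    true = tl[on] == MAIN
    assert (pred & true).sum() / true.sum() >= 0.9
    # the stem must not be tracked far beyond its true bottom
    main_z = np.nonzero((labels.labels == MAIN).any(axis=(0, 1)))[0]
    z_bottom = grid.origin[2] + main_z.min() * grid.cell_size
    assert z_bottom > -(truth.main_length + 1.5)


def test_label_partition_invariant():
    grid, labels, _ = _segmented(taproot_spec(depth=15, seed=2))
    on = int(grid.occupancy.sum())
    # scrubbed surface fuzz is the only unlabeled on-voxel source
    # (bridging may re-fill some scrubbed voxels, hence <=)
    n_bg_on = int((grid.occupancy & (labels.labels == BACKGROUND)).sum())
    assert 0 < n_bg_on <= labels.n_scrubbed
    n_bridged_added = int((labels.bridged & ~grid.occupancy).sum())
    assert labels.n_main + labels.n_lateral \
        == on - n_bg_on + n_bridged_added
    # MAIN and LATERAL are disjoint by construction of the int8 label array
    assert set(np.unique(labels.labels)) <= {BACKGROUND, MAIN, LATERAL}


def test_determinism():
    spec = taproot_spec(depth=15, seed=2)
    cloud, _ = generate(spec)
    grid = fill_internal_cavities(voxelize(cloud, 0.1))
    a = bridge_gaps(segment_main(slice_stack(grid)))
    b = bridge_gaps(segment_main(slice_stack(grid)))
    assert (a.labels == b.labels).all()
    assert (a.bridged == b.bridged).all()


def _cylinder_labels_with_gap(gap_layers):
    grid = tube_grid(radius=0.3, length=8.0, cell=0.1)
    labels = segment_main(slice_stack(grid))
    nz = grid.shape[2]
    mid = nz // 2
    sel = slice(mid, mid + gap_layers)
    labels.labels[:, :, sel] = BACKGROUND
    return labels


def test_bridge_gaps_restores_connectivity():
    labels = _cylinder_labels_with_gap(3)
    bridged = bridge_gaps(labels, max_gap_layers=5)
    main = bridged.labels == MAIN
    _, n = ndimage.label(main, structure=STRUCT_26)
    assert n == 1
    # bridged flags sit exactly on the filled layers
    zb = np.nonzero(bridged.bridged.any(axis=(0, 1)))[0]
    assert len(zb) == 3
    assert bridged.n_bridged > 0


def test_bridge_gaps_respects_max_gap():
    labels = _cylinder_labels_with_gap(10)
    with pytest.warns(UserWarning, match="exceeds max_gap"):
        bridged = bridge_gaps(labels, max_gap_layers=5)
    main = bridged.labels == MAIN
    _, n = ndimage.label(main, structure=STRUCT_26)
    assert n == 2
    assert bridged.n_bridged == 0


def test_mesh_gap_simulation_bridges_main():
    hits = 0
    n_runs = 6
    for seed in range(n_runs):
        spec = taproot_spec(depth=16, seed=seed,
                            gap_depths=(6.0,), gap_thickness=0.3)
        cloud, _ = generate(spec)
        grid = fill_internal_cavities(voxelize(
            remove_outliers_statistical(cloud), 0.1))
        labels = bridge_gaps(segment_main(slice_stack(grid)))
        main = labels.labels == MAIN
        _, n = ndimage.label(main, structure=STRUCT_26)
        hits += (n == 1)
        assert labels.n_bridged > 0 or n == 1
    assert hits >= 0.8 * n_runs


def test_lateral_radius_degradation_monotonicity():
    """Main-root precision degrades as laterals approach the main caliber."""
    precisions = []
    for br in (0.12, 0.22, 0.34):
        grid, labels, truth = _segmented(
            taproot_spec(depth=15, seed=11, branch_radius=br))
        tl = voxel_truth_labels(grid, truth)
        on = grid.occupancy
        pred = labels.labels[on] == MAIN
        true = tl[on] == MAIN
        precisions.append((pred & true).sum() / max(pred.sum(), 1))
    assert precisions[0] > precisions[-1]
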
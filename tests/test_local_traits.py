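"""Branch points, segment splitting, emergence selection, initial angles."""

import numpy as np
import pytest

from root3d.errors import ParameterError
from root3d.local_traits import (initial_angle, local_trait_table,
                                 main_max_diameter, select_emerging)
from root3d.prep import remove_outliers_statistical
from root3d.segmentation import bridge_gaps, segment_main, slice_stack
from root3d.skeleton import (RootSegment, branch_points, graph_from_mask,
                             junction_clusters, split_segments)
from root3d.synthetic import generate, taproot_spec
from root3d.voxel import fill_internal_cavities, voxelize


def _y_mask():
    """A Y: vertical trunk with two diverging arms, all 1 voxel wide."""
    occ = np.zeros((21, 21, 21), bool)
    occ[10, 10, 0:11] = True                       # trunk
    for s in range(1, 10):
        occ[10 + s, 10, 10 + s] = True             # arm 1 (diagonal)
        occ[10 - s, 10, 10 + s] = True             # arm 2
    return occ


def test_branch_points_line_and_y():
    line = np.zeros((1, 1, 15), bool)
    line[0, 0, :] = True
    skel = graph_from_mask(line, 0.1, np.zeros(3))
    assert branch_points(skel).sum() == 0
    y = graph_from_mask(_y_mask(), 0.1, np.zeros(3))
    assert branch_points(y).sum() >= 1
    assert junction_clusters(y) == 1


def test_split_segments_y_and_identity():
    y = graph_from_mask(_y_mask(), 0.1, np.zeros(3))
    segs = split_segments(y, branch_points(y))
    long_segs = [s for s in segs if len(s.path_vox) > 2]
    assert len(long_segs) == 3
    line = np.zeros((1, 1, 15), bool)
    line[0, 0, :] = True
    skel = graph_from_mask(line, 0.1, np.zeros(3))
    segs = split_segments(skel, branch_points(skel))
    assert len(segs) == 1
    assert len(segs[0].path_vox) == 15
    assert np.isclose(segs[0].length, 1.4)


def test_select_emerging_distance_rule():
    main = graph_from_mask(np.ones((1, 1, 30), bool), 0.1, np.zeros(3))
    near = RootSegment(np.zeros((2, 3), int),
                       np.array([[0.1, 0, 1.0], [3.0, 0, 1.0]]), 2.9)
    far = RootSegment(np.zeros((2, 3), int),
                      np.array([[5.0, 0, 1.0], [9.0, 0, 1.0]]), 4.0)
    out = select_emerging([near, far], main, main_max_diameter=1.0)
    assert near in out and far not in out
    assert near.emerging and not far.emerging
    assert near.start_gap < 0.2
    with pytest.raises(ParameterError):
        select_emerging([near], main, 0.0)


def test_select_emerging_reorients_start():
    main = graph_from_mask(np.ones((1, 1, 30), bool), 0.1, np.zeros(3))
    backwards = RootSegment(
        np.zeros((3, 3), int),
        np.array([[4.0, 0, 1.0], [2.0, 0, 1.0], [0.2, 0, 1.0]]), 3.8)
    out = select_emerging([backwards], main, main_max_diameter=1.0)
    assert len(out) == 1
    assert out[0].path_world[0][0] < out[0].path_world[-1][0]


def _straight_segment(direction, n=40, step=0.1):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    path = np.outer(np.arange(n) * step, d)
    return RootSegment(np.round(path / step).astype(int), path,
                       (n - 1) * step)


def test_initial_angle_straight_down_and_45():
    down = _straight_segment([0, 0, -1])
    assert abs(initial_angle(down)) < 1e-9
    oblique = _straight_segment([1, 0, -1])
    assert abs(initial_angle(oblique) - 45.0) < 1e-9
    up = _straight_segment([0, 0, 1])
    assert abs(initial_angle(up) - 180.0) < 1e-9


def test_initial_angle_short_path_flagged():
    seg = _straight_segment([1, 0, -1], n=6)
    ang = initial_angle(seg, offset=10, offset_hi=20)
    assert abs(ang - 45.0) < 1e-9
    assert seg.truncated_offset


def test_initial_angle_literal_start_vector():
    seg = _straight_segment([1, 0, -2])
    expected = np.degrees(np.arccos(2 / np.sqrt(5)))
    assert abs(initial_angle(seg, offset=10, offset_hi=None) - expected) < 1e-9
    with pytest.raises(ParameterError):
        initial_angle(seg, offset=0)


def test_angle_recovery_on_straight_laterals():
    """Laterals planted at a fixed 60 degrees: recovered mean within 5."""
    angles = []
    for seed in (1, 2, 3, 4):
        spec = taproot_spec(depth=15, seed=seed, branch_angle_deg=60.0,
                            branch_angle_jitter=0.0, n_branches=8)
        cloud, truth = generate(spec)
        grid = fill_internal_cavities(voxelize(
            remove_outliers_statistical(cloud), 0.1))
        labels = bridge_gaps(segment_main(slice_stack(grid)))
        traits, _ = local_trait_table(labels, grid, noise_sd=0.015)
        angles.extend(traits.initial_angles)
    assert len(angles) >= 24
    assert abs(np.mean(angles) - 60.0) <= 5.0


def test_local_trait_table_cylinder_only():
    from root3d.synthetic import sample_cylinder_cloud
    cloud = sample_cylinder_cloud(radius=0.3, length=8.0, density=1500,
                                  seed=5)
    grid = fill_internal_cavities(voxelize(cloud, 0.1))
    labels = segment_main(slice_stack(grid))
    traits, branches = local_trait_table(labels, grid)
    assert traits.branch_count == 0
    assert traits.branch_total_length == 0.0
    assert np.isnan(traits.branch_mean_diameter)
    assert abs(traits.main_length - 8.0) / 8.0 < 0.05
    assert abs(traits.main_diameter - 0.6) / 0.6 < 0.10
    assert len(branches) == 0


def test_local_traits_recover_taproot(small_taproot):
    cloud, truth = small_taproot
    grid = fill_internal_cavities(voxelize(
        remove_outliers_statistical(cloud), 0.1))
    labels = bridge_gaps(segment_main(slice_stack(grid)))
    traits, branches = local_trait_table(labels, grid, noise_sd=0.015)
    assert abs(traits.main_length - truth.main_length) \
        / truth.main_length < 0.05
    assert abs(traits.branch_total_length - truth.branch_total_length) \
        / truth.branch_total_length < 0.10
    assert abs(traits.branch_count - truth.branch_count) <= 1
    assert all(0 <= a <= 180 for a in traits.initial_angles)
    # reproducibility: identical labels give identical tables
    again, _ = local_trait_table(labels, grid, noise_sd=0.015)
    assert again.to_dict() == traits.to_dict()
    # main max diameter bounds the true base diameter from above
    assert main_max_diameter(labels) >= truth.main_diameter
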
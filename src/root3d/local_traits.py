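"""Per-root-type traits from labeled voxels.

MAIN and LATERAL voxel classes are skeletonized separately.  The lateral
skeleton is cut at branch points into segments; a segment "emerges" from the
main root/stem when its closest approach to the main skeleton is less than
the maximum main diameter.  Initial angles are measured between the vector
from the segment start to the point 10-15 skeleton steps along the path and
the downward vertical, so a plumb-vertical root scores 0 degrees.

Two length corrections compensate known voxel-skeleton biases (both are
documented in the methods note): homotopic thinning retracts skeleton ends
by roughly the local radius, so the main path is extended from each endpoint
along its end tangent to the mask boundary; and the LATERAL class begins at
the main-root surface while root lengths are conventionally measured from
the insertion on the main axis, so emerging segments add their start-gap to
the main skeleton.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParameterError
from .global_traits import average_diameter, tube_volume_corrected
from .segmentation import LATERAL, MAIN, RootLabels
from .skeleton import (RootSegment, SkeletonGraph, branch_points,
                       polyline_path_length, skeletonize_grid,
                       split_segments)
from .voxel import VoxelGrid

__all__ = [
    "LocalTraits",
    "select_emerging",
    "initial_angle",
    "main_max_diameter",
    "local_trait_table",
]

DEFAULT_ANGLE_OFFSET = (10, 20)   # chord endpoints, in skeleton steps
MIN_SEGMENT_LENGTH = 0.5          # cm; shorter skeleton pieces are debris
MIN_LATERAL_VOXELS = 20           # smaller 26-components are sensor debris
MAX_EMERGENCE_ANGLE = 100.0       # degrees; steeper-than-horizontal paths
                                  # pointing upward are fragments, not roots
DOWN = np.array([0.0, 0.0, -1.0])


@dataclass
class LocalTraits:
    """Per-specimen local traits (main root/stem vs lateral/nodal roots)."""

    main_length: float
    main_diameter: float
    branch_count: int
    branch_total_length: float
    branch_mean_diameter: float
    initial_angles: List[float] = field(default_factory=list)
    angle_mean: float = float("nan")
    angle_sd: float = float("nan")
    angle_cv: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def select_emerging(segments: List[RootSegment],
                    main_skeleton: SkeletonGraph,
                    main_max_diameter: float) -> List[RootSegment]:
    """Keep segments whose closest approach to the main skeleton is below the
    maximum main diameter; orient each to start at its near end.

    Sets ``start_gap`` (distance from the start point to the main skeleton)
    and the ``emerging`` flag on every input segment.
    """
    if main_skeleton.n_voxels == 0:
        raise ParameterError("main skeleton is empty")
    if main_max_diameter <= 0:
        raise ParameterError("main_max_diameter must be positive")
    tree = cKDTree(main_skeleton.coords)
    emerging = []
    for i, seg in enumerate(segments):
        dists, _ = tree.query(seg.path_world[[0, -1]])
        if dists[1] < dists[0]:
            seg = seg.reversed()
            segments[i] = seg
            dists = dists[::-1]
        d_all, _ = tree.query(seg.path_world)
        seg.start_gap = float(dists[0])
        # an emerging root starts at the main surface and then recedes from
        # it; junction-collar arcs hug the main at both ends and are not
        # roots, so require the far end to stand clearly farther out
        recedes = dists[1] - dists[0] > 0.5 * main_max_diameter
        seg.emerging = bool(d_all.min() < main_max_diameter and recedes)
        if seg.emerging:
            emerging.append(seg)
    return emerging


def initial_angle(segment: RootSegment,
                  offset: int = DEFAULT_ANGLE_OFFSET[0],
                  offset_hi: Optional[int] = DEFAULT_ANGLE_OFFSET[1],
                  vertical: np.ndarray = DOWN) -> float:
    """Angle (degrees) between the emergence vector and the downward vertical.

    The emergence vector is the chord from the path voxel ``offset`` steps
    from the start point to the voxel ``offset_hi`` steps away (defaults 10
    and 20).  Skipping the first ``offset`` voxels avoids the junction zone,
    where the skeleton of the cut lateral hooks along the main-root surface;
    with ``offset_hi=None`` the vector runs from the start point itself to
    the ``offset`` voxel.  Paths shorter than the offsets use their far end
    (flagged on the segment).
    """
    if offset < 1:
        raise ParameterError("offset must be >= 1")
    vert = np.asarray(vertical, float)
    vert = vert / np.linalg.norm(vert)
    path = segment.path_world
    last = len(path) - 1
    if last < 1:
        return float("nan")
    if offset_hi is None:
        a, b = 0, min(offset, last)
        if offset > last:
            segment.truncated_offset = True
    else:
        b = min(max(offset_hi, offset), last)
        a = min(offset, last)
        if b - a < 5:  # short path: keep a usable lever arm
            a = max(b - 10, 0)
            segment.truncated_offset = True
    v = path[b] - path[a]
    norm = np.linalg.norm(v)
    if norm == 0:
        return float("nan")
    return float(np.degrees(np.arccos(np.clip(v @ vert / norm, -1, 1))))


def _main_profile_volume(labels: RootLabels, noise_sd: float = 0.0) -> float:
    """Dilation-corrected main-root volume from branch-free cross-sections.

    Per-slice MAIN areas are trusted only on slices where no LATERAL voxel
    lies within 2 px of the MAIN mask; on junction slices (where 2D opening
    inevitably absorbs part of the branch collar) the equivalent radius is
    linearly interpolated from the flanking clean slices — the voxel
    equivalent of measuring a stem with calipers between branch junctions.
    Each radius is reduced by the surface-cloud dilation 0.5*cell + 1.4*sd.
    """
    from scipy import ndimage
    from skimage.morphology import disk

    cell = labels.cell_size
    main3d = labels.labels == MAIN
    lat3d = labels.labels == LATERAL
    zs = np.nonzero(main3d.any(axis=(0, 1)))[0]
    if len(zs) == 0:
        return float("nan")
    areas = np.zeros(len(zs))
    clean = np.zeros(len(zs), bool)
    se = disk(2)
    for i, z in enumerate(zs):
        m = main3d[:, :, z]
        areas[i] = m.sum()
        if not lat3d[:, :, z].any():
            clean[i] = True
        else:
            near = ndimage.binary_dilation(m, structure=se)
            clean[i] = not (near & lat3d[:, :, z]).any()
    # a collar fully absorbed on a junction's entry slice leaves no lateral
    # voxels behind; treat neighbors of contaminated slices as contaminated
    strict = clean & ~ndimage.binary_dilation(~clean, np.ones(9, bool))
    if strict.any():
        clean = strict
    elif not clean.any():
        clean[:] = True
    delta = 0.5 * cell + 1.4 * noise_sd
    r_eff = np.sqrt(areas * cell ** 2 / np.pi)
    r = np.maximum(r_eff - delta, 0.25 * cell)
    if clean.any() and not clean.all():
        # collars only ever add area, so the measured radius is an upper
        # bound; where clean slices do not bracket a junction run, the
        # interpolation extrapolates a constant and the bound still applies
        interp = np.interp(zs[~clean], zs[clean], r[clean])
        r[~clean] = np.minimum(r[~clean], interp)
    return float(np.sum(np.pi * r ** 2) * cell)


def main_max_diameter(labels: RootLabels) -> float:
    """Maximum per-slice equivalent-circle diameter of the MAIN mask (cm)."""
    main = labels.labels == MAIN
    areas = main.sum(axis=(0, 1)) * labels.cell_size ** 2
    if areas.max() == 0:
        return 0.0
    return float(2.0 * np.sqrt(areas.max() / np.pi))


def _end_extension(mask: np.ndarray, endpoint_vox: np.ndarray,
                   tangent: np.ndarray, cell: float,
                   max_steps: int = 60) -> float:
    """March from a skeleton endpoint along its end tangent through the mask;
    the distance to the boundary recovers length lost to thinning retraction."""
    norm = np.linalg.norm(tangent)
    if norm == 0:
        return 0.0
    t = tangent / norm
    pos = endpoint_vox.astype(float)
    dist = 0.0
    step = 0.5
    for _ in range(int(max_steps / step)):
        nxt = pos + t * step
        idx = np.round(nxt).astype(int)
        if (idx < 0).any() or (idx >= np.array(mask.shape)).any():
            break
        if not mask[idx[0], idx[1], idx[2]]:
            break
        pos = nxt
        dist += step
    return dist * cell


def _path_end_tangent(seg: RootSegment, end: int, lookback: int = 5
                      ) -> np.ndarray:
    path = seg.path_vox
    if len(path) < 2:
        return np.zeros(3)
    if end == 0:
        ref = path[min(lookback, len(path) - 1)]
        return (path[0] - ref).astype(float)
    ref = path[max(len(path) - 1 - lookback, 0)]
    return (path[-1] - ref).astype(float)


def _tree_farthest(start: int, adj) -> Tuple[int, dict]:
    """Farthest node from ``start`` in a weighted forest, with parents."""
    dist = {start: 0.0}
    parent = {start: -1}
    stack = [start]
    far, far_d = start, 0.0
    while stack:
        u = stack.pop()
        for v, w in adj.get(u, ()):
            if v in dist:
                continue
            dist[v] = dist[u] + w
            parent[v] = u
            if dist[v] > far_d:
                far, far_d = v, dist[v]
            stack.append(v)
    return far, parent


def _longest_path(skel: SkeletonGraph) -> np.ndarray:
    """Ordered node ids of the diameter path of the skeleton's spanning
    forest (largest component); junction spurs are ignored."""
    ids, lengths = skel.spanning_edges()
    adj: dict = {}
    for (a, b), w in zip(ids, lengths):
        adj.setdefault(int(a), []).append((int(b), float(w)))
        adj.setdefault(int(b), []).append((int(a), float(w)))
    if not adj:
        return np.arange(min(skel.n_voxels, 1))
    labels = skel.component_labels()
    largest = np.bincount(labels).argmax()
    start = int(np.nonzero(labels == largest)[0][0])
    u, _ = _tree_farthest(start, adj)
    v, parent = _tree_farthest(u, adj)
    path = [v]
    while parent[path[-1]] != -1:
        path.append(parent[path[-1]])
    return np.asarray(path[::-1])


def _main_path_length(main_grid: VoxelGrid, main_skel: SkeletonGraph) -> float:
    """Main length: chord-subsampled diameter path plus end extensions
    recovering the thinning retraction at both ends."""
    node_ids = _longest_path(main_skel)
    if len(node_ids) < 2:
        return 0.0
    coords = main_skel.coords[node_ids]
    vox = main_skel.voxels[node_ids]
    length = polyline_path_length(coords)
    look = min(5, len(vox) - 1)
    for endpoint, ref in ((vox[0], vox[look]), (vox[-1], vox[-1 - look])):
        tangent = (endpoint - ref).astype(float)
        length += _end_extension(main_grid.occupancy, endpoint, tangent,
                                 main_grid.cell_size)
    return length


def _main_axis_length(labels: RootLabels, noise_sd: float = 0.0) -> float:
    """Main-root/stem length from the per-slice centroid axis.

    The slice-tracking segmentation assumes one main cross-section per
    layer, so the axis is reconstructed as the polyline through the MAIN
    mask centroids of consecutive layers (lightly smoothed).  This is
    robust to the medial plates homotopic thinning leaves inside thick
    flat-capped stems, which corrupt skeleton-path length estimates.  Half
    a cell per end cap is added and the surface-dilation at both ends
    (0.5*cell + 1.4*noise_sd) removed.
    """
    cell = labels.cell_size
    main3d = labels.labels == MAIN
    zs = np.nonzero(main3d.any(axis=(0, 1)))[0]
    if len(zs) == 0:
        return 0.0
    cx = np.empty(len(zs))
    cy = np.empty(len(zs))
    for i, z in enumerate(zs):
        ii, jj = np.nonzero(main3d[:, :, z])
        cx[i] = ii.mean()
        cy[i] = jj.mean()
    if len(zs) >= 3:  # light smoothing against junction-collar shifts
        kernel = np.ones(3) / 3.0
        cx = np.convolve(np.pad(cx, 1, mode="edge"), kernel, mode="valid")
        cy = np.convolve(np.pad(cy, 1, mode="edge"), kernel, mode="valid")
    pts = np.column_stack([cx, cy, zs.astype(float)]) * cell
    seg = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    delta = 0.5 * cell + 1.4 * noise_sd
    return max(seg + cell - 2.0 * delta, cell)


def _drop_small_components(grid: VoxelGrid, min_voxels: int) -> VoxelGrid:
    """Remove 26-connected debris components below ``min_voxels``."""
    from scipy import ndimage

    from .voxel import STRUCT_26

    lab, n = ndimage.label(grid.occupancy, structure=STRUCT_26)
    if n == 0:
        return grid
    counts = np.bincount(lab.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return grid.with_occupancy(keep[lab])


def local_trait_table(labels: RootLabels, grid: VoxelGrid,
                      offset: int = DEFAULT_ANGLE_OFFSET[0],
                      offset_hi: Optional[int] = DEFAULT_ANGLE_OFFSET[1],
                      min_segment_length: float = MIN_SEGMENT_LENGTH,
                      noise_sd: float = 0.0,
                      ) -> Tuple[LocalTraits, pd.DataFrame]:
    """Extract local traits from labeled voxels.

    ``noise_sd`` is the estimated surface noise of the source cloud (cm),
    used to correct voxel-volume dilation in the diameter formula.  Returns
    the per-specimen :class:`LocalTraits` plus a per-branch table (segment
    id, length, start gap, initial angle, start point, emerging).
    """
    main_grid = labels.class_grid(MAIN).cropped()
    lat_grid = labels.class_grid(LATERAL).cropped()
    if main_grid.n_on == 0:
        raise ParameterError("labels contain no MAIN voxels")

    main_skel = skeletonize_grid(main_grid)
    main_len = _main_axis_length(labels, noise_sd)
    main_vol = _main_profile_volume(labels, noise_sd)
    if not np.isfinite(main_vol):
        main_vol = tube_volume_corrected(main_grid, main_len, noise_sd)
    main_diam = average_diameter(main_len, volume=main_vol)
    max_diam = main_max_diameter(labels)

    rows = []
    angles: List[float] = []
    branch_total = 0.0
    branch_diam = float("nan")
    n_emerging = 0
    lat_grid = _drop_small_components(lat_grid, MIN_LATERAL_VOXELS)
    if lat_grid.n_on > 0:
        lat_skel = skeletonize_grid(lat_grid)
        segments = split_segments(lat_skel, branch_points(lat_skel))
        segments = [s for s in segments if s.length >= min_segment_length]
        select_emerging(segments, main_skel, max_diam)
        branch_total = float(sum(s.length for s in segments))
        support_len = 0.0  # skeleton length of the voxel tube actually
        for i, seg in enumerate(segments):
            # present in the LATERAL class: raw path plus the thinning
            # retraction at both ends (but not the buried insertion run)
            ext_far = _end_extension(lat_grid.occupancy, seg.path_vox[-1],
                                     _path_end_tangent(seg, end=1),
                                     lat_grid.cell_size)
            ext_start = _end_extension(lat_grid.occupancy, seg.path_vox[0],
                                       _path_end_tangent(seg, end=0),
                                       lat_grid.cell_size)
            support_len += seg.length + ext_far + ext_start
            ang = float("nan")
            if seg.emerging:
                ang = initial_angle(seg, offset, offset_hi)
                if np.isfinite(ang) and ang > MAX_EMERGENCE_ANGLE:
                    # roots emerge downward or sideways; an upward path is
                    # a fragment (e.g. of a fractured main), not a root
                    seg.emerging = False
                    ang = float("nan")
            if seg.emerging:
                # reported length runs from the insertion on the main
                # axis: add the start gap and the far-end retraction
                branch_total += seg.start_gap + ext_far
                if np.isfinite(ang):
                    angles.append(ang)
            rows.append({
                "segment": i,
                "length": seg.length,
                "start_gap": seg.start_gap,
                "initial_angle": ang,
                "start_x": seg.start_point[0],
                "start_y": seg.start_point[1],
                "start_z": seg.start_point[2],
                "emerging": seg.emerging,
            })
        n_emerging = sum(bool(s.emerging) for s in segments)
        if support_len > 0:
            branch_diam = average_diameter(
                support_len, volume=tube_volume_corrected(
                    lat_grid, support_len, noise_sd))

    a = np.asarray(angles, float)
    mean = float(a.mean()) if a.size else float("nan")
    sd = float(a.std(ddof=1)) if a.size > 1 else float("nan")
    cv = sd / mean * 100.0 if a.size > 1 and mean > 0 else float("nan")
    traits = LocalTraits(
        main_length=main_len,
        main_diameter=main_diam,
        branch_count=n_emerging,
        branch_total_length=branch_total,
        branch_mean_diameter=branch_diam,
        initial_angles=list(a),
        angle_mean=mean, angle_sd=sd, angle_cv=cv,
    )
    return traits, pd.DataFrame(rows)
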
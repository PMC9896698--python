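"""Main-root/stem vs lateral/nodal segmentation by horizontal slicing.

The voxel model is sliced top to bottom.  On each slice the main root is
searched inside the previous slice's main mask dilated by 10% of its area;
within that region, morphological opening with a disc scaled to the expected
main cross-section removes thin lateral cross-sections, and the surviving
component becomes this slice's main mask.  Lateral/nodal roots are the
remainder.  Fractured blank layers (support-mesh removal) are bridged
afterwards by interpolating the flanking masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import ParameterError
from .voxel import STRUCT_26, VoxelGrid

__all__ = [
    "BACKGROUND", "MAIN", "LATERAL",
    "SliceStack", "slice_stack", "RootLabels",
    "segment_main", "bridge_gaps",
]

BACKGROUND, MAIN, LATERAL = 0, 1, 2

DEFAULT_DILATE_FRACTION = 0.10
DEFAULT_MAX_GAP_LAYERS = 5

_STRUCT_2D = ndimage.generate_binary_structure(2, 1)   # plus-shaped dilation
_LABEL_2D = np.ones((3, 3), dtype=bool)                # 8-connected labeling


@dataclass
class SliceStack:
    """Ordered top-to-bottom z-layer masks of a voxel grid.

    ``masks[t]`` is the (nx, ny) occupancy of layer ``nz - 1 - t``; layer
    thickness equals the grid cell size.  Restacking reproduces the source
    grid exactly.
    """

    masks: np.ndarray  # (nz, nx, ny) bool, top slice first
    cell_size: float
    origin: np.ndarray

    @property
    def n_slices(self) -> int:
        return self.masks.shape[0]

    def restack(self) -> VoxelGrid:
        occ = np.moveaxis(self.masks[::-1], 0, 2)
        return VoxelGrid(np.ascontiguousarray(occ), self.cell_size,
                         self.origin.copy())


def slice_stack(grid: VoxelGrid) -> SliceStack:
    """Slice a voxel grid into top-first 2D layer masks."""
    if grid.n_on == 0:
        raise ParameterError("cannot slice an empty grid")
    masks = np.moveaxis(grid.occupancy, 2, 0)[::-1].copy()
    return SliceStack(masks, grid.cell_size, grid.origin.copy())


@dataclass
class RootLabels:
    """Per-voxel partition into {MAIN, LATERAL, BACKGROUND} plus bridging
    provenance."""

    labels: np.ndarray      # (nx, ny, nz) int8
    bridged: np.ndarray     # (nx, ny, nz) bool, True for interpolated voxels
    cell_size: float
    origin: np.ndarray
    terminated_layer: Optional[int] = None  # top-first slice index, if any
    n_scrubbed: int = 0     # surface-fuzz voxels dropped from both classes

    def class_grid(self, value: int) -> VoxelGrid:
        return VoxelGrid(self.labels == value, self.cell_size,
                         self.origin.copy())

    @property
    def n_main(self) -> int:
        return int((self.labels == MAIN).sum())

    @property
    def n_lateral(self) -> int:
        return int((self.labels == LATERAL).sum())

    @property
    def n_bridged(self) -> int:
        return int(self.bridged.sum())

    def copy(self) -> "RootLabels":
        return RootLabels(self.labels.copy(), self.bridged.copy(),
                          self.cell_size, self.origin.copy(),
                          self.terminated_layer, self.n_scrubbed)


def _dilate_to_fraction(mask: np.ndarray, fraction: float,
                        extra: int = 0) -> np.ndarray:
    """Unit-dilate ``mask`` until its area grows by ``fraction`` of the
    original (at least one dilation), plus ``extra`` dilations for drift."""
    area0 = int(mask.sum())
    target = (1.0 + fraction) * area0
    out = ndimage.binary_dilation(mask, structure=_STRUCT_2D)
    while out.sum() < target:
        grown = ndimage.binary_dilation(out, structure=_STRUCT_2D)
        if grown.sum() == out.sum():
            break
        out = grown
    for _ in range(extra):
        out = ndimage.binary_dilation(out, structure=_STRUCT_2D)
    return out


def _pick_component(opened: np.ndarray, prev_main: np.ndarray
                    ) -> Optional[np.ndarray]:
    """Choose the opened component continuing the main root: max overlap with
    the previous main mask, falling back to nearest centroid."""
    lab, n = ndimage.label(opened, structure=_LABEL_2D)
    if n == 0:
        return None
    if n == 1:
        return opened
    overlaps = ndimage.sum_labels(prev_main, lab, index=range(1, n + 1))
    if overlaps.max() > 0:
        best = int(np.argmax(overlaps)) + 1
    else:
        prev_c = np.array(ndimage.center_of_mass(prev_main))
        centers = np.array(ndimage.center_of_mass(opened, lab,
                                                  range(1, n + 1)))
        best = int(np.argmin(((centers - prev_c) ** 2).sum(axis=1))) + 1
    return lab == best


def _resume_plausible(comp: np.ndarray, prev_main: np.ndarray,
                      ref_area: float) -> bool:
    """Per-slice continuity check for the tracked main cross-section.

    The candidate must keep a comparable area (>= 55% of the smallest of
    the recent accepted areas; thin cross-sections, reference < 40 px, use
    a looser 30% bound since their ratios are noisy), a centroid within
    1.5 equivalent radii of the last one, and must contain its own
    centroid.  A real axis tapers gradually, so an abrupt area collapse
    marks a hand-over to a lateral; the centroid-containment condition
    separately rejects rings of merged lateral cross-sections around a
    vanished stem (a filled main blob covers its center of mass, a
    cluster of nodal roots surrounding the empty axis does not).  The
    minimum reference keeps junction-inflated slices from poisoning the
    comparison: collars only ever add area.
    """
    min_ratio = 0.55 if ref_area >= 40 else 0.3
    if comp.sum() < min_ratio * ref_area:
        return False
    c_prev = np.array(ndimage.center_of_mass(prev_main))
    c_new = np.array(ndimage.center_of_mass(comp))
    r_eq = np.sqrt(max(float(prev_main.sum()), 1.0) / np.pi)
    if np.linalg.norm(c_new - c_prev) > 1.5 * max(r_eq, 2.0):
        return False
    ci, cj = np.round(c_new).astype(int)
    ci = np.clip(ci, 0, comp.shape[0] - 1)
    cj = np.clip(cj, 0, comp.shape[1] - 1)
    return bool(comp[ci, cj])


def _open_region(region: np.ndarray, r0: int, r_max: int) -> np.ndarray:
    """Escalate opening radius from r0 until at most one component remains."""
    opened = region
    for r in range(r0, r_max + 1):
        opened = ndimage.binary_opening(region, structure=disk(r))
        _, n = ndimage.label(opened, structure=_LABEL_2D)
        if n <= 1:
            break
    return opened


def segment_main(stack: SliceStack,
                 dilate_fraction: float = DEFAULT_DILATE_FRACTION,
                 opening_start_factor: float = 0.5,
                 opening_max_factor: float = 2.0,
                 open_within_region: bool = True,
                 max_carry_layers: int = 10) -> RootLabels:
    """Track the main root/stem down the slice stack; the rest is lateral.

    Per slice: (1) the search region is the previous main mask dilated until
    its area grows by ``dilate_fraction``; (2) the slice content inside the
    region is opened with a disc of radius 0.5x the previous main equivalent
    radius (escalating to 2x while more than one component survives); (3) the
    surviving component is MAIN, everything else on the slice LATERAL.  The
    topmost non-blank slice seeds with its largest connected component.

    Fully blank slices (mesh-removal fractures) are carried across for up to
    ``max_carry_layers`` layers.  If the search region is empty or nothing
    survives opening on a non-blank slice, the main root is declared
    terminated at that depth and all deeper voxels are LATERAL.
    """
    if dilate_fraction < 0:
        raise ParameterError("dilate_fraction must be >= 0")
    nz = stack.n_slices
    main_masks = np.zeros_like(stack.masks)
    terminated_layer: Optional[int] = None

    # seed: largest 8-connected component of the topmost non-blank slice
    # that is a substantial cross-section (isolated jitter specks above the
    # root base must not seed the tracking)
    t_first = 0
    while t_first < nz and not stack.masks[t_first].any():
        t_first += 1
    if t_first == nz:
        raise ParameterError("slice stack is entirely empty")
    window = range(t_first, min(t_first + 10, nz))
    largest = {}
    for t in window:
        lab, n = ndimage.label(stack.masks[t], structure=_LABEL_2D)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=range(1, n + 1))
        largest[t] = (lab, int(np.argmax(sizes)) + 1, float(sizes.max()))
    ref_area = max(v[2] for v in largest.values())
    t0 = next(t for t in window
              if t in largest and largest[t][2] >= 0.3 * ref_area)
    lab, comp_id, _ = largest[t0]
    main_masks[t0] = lab == comp_id

    prev_main = main_masks[t0]
    from collections import deque
    recent_areas = deque([float(prev_main.sum())], maxlen=5)
    misses = 0  # consecutive layers without a trackable main cross-section
    for t in range(t0 + 1, nz):
        sl = stack.masks[t]
        if terminated_layer is not None:
            continue
        if not sl.any():
            # fully blank layer: mesh-removal fracture; carry across
            misses += 1
            if misses > max_carry_layers:
                terminated_layer = t
            continue
        search = _dilate_to_fraction(prev_main, dilate_fraction, extra=misses)
        region = sl & search
        if not region.any():
            misses += 1
            if misses > max_carry_layers:
                terminated_layer = t
            continue
        area_px = int(prev_main.sum())
        r_eq = float(np.sqrt(area_px / np.pi))
        r0 = int(round(opening_start_factor * r_eq))
        if r0 >= 1:
            r_max = max(r0, int(np.ceil(opening_max_factor * r0)))
            target = region if open_within_region else sl
            opened = _open_region(target, r0, r_max)
            if open_within_region:
                opened &= region
            else:
                opened &= search
        else:
            opened = region  # main too thin to survive any opening
        comp = _pick_component(opened, prev_main)
        if comp is None or not comp.any():
            # nothing main-like survives: defective layer or the main has
            # genuinely ended (e.g. stem base); decide after a grace run
            misses += 1
            if misses > max_carry_layers:
                terminated_layer = t
            continue
        ref_area = float(min(recent_areas))
        if not _resume_plausible(comp, prev_main, ref_area):
            # a lateral blob inside the search region must not hijack the
            # main: cross-sections evolve gradually down a real axis, so an
            # abrupt area collapse or centroid jump marks an impostor
            misses += 1
            if misses > max_carry_layers:
                terminated_layer = t
            continue
        misses = 0
        # Re-adsorb the ragged 1-px boundary ring the erosion step shaved
        # off, but spare genuine lateral cross-sections: residue that
        # survives a unit opening is a real lateral, not boundary fuzz.
        residue = region & ~comp
        solid_lateral = ndimage.binary_opening(residue, structure=disk(1))
        ring = ndimage.binary_dilation(comp, structure=_LABEL_2D) \
            & residue & ~solid_lateral
        main_masks[t] = (comp | ring) & sl
        prev_main = main_masks[t]
        recent_areas.append(float(prev_main.sum()))

    nz_, nx, ny = stack.masks.shape
    labels3d = np.zeros((nx, ny, nz_), dtype=np.int8)
    # map top-first slice index t back to grid layer iz = nz - 1 - t
    lateral = stack.masks & ~main_masks
    main_grid = np.moveaxis(main_masks[::-1], 0, 2)
    lat_grid = np.moveaxis(lateral[::-1], 0, 2)
    labels3d[main_grid] = MAIN
    labels3d[lat_grid] = LATERAL
    n_scrubbed = _scrub_surface_fuzz(labels3d)
    return RootLabels(labels3d, np.zeros_like(labels3d, dtype=bool),
                      stack.cell_size, stack.origin.copy(), terminated_layer,
                      n_scrubbed)


def _scrub_surface_fuzz(labels3d: np.ndarray) -> int:
    """Drop thin LATERAL shell fragments hugging the MAIN surface.

    Slice-wise tracking can only absorb boundary fuzz inside its search
    region; fragments of the main-root surface shell (and the end-cap
    shell left where the main terminates) otherwise attach to lateral
    components and corrupt lateral skeletons with phantom arcs.  A voxel
    is scrubbed when it lies within 2 voxels of MAIN and 3 layers of the
    main span and does not survive a unit 6-connected opening of the
    lateral class (i.e. it is not part of a solid lateral root).  Scrubbed
    voxels belong to neither class; their count is recorded.
    """
    from .voxel import STRUCT_26, STRUCT_6

    main3d = labels3d == MAIN
    lat3d = labels3d == LATERAL
    if not main3d.any() or not lat3d.any():
        return 0
    solid = ndimage.binary_opening(lat3d, structure=STRUCT_6)
    near_main = ndimage.binary_dilation(main3d, structure=STRUCT_26,
                                        iterations=2)
    zmask = ndimage.binary_dilation(main3d.any(axis=(0, 1)),
                                    structure=np.ones(7, bool))
    crumbs = lat3d & ~solid & near_main & zmask[None, None, :]
    labels3d[crumbs] = BACKGROUND
    return int(crumbs.sum())


def _layer_main(labels: RootLabels, t: int) -> np.ndarray:
    nz = labels.labels.shape[2]
    return labels.labels[:, :, nz - 1 - t] == MAIN


def _disc_mask(shape, center, radius) -> np.ndarray:
    xx, yy = np.ogrid[: shape[0], : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2


def bridge_gaps(labels: RootLabels,
                max_gap_layers: int = DEFAULT_MAX_GAP_LAYERS) -> RootLabels:
    """Reconnect the main root across short runs of blank layers.

    Runs of at most ``max_gap_layers`` consecutive layers with an empty MAIN
    mask, flanked above and below by non-empty MAIN, are filled with discs
    whose centroid and equivalent radius interpolate the flanking masks.
    Filled voxels are flagged as bridged.  Longer gaps are left open with a
    warning naming the layer range.
    """
    if max_gap_layers < 0:
        raise ParameterError("max_gap_layers must be >= 0")
    out = labels.copy()
    nz = labels.labels.shape[2]
    present = np.array([_layer_main(labels, t).any() for t in range(nz)])
    if not present.any():
        return out
    first, last = np.nonzero(present)[0][[0, -1]]
    t = first + 1
    while t < last:
        if present[t]:
            t += 1
            continue
        run_start = t
        while t < last and not present[t]:
            t += 1
        run_end = t  # first present layer after the run
        run_len = run_end - run_start
        if run_len > max_gap_layers:
            warnings.warn(
                f"main-root gap of {run_len} layers "
                f"(slices {run_start}..{run_end - 1}) exceeds "
                f"max_gap_layers={max_gap_layers}; left unbridged"
            )
            continue
        above = _layer_main(labels, run_start - 1)
        below = _layer_main(labels, run_end)
        c_a = np.array(ndimage.center_of_mass(above))
        c_b = np.array(ndimage.center_of_mass(below))
        r_a = np.sqrt(above.sum() / np.pi)
        r_b = np.sqrt(below.sum() / np.pi)
        for g, tg in enumerate(range(run_start, run_end), start=1):
            w = g / (run_len + 1)
            center = (1 - w) * c_a + w * c_b
            radius = max((1 - w) * r_a + w * r_b, 0.5)
            disc = _disc_mask(above.shape, center, radius)
            iz = nz - 1 - tg
            fill = disc & (out.labels[:, :, iz] == BACKGROUND)
            out.labels[:, :, iz][fill] = MAIN
            out.bridged[:, :, iz] |= fill
    return out
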
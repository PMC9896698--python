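"""Voxel skeletons as metric graphs.

Skeletonization uses 3D homotopic thinning (Lee et al.'s method as shipped in
scikit-image), which preserves the 26-connected topology of the input solid
and yields 1-voxel-wide centerlines except at junctions.  The skeleton is
turned into a graph whose edges join 26-adjacent voxels with metric lengths
cell_size * {1, sqrt(2), sqrt(3)}; root length is measured on a per-component
minimum spanning structure of that graph so parallel adjacencies around
junctions are not double counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from skimage.morphology import skeletonize as _skeletonize_nd

from .errors import ParameterError
from .voxel import STRUCT_26, VoxelGrid

__all__ = [
    "SkeletonGraph",
    "skeletonize_grid",
    "total_root_length",
    "branch_points",
    "junction_clusters",
    "RootSegment",
    "split_segments",
]

# the 13 lexicographically positive offsets of the 26-neighborhood
_HALF_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ],
    dtype=np.int64,
)


@dataclass
class SkeletonGraph:
    """Skeleton voxels with 26-adjacency edges and metric edge lengths."""

    voxels: np.ndarray          # (M, 3) int voxel indices
    cell_size: float
    origin: np.ndarray
    edges: np.ndarray           # (E, 2) int indices into voxels
    edge_lengths: np.ndarray    # (E,) cm, in cell_size * {1, sqrt2, sqrt3}
    _spanning: Optional[Tuple[np.ndarray, np.ndarray]] = field(
        default=None, repr=False)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def coords(self) -> np.ndarray:
        """World (cm) coordinates of skeleton voxel centers."""
        return self.origin + self.cell_size * (self.voxels + 0.5)

    def _csr(self):
        n = self.n_voxels
        if len(self.edges) == 0:
            return coo_matrix((n, n)).tocsr()
        i, j = self.edges[:, 0], self.edges[:, 1]
        return coo_matrix(
            (self.edge_lengths, (i, j)), shape=(n, n)
        ).tocsr()

    def component_labels(self) -> np.ndarray:
        if self.n_voxels == 0:
            return np.zeros(0, dtype=int)
        _, labels = connected_components(self._csr(), directed=False)
        return labels

    def n_components(self) -> int:
        if self.n_voxels == 0:
            return 0
        n, _ = connected_components(self._csr(), directed=False)
        return int(n)

    def cycle_rank(self) -> int:
        """First Betti number of the adjacency graph: E - V + C."""
        if self.n_voxels == 0:
            return 0
        return len(self.edges) - self.n_voxels + self.n_components()

    def spanning_edges(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-component minimum-spanning edge set: ((E', 2) ids, lengths)."""
        if self._spanning is None:
            if len(self.edges) == 0:
                self._spanning = (np.zeros((0, 2), int), np.zeros(0))
            else:
                mst = minimum_spanning_tree(self._csr()).tocoo()
                ids = np.column_stack([mst.row, mst.col]).astype(int)
                self._spanning = (ids, mst.data.copy())
        return self._spanning

    def spanning_midpoints(self) -> Tuple[np.ndarray, np.ndarray]:
        """World midpoints and lengths of the spanning edges."""
        ids, lengths = self.spanning_edges()
        coords = self.coords
        if len(ids) == 0:
            return np.zeros((0, 3)), lengths
        mids = 0.5 * (coords[ids[:, 0]] + coords[ids[:, 1]])
        return mids, lengths

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_voxels, dtype=int)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg


def _build_edges(voxels: np.ndarray, shape) -> Tuple[np.ndarray, np.ndarray]:
    """All 26-adjacent pairs among ``voxels`` via sorted raveled codes."""
    if len(voxels) == 0:
        return np.zeros((0, 2), int), np.zeros(0)
    mx = voxels.max(axis=0) + 2
    codes = np.ravel_multi_index(voxels.T, mx)
    order = np.argsort(codes)
    sorted_codes = codes[order]
    src, dst, steps = [], [], []
    for off in _HALF_OFFSETS:
        nb = voxels + off
        valid = (nb >= 0).all(axis=1) & (nb < mx).all(axis=1)
        nb_codes = np.ravel_multi_index(nb[valid].T, mx)
        pos = np.searchsorted(sorted_codes, nb_codes)
        pos = np.clip(pos, 0, len(sorted_codes) - 1)
        hit = sorted_codes[pos] == nb_codes
        ii = np.nonzero(valid)[0][hit]
        jj = order[pos[hit]]
        src.append(ii)
        dst.append(jj)
        steps.append(np.full(hit.sum(), np.sqrt((off ** 2).sum())))
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    steps = np.concatenate(steps)
    return np.column_stack([src, dst]), steps


def graph_from_mask(mask: np.ndarray, cell_size: float,
                    origin) -> SkeletonGraph:
    voxels = np.argwhere(mask)
    edges, steps = _build_edges(voxels, mask.shape)
    return SkeletonGraph(voxels, cell_size, np.asarray(origin, float),
                         edges, steps * cell_size)


def skeletonize_grid(grid: VoxelGrid) -> SkeletonGraph:
    """Homotopic-thinning centerline skeleton of a voxel grid, as a graph."""
    if grid.n_on == 0:
        raise ParameterError("cannot skeletonize an empty grid")
    mask = _skeletonize_nd(grid.occupancy).astype(bool)
    return graph_from_mask(mask, grid.cell_size, grid.origin)


def total_root_length(skeleton: SkeletonGraph) -> float:
    """Sum of spanning-structure edge lengths (cm); junctions counted once."""
    _, lengths = skeleton.spanning_edges()
    return float(lengths.sum())


def branch_points(skeleton: SkeletonGraph) -> np.ndarray:
    """Boolean mask over skeleton voxels with >= 3 neighbors (26-adjacency)."""
    return skeleton.degrees() >= 3


def junction_clusters(skeleton: SkeletonGraph) -> int:
    """Number of junctions after merging 26-adjacent branch-point voxels."""
    bp = branch_points(skeleton)
    if not bp.any():
        return 0
    vox = skeleton.voxels[bp]
    shape = vox.max(axis=0) + 1
    mask = np.zeros(shape, dtype=bool)
    mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    _, n = ndimage.label(mask, structure=STRUCT_26)
    return int(n)


@dataclass(eq=False)
class RootSegment:
    """An ordered, junction-free skeleton path.

    ``path_world`` runs from ``start_point`` (the end closest to the main
    root/stem once :func:`root3d.local_traits.select_emerging` has been
    applied) to the far end.
    """

    path_vox: np.ndarray       # (L, 3) ordered voxel indices
    path_world: np.ndarray     # (L, 3) ordered world coords, cm
    length: float              # cm, sum of consecutive step lengths
    emerging: bool = False
    start_gap: float = np.nan  # cm from start_point to the main skeleton
    truncated_offset: bool = False  # angle offset exceeded the path length

    @property
    def start_point(self) -> np.ndarray:
        return self.path_world[0]

    def reversed(self) -> "RootSegment":
        seg = RootSegment(self.path_vox[::-1].copy(),
                          self.path_world[::-1].copy(), self.length,
                          self.emerging, self.start_gap)
        return seg


def polyline_path_length(path_world: np.ndarray, step: int = 4) -> float:
    """Length of an ordered voxel path by chords over every ``step`` voxels.

    Summing per-voxel steps weighted {1, sqrt2, sqrt3} overestimates oblique
    digitized lines by up to ~8%; chord subsampling suppresses that direction
    quantization while remaining exact on straight axis/diagonal runs.
    """
    path = np.asarray(path_world, float)
    if len(path) < 2:
        return 0.0
    idx = list(range(0, len(path), step))
    if idx[-1] != len(path) - 1:
        idx.append(len(path) - 1)
    pts = path[idx]
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _adjacency(ids: Sequence[int], edges: np.ndarray) -> Dict[int, List[int]]:
    adj: Dict[int, List[int]] = {int(i): [] for i in ids}
    for a, b in edges:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    return adj


def _order_path(nodes: List[int], adj: Dict[int, List[int]]) -> List[int]:
    """Linearize a tree that is a simple path, starting from an endpoint."""
    if len(nodes) == 1:
        return nodes
    endpoints = [n for n in nodes if len(adj[n]) <= 1]
    start = endpoints[0] if endpoints else nodes[0]
    path = [start]
    prev = None
    cur = start
    while True:
        nxt = [n for n in adj[cur] if n != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        path.append(cur)
        if len(path) > len(nodes):
            break  # safety on unexpected cycles
    return path


def split_segments(skeleton: SkeletonGraph,
                   branch_mask: Optional[np.ndarray] = None
                   ) -> List[RootSegment]:
    """Cut the skeleton at branch points and linearize each remaining piece.

    Each 26-connected component of (skeleton - branch points) is reduced to
    its minimum spanning tree; tree nodes of degree >= 3 (diagonal-adjacency
    shortcuts) are removed recursively until every piece is a simple path.
    """
    if branch_mask is None:
        branch_mask = branch_points(skeleton)
    keep = ~np.asarray(branch_mask, bool)
    keep_ids = np.nonzero(keep)[0]
    if len(keep_ids) == 0:
        return []
    edge_keep = keep[skeleton.edges[:, 0]] & keep[skeleton.edges[:, 1]] \
        if len(skeleton.edges) else np.zeros(0, bool)
    edges = skeleton.edges[edge_keep]
    lengths = skeleton.edge_lengths[edge_keep]

    # per-component MST on the reduced graph
    n = skeleton.n_voxels
    sub = coo_matrix((lengths, (edges[:, 0], edges[:, 1])), shape=(n, n))
    mst = minimum_spanning_tree(sub.tocsr()).tocoo()
    tree_edges = np.column_stack([mst.row, mst.col]).astype(int)

    adj = _adjacency(keep_ids, tree_edges)
    # recursively split at remaining high-degree tree nodes
    changed = True
    while changed:
        changed = False
        for node in list(adj):
            if len(adj[node]) >= 3:
                for nb in adj[node]:
                    adj[nb].remove(node)
                del adj[node]
                changed = True

    # collect connected pieces of the remaining forest
    coords = skeleton.coords
    visited = set()
    segments: List[RootSegment] = []
    for node in adj:
        if node in visited:
            continue
        comp = [node]
        visited.add(node)
        stack = [node]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in visited:
                    visited.add(nb)
                    comp.append(nb)
                    stack.append(nb)
        order = _order_path(comp, adj)
        world = coords[order]
        vox = skeleton.voxels[order]
        segments.append(RootSegment(vox, world,
                                    polyline_path_length(world)))
    return segments
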
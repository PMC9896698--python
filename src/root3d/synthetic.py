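"""Parametric synthetic root systems with exact ground truth.

The generator emulates what multi-view-stereo reconstruction delivers for an
excavated, mesh-supported root system: a dense *surface* point cloud of a
downward-growing root system (taproot with laterals, or a short thick stem
with nodal roots), contaminated with Gaussian sensor jitter, sparse uniform
outliers, and optionally near-black support-mesh points and horizontal blank
slabs where the mesh was cut away.

Centerlines are piecewise-linear curves built before discretization, so all
ground-truth quantities (lengths, depth, width, frusta volumes and surface
areas, per-branch initial angles) are exact by construction, and every
generated point carries a provenance label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .cloud import PointCloud
from .voxel import VoxelGrid

__all__ = [
    "RootSystemSpec", "GroundTruth", "generate", "generate_cohort",
    "taproot_spec", "fibrous_spec", "voxel_truth_labels",
    "sample_cylinder_cloud", "tube_grid",
    "P_MAIN", "P_BRANCH", "P_OUTLIER", "P_MESH",
]

# per-point provenance labels
P_MAIN, P_BRANCH, P_OUTLIER, P_MESH = 0, 1, 2, 3

_STEP = 0.25  # cm, centerline discretization step


@dataclass
class RootSystemSpec:
    """Parameters of one synthetic root system.

    ``depth`` is the arc length of the main axis (taproot) or of the stem
    (fibrous); nodal/lateral roots are controlled by the branch fields.
    Angles are degrees from the downward vertical.
    """

    architecture: str = "taproot"      # {taproot, fibrous}
    depth: float = 30.0                # cm, main-axis length
    base_radius: float = 0.45          # cm
    tip_radius: float = 0.10           # cm
    wander_amplitude: float = 0.5      # cm, sinusoidal main-axis wander
    wander_wavelength: float = 30.0    # cm
    n_branches: int = 6
    insertion_range: Tuple[float, float] = (0.08, 0.6)  # fractions of depth
    branch_angle_deg: float = 55.0
    branch_angle_jitter: float = 8.0   # per-branch uniform +- jitter
    branch_length_range: Tuple[float, float] = (9.0, 14.0)  # cm
    branch_radius: float = 0.16        # cm
    branch_taper: float = 0.6          # tip radius = taper * branch_radius
    curvature_deg_per_cm: float = 0.0  # gravitropic bend toward -z
    point_density: float = 800.0       # surface points per cm^2
    jitter_sd: float = 0.015           # cm
    outlier_fraction: float = 0.005
    n_mesh_points: int = 0
    mesh_color: Tuple[int, int, int] = (20, 20, 20)
    mesh_spacing: float = 12.0         # cm between mesh discs
    root_color: Tuple[int, int, int] = (150, 110, 80)
    gap_depths: Tuple[float, ...] = () # cm; blank slab centers (mesh removal)
    gap_thickness: float = 0.3         # cm
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.architecture not in ("taproot", "fibrous"):
            bad.append("architecture")
        if self.depth <= 0:
            bad.append("depth")
        if self.base_radius <= 0 or self.tip_radius <= 0:
            bad.append("base_radius/tip_radius")
        if self.n_branches < 0:
            bad.append("n_branches")
        if not (0 <= self.insertion_range[0] <= self.insertion_range[1] <= 1):
            bad.append("insertion_range")
        if not (0 <= self.branch_angle_deg <= 90):
            bad.append("branch_angle_deg")
        if self.n_branches and self.branch_radius <= 0:
            bad.append("branch_radius")
        if self.point_density <= 0:
            bad.append("point_density")
        if self.jitter_sd < 0:
            bad.append("jitter_sd")
        if not (0 <= self.outlier_fraction < 1):
            bad.append("outlier_fraction")
        if bad:
            raise ValueError(
                "invalid RootSystemSpec fields: " + ", ".join(bad))


@dataclass
class GroundTruth:
    """Exact trait values and provenance labels for one synthetic specimen."""

    depth: float
    width: float
    main_length: float
    branch_lengths: List[float]
    branch_total_length: float
    total_length: float
    branch_count: int
    branch_angles: List[float]
    branch_azimuths: List[float]        # radians, per branch
    branch_insertions: np.ndarray       # (n, 3) world points on the main axis
    main_volume: float
    main_surface_area: float
    branch_volume: float
    branch_surface_area: float
    main_diameter: float                # 2*sqrt(V/(pi*L)) of the main axis
    branch_mean_diameter: float
    labels: np.ndarray                  # per returned point, P_* codes
    main_polyline: np.ndarray = field(repr=False, default=None)
    main_radii: np.ndarray = field(repr=False, default=None)
    branch_polylines: List[np.ndarray] = field(repr=False, default_factory=list)
    branch_radii: List[np.ndarray] = field(repr=False, default_factory=list)


# ------------------------------------------------------------ geometry


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())


def _frusta_volume_area(poly: np.ndarray, radii: np.ndarray):
    d = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    r1, r2 = radii[:-1], radii[1:]
    vol = float((np.pi * d / 3.0 * (r1 ** 2 + r1 * r2 + r2 ** 2)).sum())
    slant = np.sqrt(d ** 2 + (r1 - r2) ** 2)
    area = float((np.pi * (r1 + r2) * slant).sum())
    return vol, area


def _main_polyline(spec: RootSystemSpec, rng) -> Tuple[np.ndarray, np.ndarray]:
    n = max(int(np.ceil(spec.depth / _STEP)), 2)
    s = np.linspace(0.0, spec.depth, n + 1)
    phi1, phi2 = rng.uniform(0, 2 * np.pi, 2)
    lam = spec.wander_wavelength
    amp = spec.wander_amplitude
    x = amp * (np.sin(2 * np.pi * s / lam + phi1) - np.sin(phi1))
    y = amp * (np.sin(2 * np.pi * s / lam + phi2) - np.sin(phi2))
    poly = np.column_stack([x, y, -s])
    radii = spec.base_radius + (spec.tip_radius - spec.base_radius) * \
        (s / spec.depth)
    return poly, radii


def _rotate_toward(d: np.ndarray, target: np.ndarray, alpha: float
                   ) -> np.ndarray:
    """Rotate unit vector d by alpha radians toward unit vector target."""
    c = float(np.dot(d, target))
    if c > 1 - 1e-12:
        return d
    w = target - c * d
    w /= np.linalg.norm(w)
    return d * np.cos(alpha) + w * np.sin(alpha)


def _branch_polyline(origin: np.ndarray, theta_deg: float, azimuth: float,
                     length: float, curvature_deg_per_cm: float
                     ) -> np.ndarray:
    theta = np.radians(theta_deg)
    d = np.array([np.sin(theta) * np.cos(azimuth),
                  np.sin(theta) * np.sin(azimuth),
                  -np.cos(theta)])
    down = np.array([0.0, 0.0, -1.0])
    pts = [origin]
    n = max(int(np.ceil(length / _STEP)), 1)
    ds = length / n
    alpha = np.radians(curvature_deg_per_cm) * ds
    for _ in range(n):
        pts.append(pts[-1] + d * ds)
        if alpha > 0:
            d = _rotate_toward(d, down, alpha)
    return np.asarray(pts)


def _max_pairwise_xy(points: np.ndarray) -> float:
    xy = points[:, :2]
    if len(xy) > 8:
        try:
            xy = xy[ConvexHull(xy).vertices]
        except QhullError:
            pass
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


# ------------------------------------------------------------ sampling


def _ortho_frame(d: np.ndarray):
    d = d / np.linalg.norm(d)
    helper = np.eye(3)[np.argmin(np.abs(d))]
    n1 = np.cross(d, helper)
    n1 /= np.linalg.norm(n1)
    return n1, np.cross(d, n1)


def _sample_tube(poly: np.ndarray, radii: np.ndarray, density: float, rng,
                 cap_start: bool = True, cap_end: bool = True) -> np.ndarray:
    """Poisson-sampled points on a tube surface around a polyline."""
    out = []
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    for i, (p1, d, h) in enumerate(zip(poly[:-1], seg, seg_len)):
        if h == 0:
            continue
        r1, r2 = radii[i], radii[i + 1]
        slant = np.sqrt(h ** 2 + (r1 - r2) ** 2)
        n = rng.poisson(density * np.pi * (r1 + r2) * slant)
        if n == 0:
            continue
        u = rng.uniform(0, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        n1, n2 = _ortho_frame(d)
        r = r1 + (r2 - r1) * u
        centers = p1 + np.outer(u, d)
        out.append(centers + r[:, None] *
                   (np.outer(np.cos(phi), n1) + np.outer(np.sin(phi), n2)))
    for cap, idx, nb in ((cap_start, 0, 1), (cap_end, -1, -2)):
        if not cap:
            continue
        r = radii[idx]
        n = rng.poisson(density * np.pi * r ** 2)
        if n == 0:
            continue
        d = poly[idx] - poly[nb]
        n1, n2 = _ortho_frame(d)
        rr = r * np.sqrt(rng.uniform(0, 1, n))
        phi = rng.uniform(0, 2 * np.pi, n)
        out.append(poly[idx] + rr[:, None] *
                   (np.outer(np.cos(phi), n1) + np.outer(np.sin(phi), n2)))
    if not out:
        return np.zeros((0, 3))
    return np.vstack(out)


# ------------------------------------------------------------ generation


def generate(spec: RootSystemSpec) -> Tuple[PointCloud, GroundTruth]:
    """Build one synthetic specimen: surface point cloud plus ground truth.

    Fully deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    main_poly, main_radii = _main_polyline(spec, rng)
    main_len = _polyline_length(main_poly)

    # branch geometry
    n_b = spec.n_branches
    lo, hi = spec.insertion_range
    fractions = np.sort(rng.uniform(lo, hi, n_b)) if n_b else np.zeros(0)
    golden = np.radians(137.508)
    azimuths = (np.arange(n_b) * golden + rng.uniform(0, 2 * np.pi)) \
        % (2 * np.pi)
    angles = spec.branch_angle_deg + \
        rng.uniform(-1, 1, n_b) * spec.branch_angle_jitter
    angles = np.clip(angles, 0.0, 90.0)
    lengths = rng.uniform(*spec.branch_length_range, n_b)

    branch_polys: List[np.ndarray] = []
    branch_radii: List[np.ndarray] = []
    insertions = np.zeros((n_b, 3))
    s_grid = np.linspace(0, spec.depth, len(main_poly))
    for i in range(n_b):
        s_ins = fractions[i] * spec.depth
        j = int(np.searchsorted(s_grid, s_ins))
        j = min(max(j, 1), len(main_poly) - 1)
        w = (s_ins - s_grid[j - 1]) / (s_grid[j] - s_grid[j - 1])
        origin = (1 - w) * main_poly[j - 1] + w * main_poly[j]
        insertions[i] = origin
        poly = _branch_polyline(origin, angles[i], azimuths[i], lengths[i],
                                spec.curvature_deg_per_cm)
        rad = spec.branch_radius + \
            (spec.branch_taper * spec.branch_radius - spec.branch_radius) * \
            np.linspace(0, 1, len(poly))
        branch_polys.append(poly)
        branch_radii.append(rad)

    # exact truth from the centerlines
    branch_lens = [_polyline_length(p) for p in branch_polys]
    all_poly = np.vstack([main_poly] + branch_polys) if branch_polys \
        else main_poly
    truth_depth = float(-all_poly[:, 2].min())
    truth_width = _max_pairwise_xy(all_poly)
    mv, ma = _frusta_volume_area(main_poly, main_radii)
    bv = ba = 0.0
    for p, r in zip(branch_polys, branch_radii):
        v, a = _frusta_volume_area(p, r)
        bv += v
        ba += a
    b_total = float(sum(branch_lens))
    main_diam = 2.0 * np.sqrt(mv / (np.pi * main_len))
    branch_diam = 2.0 * np.sqrt(bv / (np.pi * b_total)) if b_total else \
        float("nan")

    # surface sampling
    pts_main = _sample_tube(main_poly, main_radii, spec.point_density, rng)
    pts_branch = [
        _sample_tube(p, r, spec.point_density, rng, cap_start=False)
        for p, r in zip(branch_polys, branch_radii)
    ]
    pts_branch = np.vstack(pts_branch) if pts_branch else np.zeros((0, 3))

    points = [pts_main, pts_branch]
    labels = [np.full(len(pts_main), P_MAIN, np.int8),
              np.full(len(pts_branch), P_BRANCH, np.int8)]

    n_root = len(pts_main) + len(pts_branch)
    # sparse uniform outliers over the expanded bounding box
    n_out = int(round(spec.outlier_fraction * n_root))
    if n_out:
        box = np.vstack([p for p in points if len(p)])
        lo_b, hi_b = box.min(0), box.max(0)
        pad = 0.2 * (hi_b - lo_b + 1e-6)
        outl = rng.uniform(lo_b - pad, hi_b + pad, (n_out, 3))
        points.append(outl)
        labels.append(np.full(n_out, P_OUTLIER, np.int8))

    # near-black support-mesh clusters at regular depth intervals
    if spec.n_mesh_points > 0:
        depths = np.arange(spec.mesh_spacing, truth_depth,
                           spec.mesh_spacing)
        if len(depths) == 0:
            depths = np.array([truth_depth / 2])
        per = max(spec.n_mesh_points // len(depths), 1)
        mesh_pts = []
        r_mesh = max(truth_width / 2 + 1.0, 3.0)
        for zd in depths:
            rr = r_mesh * np.sqrt(rng.uniform(0.2, 1.0, per))
            phi = rng.uniform(0, 2 * np.pi, per)
            zz = -zd + rng.normal(0, 0.05, per)
            mesh_pts.append(np.column_stack(
                [rr * np.cos(phi), rr * np.sin(phi), zz]))
        mesh_pts = np.vstack(mesh_pts)
        points.append(mesh_pts)
        labels.append(np.full(len(mesh_pts), P_MESH, np.int8))

    pts = np.vstack([p for p in points if len(p)])
    lab = np.concatenate(labels)[: len(pts)]

    if spec.jitter_sd > 0:
        pts = pts + rng.normal(0, spec.jitter_sd, pts.shape)

    # colors: root color with pixel noise; mesh near-black; outliers gray
    cols = np.empty((len(pts), 3), dtype=np.int16)
    cols[:] = spec.root_color
    cols[lab == P_MESH] = spec.mesh_color
    cols[lab == P_OUTLIER] = rng.integers(60, 220, ((lab == P_OUTLIER).sum(),
                                                    3))
    cols = np.clip(cols + rng.integers(-12, 13, cols.shape), 0, 255)

    # mesh-removal fractures: delete everything inside horizontal slabs
    if spec.gap_depths:
        keep = np.ones(len(pts), bool)
        for gd in spec.gap_depths:
            keep &= ~((pts[:, 2] > -gd - spec.gap_thickness / 2) &
                      (pts[:, 2] < -gd + spec.gap_thickness / 2))
        pts, cols, lab = pts[keep], cols[keep], lab[keep]

    cloud = PointCloud(pts, cols.astype(np.uint8), frame_oriented=True)
    truth = GroundTruth(
        depth=truth_depth, width=truth_width, main_length=main_len,
        branch_lengths=branch_lens, branch_total_length=b_total,
        total_length=main_len + b_total, branch_count=n_b,
        branch_angles=list(map(float, angles)),
        branch_azimuths=list(map(float, azimuths)),
        branch_insertions=insertions,
        main_volume=mv, main_surface_area=ma,
        branch_volume=bv, branch_surface_area=ba,
        main_diameter=main_diam, branch_mean_diameter=branch_diam,
        labels=lab,
        main_polyline=main_poly, main_radii=main_radii,
        branch_polylines=branch_polys, branch_radii=branch_radii,
    )
    return cloud, truth


def generate_cohort(spec: RootSystemSpec, n: int, seed: int
                    ) -> List[Tuple[PointCloud, GroundTruth]]:
    """n independent specimens with per-specimen seeds derived from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    return [generate(replace(spec, seed=int(s))) for s in child_seeds]


# ------------------------------------------------------------ presets


def taproot_spec(depth: float = 30.0, seed: int = 0, **overrides
                 ) -> RootSystemSpec:
    """Rapeseed-like taproot: one tapering main root with thinner laterals."""
    spec = RootSystemSpec(
        architecture="taproot", depth=depth,
        base_radius=0.45, tip_radius=0.10,
        wander_amplitude=0.5, wander_wavelength=30.0,
        n_branches=6, insertion_range=(0.08, 0.6),
        branch_angle_deg=55.0, branch_angle_jitter=8.0,
        branch_length_range=(0.30 * depth, 0.45 * depth),
        branch_radius=0.16, branch_taper=0.6,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def fibrous_spec(system_depth: float = 25.0, seed: int = 0, **overrides
                 ) -> RootSystemSpec:
    """Maize-like fibrous system: short thick stem bearing unbranched nodal
    roots of similar caliber.  The visible nodal-root count grows with
    plant size (6 at the seedling stage up to 12 when mature), as does the
    below-ground stem length."""
    stem = float(np.clip(0.2 * system_depth, 4.0, 8.0))
    reach = (system_depth - 1.0) / np.cos(np.radians(40.0))
    n_nodal = int(np.clip(round(4 + 0.25 * system_depth), 6, 12))
    spec = RootSystemSpec(
        architecture="fibrous", depth=stem,
        base_radius=0.80, tip_radius=0.70,
        wander_amplitude=0.1, wander_wavelength=20.0,
        n_branches=n_nodal, insertion_range=(0.1, 0.9),
        branch_angle_deg=40.0, branch_angle_jitter=8.0,
        branch_length_range=(0.9 * reach, 1.1 * reach),
        branch_radius=0.30, branch_taper=0.6,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


# ------------------------------------------------------------ oracles


def voxel_truth_labels(grid: VoxelGrid, truth: GroundTruth) -> np.ndarray:
    """Ground-truth {BACKGROUND, MAIN, LATERAL} labels for a voxel grid.

    An on-voxel is MAIN when its center lies within the main-axis tube
    (local radius plus half a voxel diagonal, i.e. the voxel intersects the
    tube); remaining on-voxels are LATERAL.  Returns an int8 array matching
    ``grid.occupancy`` using the segmentation label codes.
    """
    from .segmentation import LATERAL, MAIN  # avoid import cycle

    # densify the main axis so nearest-sample radius lookup is accurate
    poly, radii = truth.main_polyline, truth.main_radii
    dense_p, dense_r = [], []
    for i in range(len(poly) - 1):
        seg = poly[i + 1] - poly[i]
        n = max(int(np.ceil(np.linalg.norm(seg) / (grid.cell_size / 2))), 1)
        w = np.linspace(0, 1, n, endpoint=False)
        dense_p.append(poly[i] + np.outer(w, seg))
        dense_r.append(radii[i] + w * (radii[i + 1] - radii[i]))
    dense_p.append(poly[-1:])
    dense_r.append(radii[-1:])
    dense_p = np.vstack(dense_p)
    dense_r = np.concatenate(dense_r)

    labels = np.zeros(grid.shape, dtype=np.int8)
    idx = np.argwhere(grid.occupancy)
    centers = grid.voxel_centers(idx)
    dist, nearest = cKDTree(dense_p).query(centers)
    margin = 0.5 * np.sqrt(3) * grid.cell_size
    is_main = dist <= dense_r[nearest] + margin
    labels[idx[:, 0], idx[:, 1], idx[:, 2]] = np.where(is_main, MAIN, LATERAL)
    return labels


def sample_cylinder_cloud(radius: float, length: float,
                          density: float = 3000.0, seed: int = 0,
                          axis: str = "z") -> PointCloud:
    """Dense surface cloud of a capped vertical (or x-aligned) cylinder."""
    rng = np.random.default_rng(seed)
    poly = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -length]])
    pts = _sample_tube(poly, np.array([radius, radius]), density, rng)
    if axis == "x":
        pts = pts[:, [2, 1, 0]]
    return PointCloud(pts, frame_oriented=True)


def tube_grid(radius: float, length: float, cell: float,
              axis: int = 2) -> VoxelGrid:
    """Rasterized solid cylinder: voxel on iff its center is inside."""
    n_r = int(np.ceil(radius / cell)) + 2
    n_l = int(np.ceil(length / cell))
    shape = [2 * n_r + 1] * 3
    shape[axis] = n_l
    occ = np.zeros(shape, bool)
    ax0, ax1 = [a for a in range(3) if a != axis]
    ii = (np.arange(shape[ax0]) + 0.5 - shape[ax0] / 2) * cell
    jj = (np.arange(shape[ax1]) + 0.5 - shape[ax1] / 2) * cell
    disc = ii[:, None] ** 2 + jj[None, :] ** 2 <= radius ** 2
    occ = np.moveaxis(
        np.broadcast_to(disc, (n_l,) + disc.shape).copy(), 0, axis)
    return VoxelGrid(occ, cell, np.zeros(3))
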
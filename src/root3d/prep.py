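"""Cleaning, scaling, and orienting raw root point clouds.

Raw photogrammetry clouds of excavated root systems carry three artifacts:
the black support mesh (removed by color), sparse reconstruction outliers
(removed by a k-NN statistical filter), and an arbitrary scale/orientation
(fixed by a known reference distance and a user-supplied up vector).  All
cleaning operations return subsets of the input points in input order.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import MissingColorError, ParameterError

__all__ = [
    "remove_by_color",
    "remove_outliers_statistical",
    "scale_to_reference",
    "orient_up",
]

DEFAULT_COLOR_THRESHOLD = 40.0  # Euclidean RGB distance on the 0-255 scale
DEFAULT_SOR_K = 10
DEFAULT_SOR_N_STD = 2.0


def remove_by_color(cloud: PointCloud, reference_color,
                    threshold: float = DEFAULT_COLOR_THRESHOLD) -> PointCloud:
    """Drop every point whose RGB color is within ``threshold`` of a reference.

    Used to delete the matte-black support mesh: keeps the points whose
    Euclidean RGB distance to ``reference_color`` is strictly greater than
    ``threshold``.  Point order is preserved.
    """
    if not cloud.has_colors:
        raise MissingColorError(
            "cloud has no colors; skip the color-based mesh removal stage"
        )
    if threshold < 0:
        raise ParameterError("color threshold must be non-negative")
    ref = np.asarray(reference_color, dtype=np.float64)
    if ref.shape != (3,):
        raise ParameterError("reference_color must be an (r, g, b) triple")
    dist = np.linalg.norm(cloud.colors.astype(np.float64) - ref, axis=1)
    return cloud.select(dist > threshold)


def remove_outliers_statistical(cloud: PointCloud, k: int = DEFAULT_SOR_K,
                                n_std: float = DEFAULT_SOR_N_STD) -> PointCloud:
    """Statistical outlier removal by mean k-nearest-neighbor distance.

    Each point's mean distance to its ``k`` nearest neighbors is compared to
    the global distribution; points above ``mean + n_std * std`` are removed.
    """
    n = len(cloud)
    if k <= 0 or k >= n:
        raise ParameterError(f"k must satisfy 0 < k < N (k={k}, N={n})")
    tree = cKDTree(cloud.points)
    # k+1 because the nearest neighbor of each point is itself
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    cutoff = mean_d.mean() + n_std * mean_d.std()
    return cloud.select(mean_d <= cutoff)


def scale_to_reference(cloud: PointCloud, p1, p2,
                       known_distance: float) -> PointCloud:
    """Rescale so two reference points end up ``known_distance`` cm apart.

    The reference points are typically two features on a support-mesh disc of
    known diameter; all coordinates are multiplied by
    ``known_distance / |p1 - p2|``.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    if known_distance <= 0:
        raise ParameterError("known_distance must be positive")
    current = np.linalg.norm(p1 - p2)
    if current == 0:
        raise ParameterError("reference points are coincident")
    factor = known_distance / current
    return cloud.with_points(cloud.points * factor)


def orient_up(cloud: PointCloud, up_vector) -> PointCloud:
    """Rotate the cloud so ``up_vector`` maps to +z (growth along -z).

    Applies the minimal rotation (axis = up x z); the degenerate case
    up = -z is resolved by a 180 degree rotation about x.  Rigid: all
    pairwise distances are preserved.
    """
    up = np.asarray(up_vector, dtype=np.float64)
    norm = np.linalg.norm(up)
    if norm == 0:
        raise ParameterError("up_vector must be nonzero")
    u = up / norm
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(u, z))
    if np.isclose(c, 1.0):
        rot = np.eye(3)
    elif np.isclose(c, -1.0):
        rot = np.diag([1.0, -1.0, -1.0])  # 180 degrees about x
    else:
        axis = np.cross(u, z)
        s = np.linalg.norm(axis)
        axis = axis / s
        kx, ky, kz = axis
        kmat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
        rot = np.eye(3) + s * kmat + (1 - c) * (kmat @ kmat)
    return cloud.with_points(cloud.points @ rot.T, frame_oriented=True)


def depth_below_base(cloud: PointCloud) -> np.ndarray:
    """Per-point depth (cm) below the root base (highest remaining point)."""
    return cloud.points[:, 2].max() - cloud.points[:, 2]


def estimate_surface_noise(cloud: PointCloud, k: int = 12,
                           max_sample: int = 4000, seed: int = 0) -> float:
    """Estimate the surface-noise standard deviation (cm) of a surface cloud.

    For each of up to ``max_sample`` points, a local plane is fit by PCA over
    the k nearest neighbors; the median out-of-plane standard deviation
    (sqrt of the smallest covariance eigenvalue) estimates the sensor jitter.
    Used to correct the dilation of voxel volumes built from surface clouds.
    """
    pts = cloud.points
    n = len(pts)
    if n <= k + 1:
        return 0.0
    rng = np.random.default_rng(seed)
    sample = pts if n <= max_sample else \
        pts[rng.choice(n, max_sample, replace=False)]
    tree = cKDTree(pts)
    _, idx = tree.query(sample, k=k + 1)
    neigh = pts[idx]                       # (m, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("mki,mkj->mij", centered, centered) / (k + 1)
    eig = np.linalg.eigvalsh(cov)          # ascending
    return float(np.median(np.sqrt(np.maximum(eig[:, 0], 0.0))))
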
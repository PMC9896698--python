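"""Synthetic-cohort recovery studies.

Runs the full extraction pipeline on generated specimens with known ground
truth and summarizes recovery accuracy: relative RMSE for main/branch traits,
coefficients of determination for depth, width and total root length, and
voxel-level precision/recall of the main-root segmentation.  Shared by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .cloud import PointCloud
from .global_traits import depth_width, total_root_length
from .local_traits import local_trait_table
from .prep import estimate_surface_noise, remove_outliers_statistical
from .segmentation import MAIN, bridge_gaps, segment_main, slice_stack
from .skeleton import skeletonize_grid
from .synthetic import (GroundTruth, RootSystemSpec, fibrous_spec, generate,
                        taproot_spec, voxel_truth_labels)
from .voxel import fill_internal_cavities, voxelize

__all__ = [
    "cohort_specs", "process_specimen", "run_cohort", "cohort_metrics",
    "segmentation_recovery", "rrmse", "r_squared",
]

# study conditions: 5 size stages per architecture, 3 replicates each
TAPROOT_STAGES = (12.0, 24.0, 36.0, 48.0, 60.0)
FIBROUS_STAGES = (10.0, 17.0, 24.0, 31.0, 38.0)
REPLICATES = 3
DEFAULT_CELL = 0.1


def rrmse(estimated, truth) -> float:
    """Relative RMSE in percent: RMSE / mean(truth) * 100."""
    e = np.asarray(estimated, float)
    t = np.asarray(truth, float)
    return float(100.0 * np.sqrt(np.mean((e - t) ** 2)) / np.mean(t))


def r_squared(estimated, truth) -> float:
    """Squared Pearson correlation of extracted vs true values."""
    e = np.asarray(estimated, float)
    t = np.asarray(truth, float)
    return float(np.corrcoef(e, t)[0, 1] ** 2)


def cohort_specs(seed: int) -> List[RootSystemSpec]:
    """The 30-specimen validation cohort: 15 taproot + 15 fibrous specimens
    across 5 size stages, low-noise preset, straight branches."""
    n = (len(TAPROOT_STAGES) + len(FIBROUS_STAGES)) * REPLICATES
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    specs = []
    i = 0
    for depth in TAPROOT_STAGES:
        for _ in range(REPLICATES):
            specs.append(taproot_spec(depth=depth, seed=int(seeds[i])))
            i += 1
    for depth in FIBROUS_STAGES:
        for _ in range(REPLICATES):
            specs.append(fibrous_spec(system_depth=depth,
                                      seed=int(seeds[i])))
            i += 1
    return specs


def process_specimen(cloud: PointCloud, truth: GroundTruth,
                     cell: float = DEFAULT_CELL) -> Dict[str, float]:
    """Run prep -> voxelize -> segment -> traits on one specimen and compare
    against its ground truth."""
    clean = remove_outliers_statistical(cloud)
    grid = fill_internal_cavities(voxelize(clean, cell))

    depth, width, _ = depth_width(clean)
    skel = skeletonize_grid(grid)
    trl = total_root_length(skel)
    noise_sd = estimate_surface_noise(clean)

    labels = bridge_gaps(segment_main(slice_stack(grid)))
    local, branches = local_trait_table(labels, grid, noise_sd=noise_sd)

    # voxel-level main-root precision/recall against the analytic tube
    tl = voxel_truth_labels(grid, truth)
    on = grid.occupancy
    pred_main = labels.labels[on] == MAIN
    true_main = tl[on] == MAIN
    tp = int((pred_main & true_main).sum())
    precision = tp / max(int(pred_main.sum()), 1)
    recall = tp / max(int(true_main.sum()), 1)

    # per-branch angle pairs, matched by start point vs true insertion
    angle_pairs = _match_angles(branches, truth)

    return {
        "depth_est": depth, "depth_true": truth.depth,
        "width_est": width, "width_true": truth.width,
        "trl_est": trl, "trl_true": truth.total_length,
        "main_length_est": local.main_length,
        "main_length_true": truth.main_length,
        "main_diameter_est": local.main_diameter,
        "main_diameter_true": truth.main_diameter,
        "branch_length_est": local.branch_total_length,
        "branch_length_true": truth.branch_total_length,
        "branch_diameter_est": local.branch_mean_diameter,
        "branch_diameter_true": truth.branch_mean_diameter,
        "branch_count_est": local.branch_count,
        "branch_count_true": truth.branch_count,
        "angle_pairs": angle_pairs,
        "main_precision": precision,
        "main_recall": recall,
        "n_main_tp": tp,
        "n_main_pred": int(pred_main.sum()),
        "n_main_true": int(true_main.sum()),
    }


def _match_angles(branches, truth: GroundTruth,
                  max_match_distance: float = 1.5
                  ) -> List[Tuple[float, float]]:
    """Pair extracted emerging segments with true branches.

    Each extracted segment starts roughly ``start_gap`` cm from the main
    axis along its branch direction, so the expected start point of true
    branch j for that segment is insertion_j + direction_j * start_gap.
    Greedy unique assignment by smallest start-to-expected-start distance.
    """
    n_t = len(truth.branch_insertions)
    if n_t == 0 or len(branches) == 0:
        return []
    rows = branches[branches["emerging"]
                    & np.isfinite(branches["initial_angle"])]
    if len(rows) == 0:
        return []
    theta = np.radians(np.asarray(truth.branch_angles))
    az = np.asarray(truth.branch_azimuths)
    dirs = np.column_stack([np.sin(theta) * np.cos(az),
                            np.sin(theta) * np.sin(az),
                            -np.cos(theta)])
    starts = rows[["start_x", "start_y", "start_z"]].to_numpy()
    gaps = rows["start_gap"].to_numpy()
    expected = truth.branch_insertions[None, :, :] + \
        dirs[None, :, :] * gaps[:, None, None]     # (n_seg, n_t, 3)
    dist = np.linalg.norm(expected - starts[:, None, :], axis=2)
    pairs = []
    used_seg, used_t = set(), set()
    for flat in np.argsort(dist, axis=None):
        i, j = np.unravel_index(flat, dist.shape)
        if dist[i, j] > max_match_distance:
            break
        if i in used_seg or j in used_t:
            continue
        used_seg.add(i)
        used_t.add(j)
        pairs.append((float(rows["initial_angle"].iloc[i]),
                      float(truth.branch_angles[j])))
    return pairs


def run_cohort(seed: int, cell: float = DEFAULT_CELL,
               specs: Optional[List[RootSystemSpec]] = None
               ) -> List[Dict[str, float]]:
    """Generate and process the validation cohort; one record per specimen."""
    if specs is None:
        specs = cohort_specs(seed)
    records = []
    for spec in specs:
        cloud, truth = generate(spec)
        records.append(process_specimen(cloud, truth, cell=cell))
    return records


def cohort_metrics(seed: int, cell: float = DEFAULT_CELL,
                   records: Optional[List[Dict[str, float]]] = None
                   ) -> Dict[str, float]:
    """Pooled recovery metrics over the validation cohort.

    rRMSEs are percent (RMSE over the cohort divided by the truth mean);
    r^2 values are squared Pearson correlations of extracted vs true.
    """
    if records is None:
        records = run_cohort(seed, cell=cell)

    def col(name):
        return np.array([r[name] for r in records])

    angle_pairs = [p for r in records for p in r["angle_pairs"]]
    est_a = [p[0] for p in angle_pairs]
    true_a = [p[1] for p in angle_pairs]

    metrics = {
        "n_specimens": len(records),
        "rrmse_main_length": rrmse(col("main_length_est"),
                                   col("main_length_true")),
        "rrmse_main_diameter": rrmse(col("main_diameter_est"),
                                     col("main_diameter_true")),
        "rrmse_branch_length": rrmse(col("branch_length_est"),
                                     col("branch_length_true")),
        "rrmse_branch_diameter": rrmse(col("branch_diameter_est"),
                                       col("branch_diameter_true")),
        "rrmse_branch_angle": rrmse(est_a, true_a),
        "n_angle_pairs": len(angle_pairs),
        "r2_depth": r_squared(col("depth_est"), col("depth_true")),
        "r2_width": r_squared(col("width_est"), col("width_true")),
        "r2_trl": r_squared(col("trl_est"), col("trl_true")),
        "mean_main_precision": float(col("main_precision").mean()),
        "mean_main_recall": float(col("main_recall").mean()),
    }
    metrics["rrmse_main_pooled"] = max(metrics["rrmse_main_length"],
                                       metrics["rrmse_main_diameter"])
    metrics["rrmse_branch_pooled"] = max(metrics["rrmse_branch_length"],
                                         metrics["rrmse_branch_diameter"],
                                         metrics["rrmse_branch_angle"])
    metrics["r2_depth_width_min"] = min(metrics["r2_depth"],
                                        metrics["r2_width"])
    return metrics


def segmentation_recovery(seed: int, n_seeds: int = 20,
                          depth: float = 30.0,
                          cell: float = DEFAULT_CELL) -> Dict[str, float]:
    """Voxel-level MAIN precision/recall pooled over a taproot cohort
    (6 laterals, lateral radius ~36% of the main base radius)."""
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2 ** 31)
    tp = n_pred = n_true = 0
    per_p, per_r = [], []
    for s in seeds:
        spec = taproot_spec(depth=depth, seed=int(s))
        cloud, truth = generate(spec)
        grid = fill_internal_cavities(voxelize(
            remove_outliers_statistical(cloud), cell))
        labels = bridge_gaps(segment_main(slice_stack(grid)))
        tl = voxel_truth_labels(grid, truth)
        on = grid.occupancy
        pred = labels.labels[on] == MAIN
        true = tl[on] == MAIN
        t = int((pred & true).sum())
        tp += t
        n_pred += int(pred.sum())
        n_true += int(true.sum())
        per_p.append(t / max(int(pred.sum()), 1))
        per_r.append(t / max(int(true.sum()), 1))
    return {
        "precision_pooled": tp / max(n_pred, 1),
        "recall_pooled": tp / max(n_true, 1),
        "precision_min": float(np.min(per_p)),
        "recall_min": float(np.min(per_r)),
        "n_seeds": n_seeds,
    }
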
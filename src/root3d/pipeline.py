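"""End-to-end orchestration: prep -> voxelize -> traits -> RLD -> segment ->
local traits, with a validated config, per-stage artifacts, and a run
manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cloud import PointCloud, load_cloud, save_cloud
from .density import DEFAULT_BIN, DEFAULT_CUBE_VOLUME, RLDResult, rld_cubes
from .errors import ParameterError, PipelineStageError
from .global_traits import GlobalTraits, global_trait_table
from .local_traits import LocalTraits, local_trait_table
from .prep import (orient_up, remove_by_color, remove_outliers_statistical,
                   scale_to_reference)
from .segmentation import (RootLabels, bridge_gaps, segment_main, slice_stack)
from .skeleton import skeletonize_grid
from .voxel import (DEFAULT_CELL_SIZE, VoxelGrid, fill_internal_cavities,
                    save_grid, voxelize)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "save_labels", "load_labels"]


@dataclass
class PipelineConfig:
    """All pipeline parameters with defaults; round-trips through YAML."""

    input: Optional[str] = None
    output_dir: str = "root3d_out"
    # prep
    remove_color: bool = False
    reference_color: Tuple[int, int, int] = (20, 20, 20)
    color_threshold: float = 40.0
    sor_k: int = 10
    sor_n_std: float = 2.0
    scale_p1: Optional[Tuple[float, float, float]] = None
    scale_p2: Optional[Tuple[float, float, float]] = None
    scale_distance: Optional[float] = None
    up_vector: Optional[Tuple[float, float, float]] = None
    # voxelize
    cell_size: float = DEFAULT_CELL_SIZE
    fill_cavities: bool = True
    # segmentation
    dilate_fraction: float = 0.10
    opening_start_factor: float = 0.5
    opening_max_factor: float = 2.0
    max_gap_layers: int = 5
    # local traits
    angle_offset: int = 10
    angle_offset_hi: int = 20
    # density
    cube_volume: float = DEFAULT_CUBE_VOLUME
    cube_edge: Optional[float] = None
    vertical_bin: float = DEFAULT_BIN
    horizontal_bin: float = DEFAULT_BIN
    # run
    seed: int = 0
    cache: bool = True

    def validate(self) -> None:
        if self.cell_size <= 0:
            raise ParameterError("cell_size must be positive")
        if self.dilate_fraction < 0:
            raise ParameterError("dilate_fraction must be >= 0")
        if self.max_gap_layers < 0:
            raise ParameterError("max_gap_layers must be >= 0")
        if self.angle_offset < 1:
            raise ParameterError("angle_offset must be >= 1")
        if self.cube_volume is not None and self.cube_volume <= 0 \
                and self.cube_edge is None:
            raise ParameterError("cube_volume must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v)
                     for k, v in data.items()})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d.items()}

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    global_traits: GlobalTraits
    local_traits: LocalTraits
    rld: RLDResult
    labels: Optional[RootLabels]
    manifest: dict
    output_dir: Path
    cloud: Optional[PointCloud] = None
    grid: Optional[VoxelGrid] = None


def save_labels(labels: RootLabels, path) -> None:
    np.savez_compressed(
        path, labels=labels.labels,
        bridged=np.packbits(labels.bridged),
        cell_size=labels.cell_size, origin=labels.origin,
        terminated=-1 if labels.terminated_layer is None
        else labels.terminated_layer,
    )


def load_labels(path) -> RootLabels:
    with np.load(path) as d:
        lab = d["labels"]
        bridged = np.unpackbits(d["bridged"])[: lab.size].reshape(
            lab.shape).astype(bool)
        term = int(d["terminated"])
        return RootLabels(lab, bridged, float(d["cell_size"]), d["origin"],
                          None if term < 0 else term)


def run_pipeline(config: PipelineConfig,
                 cloud: Optional[PointCloud] = None) -> PipelineResult:
    """Run the full trait-extraction pipeline and write per-stage artifacts.

    ``cloud`` may be passed directly (e.g. from the synthetic generator);
    otherwise it is loaded from ``config.input``.  Reruns with an unchanged
    config and cache enabled reuse the written trait tables.
    """
    config.validate()
    if cloud is None and config.input is None:
        raise ParameterError("config.input is required when no cloud is "
                             "passed")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    cfg_hash = config.config_hash()

    if config.cache and manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = {}
        if previous.get("config_hash") == cfg_hash and \
                (out / "traits_global.json").exists():
            return _load_cached(out, previous)

    timings = {}
    manifest = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "root3d_version": __version__,
        "numpy_version": np.__version__,
        "stages": timings,
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    manifest["failed_stage"] = name
                    manifest_path.write_text(json.dumps(manifest, indent=2))
                    raise PipelineStageError(name, exc) from exc
        return _Timer()

    with stage("load"):
        if cloud is None:
            if config.input is None:
                raise ParameterError("config.input is required when no cloud "
                                     "is passed")
            cloud = load_cloud(config.input)

    with stage("prep"):
        if config.remove_color:
            cloud = remove_by_color(cloud, config.reference_color,
                                    config.color_threshold)
        if config.sor_k > 0:
            cloud = remove_outliers_statistical(cloud, config.sor_k,
                                                config.sor_n_std)
        if config.scale_p1 is not None and config.scale_p2 is not None \
                and config.scale_distance is not None:
            cloud = scale_to_reference(cloud, config.scale_p1,
                                       config.scale_p2,
                                       config.scale_distance)
        if config.up_vector is not None:
            cloud = orient_up(cloud, config.up_vector)
        save_cloud(cloud, out / "prep.ply")

    with stage("voxelize"):
        grid = voxelize(cloud, config.cell_size)
        if config.fill_cavities:
            grid = fill_internal_cavities(grid)
        save_grid(grid, out / "grid.npz")

    with stage("global_traits"):
        skeleton = skeletonize_grid(grid)
        gtraits = global_trait_table(cloud, grid, skeleton)
        _write_traits(gtraits.to_dict(), out / "traits_global")

    with stage("density"):
        rld = rld_cubes(skeleton, cube_edge=config.cube_edge,
                        cube_volume=config.cube_volume,
                        profile_bin=config.vertical_bin)
        rld.cubes.to_csv(out / "rld_cubes.csv", index=False)
        rld.vertical_profile.to_csv(out / "rld_vertical.csv", index=False)
        rld.horizontal_profile.to_csv(out / "rld_horizontal.csv", index=False)

    with stage("segmentation"):
        labels = segment_main(
            slice_stack(grid),
            dilate_fraction=config.dilate_fraction,
            opening_start_factor=config.opening_start_factor,
            opening_max_factor=config.opening_max_factor,
        )
        labels = bridge_gaps(labels, config.max_gap_layers)
        save_labels(labels, out / "labels.npz")

    with stage("local_traits"):
        from .prep import estimate_surface_noise
        ltraits, branches = local_trait_table(
            labels, grid, offset=config.angle_offset,
            offset_hi=config.angle_offset_hi,
            noise_sd=estimate_surface_noise(cloud))
        d = ltraits.to_dict()
        d["initial_angles"] = list(map(float, d["initial_angles"]))
        _write_traits(d, out / "traits_local")
        branches.to_csv(out / "branches.csv", index=False)

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return PipelineResult(gtraits, ltraits, rld, labels, manifest, out,
                          cloud=cloud, grid=grid)


def _write_traits(d: dict, stem: Path) -> None:
    stem.with_suffix(".json").write_text(json.dumps(d, indent=2, default=str))
    flat = {k: v for k, v in d.items() if not isinstance(v, (list, dict))}
    pd.DataFrame([flat]).to_csv(stem.with_suffix(".csv"), index=False)


def _load_cached(out: Path, manifest: dict) -> PipelineResult:
    gdict = json.loads((out / "traits_global.json").read_text())
    ldict = json.loads((out / "traits_local.json").read_text())
    ldict["initial_angles"] = [float(a) for a in
                               ldict.get("initial_angles", [])]
    rld = RLDResult(
        cube_edge=float("nan"),
        cubes=pd.read_csv(out / "rld_cubes.csv"),
        vertical_profile=pd.read_csv(out / "rld_vertical.csv"),
        horizontal_profile=pd.read_csv(out / "rld_horizontal.csv"),
        base_position=np.full(3, np.nan),
        total_length=gdict["total_root_length"],
    )
    return PipelineResult(
        GlobalTraits(**{k: float(v) for k, v in gdict.items()}),
        LocalTraits(**ldict), rld, None, manifest, out)
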
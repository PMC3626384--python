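"""End-to-end orchestration of the three-step segmentation.

noise subtraction -> ventilation clustering -> airway removal -> VLV, with
structured logging, reproducible seeding, and optional intermediate-mask
output.  Configurable from a TOML file mirrored by CLI flags (flags win).
"""

from __future__ import annotations

import json
import logging
import os
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import airway_removal, noise_subtraction, quantification_stats, ventilation_clustering
from .airway_removal import SeedSpec, load_seed_specs
from .image_io import ImageStack, MaskStack, read_stack, write_mask

logger = logging.getLogger("heliovent")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_pipeline_arrays"]


@dataclass
class PipelineConfig:
    """All pipeline parameters with their documented defaults.

    Geometry and the method constants (25x50 noise box, C=4 clusters, m=2,
    50-pixel area filter) default to the values the method was designed
    with; the remaining knobs (epsilon, iteration caps, disk radius,
    stopping rule) are open choices documented in the methods note.
    """

    input_path: str = ""
    input_format: str = "nifti"
    seeds_path: str | None = None
    output_dir: str | None = None
    keep_intermediates: bool = False
    subject_id: str = ""
    # geometry overrides (None -> from header / package defaults)
    in_plane_mm: float | None = None
    slice_thickness_mm: float | None = None
    slice_gap_mm: float = 0.0
    # noise subtraction
    noise_box_rows: int = noise_subtraction.BOX_ROWS
    noise_box_cols: int = noise_subtraction.BOX_COLS
    noise_clamp_g: bool = False
    # clustering
    n_clusters: int = 4
    fuzziness: float = 2.0
    epsilon: float = 1e-5
    max_iter: int = 100
    cluster_seed: int = 0
    cluster_backend: str = "fcm"
    whole_image_clustering: bool = False
    # airway removal
    stop_delta: float | None = None  # None -> max(0.2 * seed value, 2 * sigma_hat)
    disk_radius: int = airway_removal.DISK_RADIUS
    min_area: int = airway_removal.MIN_AREA
    grow_on: str = "image"

    @classmethod
    def from_toml(cls, path: str | os.PathLike, **overrides: Any) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    final: MaskStack
    initial: MaskStack
    refined: MaskStack
    label_map: np.ndarray
    fits: list[noise_subtraction.NoiseFit]
    cluster_model: ventilation_clustering.ClusterModel
    vlv: quantification_stats.VLVResult
    log: list[dict[str, Any]]


def _stage(log: list[dict[str, Any]], name: str, **params: Any) -> None:
    entry = {"stage": name, "time": time.time(), **params}
    log.append(entry)
    logger.info(json.dumps(entry))


def run_pipeline_arrays(
    stack: ImageStack,
    specs: Sequence[SeedSpec] = (),
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the three-step segmentation on an in-memory stack.

    Slices listed in ``specs`` get seeded airway removal; others pass
    through morphological cleanup only.  Identical inputs and config give
    bit-identical outputs.
    """
    cfg = config or PipelineConfig()
    log: list[dict[str, Any]] = []

    _stage(log, "noise_subtraction", box=[cfg.noise_box_rows, cfg.noise_box_cols],
           clamp_g=cfg.noise_clamp_g)
    try:
        fits = noise_subtraction.fit_stack(
            stack, cfg.noise_box_rows, cfg.noise_box_cols, cfg.noise_clamp_g
        )
        initial = noise_subtraction.apply_threshold(stack, fits)
    except Exception as exc:
        raise RuntimeError(f"noise_subtraction stage failed: {exc}") from exc

    _stage(log, "ventilation_clustering", C=cfg.n_clusters, m=cfg.fuzziness,
           epsilon=cfg.epsilon, max_iter=cfg.max_iter, seed=cfg.cluster_seed,
           backend=cfg.cluster_backend)
    try:
        model = ventilation_clustering.cluster_stack(
            stack,
            initial,
            n_clusters=cfg.n_clusters,
            fuzziness=cfg.fuzziness,
            epsilon=cfg.epsilon,
            max_iter=cfg.max_iter,
            seed=cfg.cluster_seed,
            backend=cfg.cluster_backend,
            whole_image=cfg.whole_image_clustering,
        )
        refined, label_map = ventilation_clustering.refine_mask(stack, initial, model)
    except Exception as exc:
        raise RuntimeError(f"ventilation_clustering stage failed: {exc}") from exc

    if not specs:
        logger.warning("no airway seeds supplied; applying morphological cleanup only")
    _stage(log, "airway_removal", n_specs=len(specs), disk_radius=cfg.disk_radius,
           min_area=cfg.min_area, stop_delta=cfg.stop_delta, grow_on=cfg.grow_on)
    try:
        # default stopping rule: generous homogeneity bound from the seed's
        # gray value and the slice's fitted noise scale
        stop_deltas = None
        if cfg.stop_delta is None:
            stop_deltas = []
            by_slice = {s.slice_index: s for s in specs}
            for i in range(stack.n_slices):
                spec = by_slice.get(i)
                if spec is None:
                    stop_deltas.append(0.0)
                else:
                    seed_val = float(stack.slices[i][spec.seed])
                    stop_deltas.append(max(0.2 * seed_val, 2.0 * fits[i].sigma))
        final = airway_removal.remove_airways(
            stack,
            refined,
            specs,
            stop_delta=cfg.stop_delta,
            stop_deltas=stop_deltas,
            disk_radius=cfg.disk_radius,
            min_area=cfg.min_area,
            grow_on=cfg.grow_on,
        )
    except Exception as exc:
        raise RuntimeError(f"airway_removal stage failed: {exc}") from exc

    vlv = quantification_stats.compute_vlv(final, cfg.subject_id)
    _stage(log, "quantification", total_l=vlv.total_l,
           taus=[f.tau for f in fits], centers=list(map(float, model.centers)))
    return PipelineResult(
        final=final,
        initial=initial,
        refined=refined,
        label_map=label_map,
        fits=fits,
        cluster_model=model,
        vlv=vlv,
        log=log,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: read inputs, run, write outputs."""
    stack = read_stack(
        config.input_path,
        config.input_format,  # type: ignore[arg-type]
        in_plane_mm=config.in_plane_mm,
        slice_thickness_mm=config.slice_thickness_mm,
        slice_gap_mm=config.slice_gap_mm,
    )
    specs: list[SeedSpec] = []
    if config.seeds_path:
        specs = load_seed_specs(config.seeds_path)
    result = run_pipeline_arrays(stack, specs, config)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mask(result.final, out / "mask_final.nii.gz")
        if config.keep_intermediates:
            write_mask(result.initial, out / "mask_initial.nii.gz")
            write_mask(result.refined, out / "mask_refined.nii.gz")
        (out / "vlv.json").write_text(
            json.dumps(
                {
                    "subject_id": result.vlv.subject_id,
                    "total_l": result.vlv.total_l,
                    "per_slice_ml": list(map(float, result.vlv.per_slice_ml)),
                    "voxel_volume_mm3": result.vlv.voxel_volume_mm3,
                },
                indent=1,
            )
        )
        (out / "run_log.json").write_text(json.dumps(result.log, indent=1))
    return result
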
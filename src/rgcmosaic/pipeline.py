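"""End-to-end pipeline: simulate/load -> detect -> segment -> stats -> fit.

Stages run in the fixed order of the analysis chain; every output CSV
carries a provenance header (tool version, config hash, seed). A stage
failure aborts the run with the failing stage named and removes any partial
outputs so a half-written result directory cannot be mistaken for a
complete one. Deterministic stages are bit-identical on rerun with the same
configuration.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, io, kinetics, mosaic, segmentation, synthetic
from .config import RunConfig, config_hash

__all__ = ["PipelineError", "run_pipeline"]

log = logging.getLogger("rgcmosaic")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured pipeline; returns a map of output name -> path."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config_hash(config), "seed": config.seed}
    log.info("run config hash %s, seed %d", meta["config_hash"], config.seed)
    outputs: dict[str, Path] = {}

    def _register(name: str, path: Path) -> Path:
        outputs[name] = path
        return path

    stage = "configure"
    try:
        params = detection.DetectionParams(
            intensity_threshold=config.intensity_threshold,
            min_diameter_um=config.min_diameter_um,
            max_diameter_um=config.max_diameter_um,
            min_circularity=config.min_circularity,
            highpass_scale_um=config.highpass_scale_um,
            mask_threshold_high=config.mask_threshold_high,
            watershed_depth_px=config.watershed_depth_px,
        )
        if config.synthetic:
            stage = "simulate"
            spec = synthetic.MosaicSpec(
                field_radius_mm=config.field_radius_mm,
                target_density_per_mm2=config.target_density_per_mm2,
                exclusion_radius_um=config.exclusion_radius_um,
                density_gradient=config.density_gradient,
                seed=config.seed,
            )
            sim = synthetic.simulate_retina(
                spec,
                pixel_size_um=config.render_pixel_size_um,
                soma_diameter_um=config.soma_diameter_um,
                peak_intensity=config.peak_intensity,
                background_sd=config.background_sd,
                render_seed=config.seed,
            )
            image, geometry = sim.image, sim.geometry
            io.write_image(_register("image", out_dir / "image.tif"), image)
            io.write_ground_truth(
                _register("ground_truth", out_dir / "ground_truth.csv"), sim.points, meta
            )
        elif config.image is not None:
            stage = "load"
            if config.pixel_size_um is None:
                raise ValueError("pixel_size_um is required for a real image")
            if config.onh_x_px is None or config.onh_y_px is None:
                raise ValueError("ONH centre (onh_x_px, onh_y_px) is required")
            image = io.read_image(config.image)
            mask = detection.make_retina_mask(image, params)
            geometry = detection.RetinaGeometry(
                mask=mask,
                pixel_size_um=config.pixel_size_um,
                onh_xy_px=(config.onh_x_px, config.onh_y_px),
            )
        else:
            raise ValueError("configuration provides neither an image nor synthetic: true")

        stage = "detect"
        cells = detection.detect_cells(image, geometry, params)
        cells_df = pd.DataFrame(detection.cells_to_arrays(cells))
        io.write_cells(_register("cells", out_dir / "cells.csv"), cells_df, meta)
        summary = detection.count_summary(cells, geometry)

        stage = "segment"
        grid = segmentation.SectorGrid(
            ring_width_mm=config.ring_width_mm, n_rings=config.n_rings, eye=config.eye
        )
        xy_mm = cells_df[["x_mm", "y_mm"]].to_numpy()
        stage = "stats"
        stats: dict[str, object] = {
            "total_count": summary.total_count,
            "retina_area_mm2": summary.retina_area_mm2,
            "density_per_mm2": summary.density_per_mm2,
        }
        if len(xy_mm) >= 3:
            nnd_um = mosaic.nearest_neighbour_distances(xy_mm) * 1000.0
            sectors = segmentation.sector_table(xy_mm, geometry, grid, nnd_um)
            io.write_sectors(_register("sectors", out_dir / "sectors.csv"), sectors, meta)
            colour = segmentation.nnd_colormap_export(xy_mm, nnd_um)
            colour.to_csv(_register("nnd_map", out_dir / "nnd_map.csv"), index=False)
            stats.update(
                mean_nnd_um=float(np.mean(nnd_um)),
                regularity_index=mosaic.regularity_index(nnd_um),
            )
        summary_path = _register("summary", out_dir / "summary.json")
        summary_path.write_text(json.dumps({**meta, **stats}, indent=2), encoding="utf-8")

        if config.series is not None:
            stage = "fit"
            series = io.read_series(config.series)
            if config.fit_mode == "two":
                fits = kinetics.sector_kinetics_map(
                    series, config.t_half_fast_days, config.t_half_slow_days
                )
            else:
                fits = kinetics.sector_kinetics_map(series)
            fits.to_csv(_register("fits", out_dir / "fits.csv"), index=False)
    except Exception as exc:  # noqa: BLE001 — stage name + cleanup, then re-raise
        for path in outputs.values():
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return outputs
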
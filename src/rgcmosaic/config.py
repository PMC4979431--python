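"""Run configuration: one flat key-value file driving the whole pipeline.

The config file is flat YAML (``key: value`` per line, no nesting). Unknown
keys are rejected so typos cannot silently fall back to defaults; the CLI
accepts the same keys as overrides and there are no hidden defaults that
differ between CLI and library use.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "config_hash"]


@dataclass
class RunConfig:
    # paths
    image: str | None = None
    cells: str | None = None
    series: str | None = None
    out_dir: str = "rgcmosaic_out"
    # calibration / geometry (required for real images)
    pixel_size_um: float | None = None
    onh_x_px: float | None = None
    onh_y_px: float | None = None
    eye: str = "left"
    # detection parameters
    intensity_threshold: float = 130.0
    min_diameter_um: float = 7.0
    max_diameter_um: float = 21.0
    min_circularity: float = 0.7
    highpass_scale_um: float = 63.0
    mask_threshold_high: float = 5.0
    watershed_depth_px: float = 1.0
    # sector grid
    ring_width_mm: float = 0.3
    n_rings: int = 15
    # kinetics
    fit_mode: str = "one"  # one | two
    t_half_fast_days: float = 1.7
    t_half_slow_days: float = 16.3
    # synthetic input (used when no image path is given)
    synthetic: bool = False
    field_radius_mm: float = 4.1
    target_density_per_mm2: float = 1695.0
    exclusion_radius_um: float = 7.2
    density_gradient: float = 0.0
    soma_diameter_um: float = 12.0
    peak_intensity: float = 200.0
    background_sd: float = 0.0
    render_pixel_size_um: float = 1.0
    # bookkeeping
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected flat key-value pairs")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the full configuration, for output headers."""
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
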
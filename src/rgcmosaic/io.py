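"""Readers and writers: TIFF rasters and CSV tables with provenance headers.

All tables are plain CSV (comma separator, ``.`` decimal, UTF-8, header
row). Writers prepend ``#``-prefixed comment lines carrying the tool
version, a configuration hash and the RNG seed so any output can be traced
back to the run that produced it; readers return those as ``DataFrame.attrs``.
Floats are written at full ``repr`` precision and round-trip exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__

__all__ = [
    "read_image",
    "write_image",
    "read_cells",
    "write_cells",
    "read_sectors",
    "write_sectors",
    "read_series",
    "write_series",
    "write_ground_truth",
    "read_ground_truth",
]

CELL_COLUMNS = [
    "x_px",
    "y_px",
    "x_mm",
    "y_mm",
    "area_um2",
    "mean_intensity",
    "circularity",
    "equivalent_diameter_um",
]
SECTOR_COLUMNS = [
    "ring",
    "quadrant",
    "cell_count",
    "area_mm2",
    "density_per_mm2",
    "mean_nnd_um",
    "ri",
]
SERIES_COLUMNS = ["ring", "quadrant", "day", "density"]


def read_image(path: str | Path) -> np.ndarray:
    """Single-channel 8-bit TIFF -> uint8 array."""
    img = tifffile.imread(str(path))
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise ValueError(f"{path}: expected uint8 data, got {img.dtype}")
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.uint8))


def _write_table(
    path: str | Path,
    table: pd.DataFrame,
    columns: list[str],
    meta: dict[str, object] | None = None,
) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"table missing required columns: {missing}")
    header = {"tool": f"rgcmosaic {__version__}"}
    header.update(table.attrs)
    if meta:
        header.update(meta)
    buf = _io.StringIO()
    for key, value in header.items():
        buf.write(f"# {key}: {value}\n")
    table[columns].to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _read_table(path: str | Path, columns: list[str], what: str) -> pd.DataFrame:
    attrs: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                attrs[key.strip()] = value.strip()
    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(
            f"{path}: not a valid {what} file — missing column(s) {missing}; "
            f"found {list(table.columns)}"
        )
    table.attrs.update(attrs)
    return table


def write_cells(path: str | Path, cells: pd.DataFrame, meta: dict | None = None) -> None:
    _write_table(path, cells, CELL_COLUMNS, meta)


def read_cells(path: str | Path) -> pd.DataFrame:
    return _read_table(path, CELL_COLUMNS, "cells")


def write_sectors(path: str | Path, sectors: pd.DataFrame, meta: dict | None = None) -> None:
    _write_table(path, sectors, SECTOR_COLUMNS, meta)


def read_sectors(path: str | Path) -> pd.DataFrame:
    return _read_table(path, SECTOR_COLUMNS, "sectors")


def write_series(path: str | Path, series: pd.DataFrame, meta: dict | None = None) -> None:
    _write_table(path, series, SERIES_COLUMNS, meta)


def read_series(path: str | Path) -> pd.DataFrame:
    return _read_table(path, SERIES_COLUMNS, "series")


def write_ground_truth(path: str | Path, points_mm: np.ndarray, meta: dict | None = None) -> None:
    """Ground-truth cell centres as (x_mm, y_mm) CSV."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    table = pd.DataFrame({"x_mm": pts[:, 0] if len(pts) else [], "y_mm": pts[:, 1] if len(pts) else []})
    _write_table(path, table, ["x_mm", "y_mm"], meta)


def read_ground_truth(path: str | Path) -> np.ndarray:
    table = _read_table(path, ["x_mm", "y_mm"], "ground truth")
    return table[["x_mm", "y_mm"]].to_numpy()
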
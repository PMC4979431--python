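"""Bundled reference measurements for the rat pONT and OHT models.

Published group-mean whole-retina RGC densities from a longitudinal study of
two rat optic neuropathy models — partial optic nerve transection (pONT,
follow-up to 56 days) and Morrison-type ocular hypertension (OHT, follow-up
to 84 days, with untreated contralateral eyes tracked as well). Naïve
bilaterally-untreated eyes provide the baseline (day 0) density of
1695 RGC/mm². These tables serve as worked-example inputs for the kinetics
module and as the reference values its percentage-loss arithmetic is checked
against (``printed_loss_pct`` is the loss row as published, rounded to
integer percentages).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import DensityTimeSeries

__all__ = [
    "CONTROL_DENSITY_PER_MM2",
    "CONTROL_RGC_COUNT",
    "CONTROL_RI",
    "load_density_table",
    "density_series",
]

#: naïve control whole-retina RGC density, RGC/mm² (mean of 16 eyes)
CONTROL_DENSITY_PER_MM2: float = 1695.0
#: naïve control whole-retina RGC count
CONTROL_RGC_COUNT: float = 82592.0
#: naïve control regularity index (regular mosaic; random ≈ 1.9)
CONTROL_RI: float = 2.86

_ROWS = [
    # model, day, n_eyes, mean_count, density, density_se, printed_loss_pct
    ("pONT", 3, 5, 64844, 1233.0, 78.2, 27),
    ("pONT", 7, 7, 47512, 894.5, 98.4, 47),
    ("pONT", 21, 9, 20957, 404.3, 52.9, 76),
    ("pONT", 56, 5, 25596, 491.7, 120.4, 71),
    ("OHT", 7, 5, 73730, 1404.0, 58.1, 17),
    ("OHT", 21, 9, 67061, 1303.0, 64.9, 23),
    ("OHT", 56, 4, 61058, 1271.0, 59.5, 25),
    ("OHT", 84, 5, 76851, 1298.0, 68.4, 23),
    ("OHT_contralateral", 7, 5, 81274, 1359.0, 74.7, 20),
    ("OHT_contralateral", 21, 5, 83559, 1485.0, 21.9, 12),
    ("OHT_contralateral", 56, 3, 63514, 1283.0, 98.2, 24),
    ("OHT_contralateral", 84, 5, 78384, 1462.0, 89.7, 14),
]


def load_density_table() -> pd.DataFrame:
    """Published longitudinal whole-retina densities, long format.

    Columns: model, day, n_eyes, mean_count, density, density_se,
    printed_loss_pct (percentage loss vs naïve controls as published).
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "model",
            "day",
            "n_eyes",
            "mean_count",
            "density",
            "density_se",
            "printed_loss_pct",
        ],
    )


def density_series(model: str) -> DensityTimeSeries:
    """Whole-retina density time course for one model, with the naïve
    control density as the day-0 baseline observation."""
    table = load_density_table()
    sub = table[table["model"] == model]
    if sub.empty:
        raise ValueError(
            f"unknown model {model!r}; available: {sorted(table['model'].unique())}"
        )
    times = np.concatenate([[0.0], sub["day"].to_numpy(dtype=float)])
    dens = np.concatenate([[CONTROL_DENSITY_PER_MM2], sub["density"].to_numpy(dtype=float)])
    return DensityTimeSeries(times_days=times, densities=dens)
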
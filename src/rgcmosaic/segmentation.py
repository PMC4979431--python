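"""Ring/quadrant segmentation of the retina about the optic nerve head.

Every cell is gated into one of 60 non-overlapping sectors: 15 concentric
rings of fixed width (default 0.3 mm) crossed with the four anatomical
quadrants (Superior, Nasal, Inferior, Temporal), all centred on the optic
nerve head (ONH). Ring 1 is central, ring 15 peripheral; ring intervals are
half-open ``[inner, outer)`` so a cell sitting exactly on a boundary is
counted once. Cells beyond the outermost ring are reported as out-of-grid,
never dropped.

Quadrants are the four 90° wedges whose boundaries are the two diagonals
through the ONH (±45° to the superior axis). Membership can be computed
either from the polar angle or from Cartesian sign/slope tests against the
diagonals; the two give identical results and both are provided (the
Cartesian route is the default, the polar one serves as a cross-check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import RetinaGeometry

__all__ = [
    "QUADRANTS",
    "OUT_OF_GRID",
    "SectorGrid",
    "SectorRegion",
    "radial_distance",
    "assign_sectors",
    "sector_areas",
    "sector_table",
    "nnd_colormap_export",
    "plot_nnd_colormap",
]

QUADRANTS: tuple[str, ...] = ("Superior", "Inferior", "Nasal", "Temporal")

#: ring index reported for cells/pixels beyond the outermost ring
OUT_OF_GRID: int = 0


@dataclass(frozen=True)
class SectorGrid:
    """Ring/quadrant grid centred on the ONH.

    ``superior_angle_deg`` is the direction of the superior axis in the mm
    coordinate frame (90° = +y, the default produced by
    :meth:`RetinaGeometry.px_to_mm` for a superior-at-top image).
    ``eye`` sets the nasal/temporal laterality: for a left eye the nasal
    wedge lies on the +x side of the superior axis, for a right eye on −x.
    """

    onh_xy: tuple[float, float] = (0.0, 0.0)
    ring_width_mm: float = 0.3
    n_rings: int = 15
    superior_angle_deg: float = 90.0
    eye: str = "left"

    def __post_init__(self) -> None:
        if not self.ring_width_mm > 0:
            raise ValueError(f"ring_width_mm must be positive, got {self.ring_width_mm}")
        if self.n_rings < 1:
            raise ValueError(f"n_rings must be >= 1, got {self.n_rings}")
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {self.eye!r}")

    @property
    def outer_radius_mm(self) -> float:
        return self.n_rings * self.ring_width_mm

    def wedge_labels(self) -> tuple[str, str, str, str]:
        """Quadrant labels for wedge indices 0..3 (wedges starting at +45°,
        +135°, +225°, +315° from the lateral axis, counter-clockwise)."""
        if self.eye == "left":
            return ("Superior", "Temporal", "Inferior", "Nasal")
        return ("Superior", "Nasal", "Inferior", "Temporal")


def radial_distance(cell_xy: np.ndarray, onh_xy: tuple[float, float]) -> np.ndarray:
    """Euclidean distance d = sqrt((x-a)^2 + (y-b)^2) of centroids to the ONH."""
    xy = np.atleast_2d(np.asarray(cell_xy, dtype=float))
    return np.hypot(xy[:, 0] - onh_xy[0], xy[:, 1] - onh_xy[1])


def _local_frame(points: np.ndarray, grid: SectorGrid) -> tuple[np.ndarray, np.ndarray]:
    """(u, v) with v along the superior axis and u along the right-hand
    lateral axis, so the superior wedge is the angular range [45°, 135°)."""
    xy = np.atleast_2d(np.asarray(points, dtype=float))
    dx = xy[:, 0] - grid.onh_xy[0]
    dy = xy[:, 1] - grid.onh_xy[1]
    a = np.deg2rad(grid.superior_angle_deg)
    v = dx * np.cos(a) + dy * np.sin(a)
    u = dx * np.sin(a) - dy * np.cos(a)
    return u, v


def _wedge_cartesian(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Wedge index 0..3 by sign/slope tests against the two diagonals v=±u.

    Wedge k covers angles [45°+90k, 135°+90k); each boundary ray belongs to
    the counter-clockwise-following wedge. A point exactly at the origin is
    assigned wedge 3 (the wedge containing angle 0), matching the polar rule.
    """
    out = np.full(u.shape, 3, dtype=np.int64)
    out[(v >= u) & (v > -u)] = 0  # superior
    out[(-u >= v) & (-u > -v)] = 1  # left of superior axis
    out[(-v >= -u) & (-v > u)] = 2  # inferior
    # remaining points (including the origin) are wedge 3
    return out


def _wedge_polar(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Wedge index 0..3 from the polar angle about the ONH."""
    theta = np.degrees(np.arctan2(v, u)) % 360.0
    return (((theta - 45.0) % 360.0) // 90.0).astype(np.int64)


def assign_sectors(
    points: np.ndarray,
    grid: SectorGrid,
    method: str = "cartesian",
) -> pd.DataFrame:
    """Gate each point into (ring, quadrant).

    Returns a DataFrame with columns ``ring`` (1..n_rings, or 0 =
    out-of-grid) and ``quadrant``. ``method`` selects the Cartesian
    sign/slope or the polar-angle quadrant implementation; the two are
    equivalent and either may be used as a cross-check of the other.
    """
    xy = np.atleast_2d(np.asarray(points, dtype=float))
    d = radial_distance(xy, grid.onh_xy)
    ring = np.floor(d / grid.ring_width_mm).astype(np.int64) + 1
    ring[ring > grid.n_rings] = OUT_OF_GRID

    u, v = _local_frame(xy, grid)
    if method == "cartesian":
        wedge = _wedge_cartesian(u, v)
    elif method == "polar":
        wedge = _wedge_polar(u, v)
    else:
        raise ValueError(f"method must be 'cartesian' or 'polar', got {method!r}")
    labels = np.asarray(grid.wedge_labels(), dtype=object)
    return pd.DataFrame({"ring": ring, "quadrant": labels[wedge]})


@dataclass(frozen=True)
class SectorRegion:
    """Predicate over the retina: a ring range crossed with a quadrant set.

    ``rings=None`` means all rings (including out-of-grid), ``quadrants=None``
    all quadrants — so the default selects the whole retina.
    """

    grid: SectorGrid = SectorGrid()
    rings: tuple[int, int] | None = None  # inclusive (lo, hi)
    quadrants: frozenset[str] | None = None

    def contains(self, points: np.ndarray) -> np.ndarray:
        assigned = assign_sectors(points, self.grid)
        mask = np.ones(len(assigned), dtype=bool)
        if self.rings is not None:
            lo, hi = self.rings
            mask &= (assigned["ring"] >= lo) & (assigned["ring"] <= hi)
        if self.quadrants is not None:
            mask &= assigned["quadrant"].isin(self.quadrants).to_numpy()
        return mask


def _sector_index(ring: np.ndarray, quadrant: np.ndarray, grid: SectorGrid) -> pd.MultiIndex:
    return pd.MultiIndex.from_arrays([ring, quadrant], names=["ring", "quadrant"])


def _full_index(grid: SectorGrid) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [range(1, grid.n_rings + 1), QUADRANTS], names=["ring", "quadrant"]
    )


def sector_areas(geometry: RetinaGeometry, grid: SectorGrid) -> pd.DataFrame:
    """Pixel-count area (mm²) of mask ∩ sector for all sectors.

    The sectors partition the mask exactly: the sum of all sector areas plus
    the out-of-grid area (stored in ``DataFrame.attrs['out_of_grid_area_mm2']``)
    equals the total mask area to machine precision.
    """
    onh_px = geometry.mm_to_px([grid.onh_xy])[0]
    iy, ix = int(round(onh_px[1])), int(round(onh_px[0]))
    h, w = geometry.mask.shape
    if not (0 <= ix < w and 0 <= iy < h) or not geometry.mask[iy, ix]:
        warnings.warn("ONH centre falls outside the retina mask", RuntimeWarning, stacklevel=2)

    ys, xs = np.nonzero(geometry.mask)
    px_area = (geometry.pixel_size_um / 1000.0) ** 2
    table = pd.DataFrame(
        {"area_mm2": 0.0}, index=_full_index(grid)
    )
    out_of_grid = 0.0
    if len(xs):
        xy_mm = geometry.px_to_mm(np.column_stack([xs, ys]))
        assigned = assign_sectors(xy_mm, grid)
        in_grid = assigned["ring"] != OUT_OF_GRID
        out_of_grid = float((~in_grid).sum()) * px_area
        counts = (
            assigned[in_grid].groupby(["ring", "quadrant"], observed=True).size()
        )
        for (ring, quad), n in counts.items():
            table.loc[(ring, quad), "area_mm2"] = n * px_area
    table.attrs["out_of_grid_area_mm2"] = out_of_grid
    table.attrs["total_mask_area_mm2"] = float(len(xs)) * px_area
    return table.reset_index()


def sector_table(
    cells_xy_mm: np.ndarray,
    geometry: RetinaGeometry,
    grid: SectorGrid,
    nnd_um: np.ndarray,
) -> pd.DataFrame:
    """Per-sector count, area, density, mean NND and RI (60 rows).

    ``nnd_um`` must be the *globally* computed per-cell NNDs, aligned with
    ``cells_xy_mm``; per-sector NND statistics average these global values
    over the cells gated into the sector (no sector-restricted
    recomputation). Sectors with fewer than 3 cells report an undefined
    (NaN) RI; empty sectors report density 0 and NaN NND. Out-of-grid cell
    count is carried in ``attrs['out_of_grid_count']``.
    """
    xy = np.atleast_2d(np.asarray(cells_xy_mm, dtype=float))
    nnd = np.asarray(nnd_um, dtype=float)
    if len(xy) != len(nnd):
        raise ValueError(f"{len(xy)} cells but {len(nnd)} NND values")

    areas = sector_areas(geometry, grid).set_index(["ring", "quadrant"])
    assigned = assign_sectors(xy, grid)
    in_grid = (assigned["ring"] != OUT_OF_GRID).to_numpy()

    rows = []
    grouped = (
        pd.DataFrame({"ring": assigned["ring"], "quadrant": assigned["quadrant"], "nnd": nnd})
        .loc[in_grid]
        .groupby(["ring", "quadrant"], observed=True)
    )
    stats_by_sector = {key: g["nnd"].to_numpy() for key, g in grouped}
    for ring in range(1, grid.n_rings + 1):
        for quad in QUADRANTS:
            area = float(areas.loc[(ring, quad), "area_mm2"])
            vals = stats_by_sector.get((ring, quad), np.empty(0))
            n = len(vals)
            if n > 0 and area == 0.0:
                raise ValueError(
                    f"sector (ring {ring}, {quad}) has {n} cells but zero mask area; "
                    "geometry and cell coordinates are inconsistent"
                )
            mean_nnd = float(np.mean(vals)) if n else float("nan")
            if n >= 3:
                sd = float(np.std(vals, ddof=1))
                ri = float(np.mean(vals)) / sd if sd > 0 else float("nan")
            else:
                ri = float("nan")
            rows.append(
                {
                    "ring": ring,
                    "quadrant": quad,
                    "cell_count": n,
                    "area_mm2": area,
                    "density_per_mm2": (n / area) if area > 0 else 0.0,
                    "mean_nnd_um": mean_nnd,
                    "ri": ri,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["out_of_grid_count"] = int((~in_grid).sum())
    table.attrs["out_of_grid_area_mm2"] = areas.attrs.get("out_of_grid_area_mm2", 0.0)
    return table


def nnd_colormap_export(cells_xy_mm: np.ndarray, nnd_um: np.ndarray) -> pd.DataFrame:
    """(x, y, NND) triples for colour-mapped scatter plotting."""
    xy = np.atleast_2d(np.asarray(cells_xy_mm, dtype=float))
    nnd = np.asarray(nnd_um, dtype=float)
    if len(xy) != len(nnd):
        raise ValueError(f"{len(xy)} cells but {len(nnd)} NND values")
    return pd.DataFrame({"x_mm": xy[:, 0], "y_mm": xy[:, 1], "nnd_um": nnd})


def plot_nnd_colormap(table: pd.DataFrame, ax=None, point_size: float = 2.0):
    """Scatter of cell centroids coloured by NND, smallest NND = red.

    Small NNDs (dense, intact mosaic) map to the warm end of the scale and
    large NNDs (sparse, depleted regions) to the cool end.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(
        table["x_mm"], table["y_mm"], c=table["nnd_um"], cmap="jet_r", s=point_size
    )
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    plt.colorbar(sc, ax=ax, label="NND (µm)")
    return ax
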
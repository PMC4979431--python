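"""Ring/quadrant sector grid: gating, areas, per-sector statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rgcmosaic import (
    LossPattern,
    MosaicSpec,
    RetinaGeometry,
    SectorGrid,
    SectorRegion,
    apply_loss,
    assign_sectors,
    generate_mosaic,
    nearest_neighbour_distances,
    radial_distance,
    render_image,
    sector_areas,
    sector_table,
)
from rgcmosaic.segmentation import QUADRANTS, nnd_colormap_export


class TestRadialDistance:
    def test_pythagorean_triple(self):
        assert radial_distance([[3.0, 4.0]], (0.0, 0.0))[0] == pytest.approx(5.0)

    def test_zero_at_centre(self):
        assert radial_distance([[1.0, 2.0]], (1.0, 2.0))[0] == 0.0

    @given(arrays(float, (20, 2), elements=st.floats(-10, 10, allow_nan=False)),
           st.floats(-5, 5), st.floats(-5, 5))
    def test_agrees_with_hypot_oracle(self, pts, a, b):
        got = radial_distance(pts, (a, b))
        expected = np.sqrt((pts[:, 0] - a) ** 2 + (pts[:, 1] - b) ** 2)
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestAssignSectors:
    def test_centre_is_ring_one(self):
        out = assign_sectors([[0.0, 0.0]], SectorGrid())
        assert out["ring"].iloc[0] == 1

    def test_half_open_ring_intervals(self):
        grid = SectorGrid(ring_width_mm=0.3)
        # 0.3 <= 0.45 < 0.6 -> ring 2; boundary d=0.3 also ring 2
        assert assign_sectors([[0.45, 0.0]], grid)["ring"].iloc[0] == 2
        assert assign_sectors([[0.3, 0.0]], grid)["ring"].iloc[0] == 2

    def test_beyond_outer_ring_is_out_of_grid(self):
        grid = SectorGrid(ring_width_mm=0.3, n_rings=15)
        assert assign_sectors([[4.6, 0.0]], grid)["ring"].iloc[0] == 0

    def test_cartesian_and_polar_gating_identical(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(-5, 5, size=(10_000, 2))
        grid = SectorGrid(onh_xy=(0.3, -0.2))
        a = assign_sectors(pts, grid, method="cartesian")
        b = assign_sectors(pts, grid, method="polar")
        pd.testing.assert_frame_equal(a, b)

    def test_quadrants_on_axes(self):
        grid = SectorGrid(eye="left")  # superior = +y; nasal on +x for left eye
        pts = [[0.0, 1.0], [0.0, -1.0], [1.0, 0.0], [-1.0, 0.0]]
        quads = assign_sectors(pts, grid)["quadrant"].tolist()
        assert quads == ["Superior", "Inferior", "Nasal", "Temporal"]

    def test_eye_flag_mirrors_nasal_temporal(self):
        pts = [[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]]
        left = assign_sectors(pts, SectorGrid(eye="left"))["quadrant"].tolist()
        right = assign_sectors(pts, SectorGrid(eye="right"))["quadrant"].tolist()
        assert left == ["Nasal", "Temporal", "Superior"]
        assert right == ["Temporal", "Nasal", "Superior"]

    @given(arrays(float, (200, 2), elements=st.floats(-6, 6, allow_nan=False)))
    def test_every_point_in_exactly_one_sector(self, pts):
        out = assign_sectors(pts, SectorGrid())
        in_grid = out["ring"] != 0
        # partition: each point has exactly one (ring, quadrant) or out-of-grid
        assert len(out) == len(pts)
        assert out.loc[in_grid, "ring"].between(1, 15).all()
        assert out.loc[in_grid, "quadrant"].isin(QUADRANTS).all()

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-4, 4, size=(5_000, 2))
        theta = np.deg2rad(37.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        base = assign_sectors(pts, SectorGrid())
        rotated = assign_sectors(pts @ rot.T, SectorGrid(superior_angle_deg=90.0 + 37.0))
        counts_a = base.value_counts(["ring", "quadrant"]).sort_index()
        counts_b = rotated.value_counts(["ring", "quadrant"]).sort_index()
        pd.testing.assert_series_equal(counts_a, counts_b)

    def test_ring_gating_equals_annulus_membership(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-5, 5, size=(2_000, 2))
        grid = SectorGrid()
        rings = assign_sectors(pts, grid)["ring"].to_numpy()
        d = radial_distance(pts, grid.onh_xy)
        for k in range(1, grid.n_rings + 1):
            in_annulus = ((k - 1) * grid.ring_width_mm <= d) & (d < k * grid.ring_width_mm)
            np.testing.assert_array_equal(rings == k, in_annulus)


@pytest.fixture(scope="module")
def small_retina():
    """1 mm synthetic retina with its rendered geometry and a matched grid."""
    spec = MosaicSpec(field_radius_mm=1.0, target_density_per_mm2=1700.0,
                      exclusion_radius_um=0.0, seed=17)
    pts = generate_mosaic(spec)
    _, geom = render_image(pts, pixel_size_um=4.0, field_radius_mm=1.0)
    grid = SectorGrid(ring_width_mm=1.0 / 15, n_rings=15)
    return pts, geom, grid


class TestSectorAreas:
    def test_partition_conserves_total_mask_area(self, small_retina):
        _, geom, grid = small_retina
        areas = sector_areas(geom, grid)
        total = areas["area_mm2"].sum() + areas.attrs["out_of_grid_area_mm2"]
        assert total == pytest.approx(areas.attrs["total_mask_area_mm2"], abs=1e-12)

    def test_matches_analytic_annulus_quadrant_area(self, small_retina):
        _, geom, grid = small_retina
        areas = sector_areas(geom, grid).set_index(["ring", "quadrant"])
        w = grid.ring_width_mm
        for ring in (5, 10, 15):
            analytic = np.pi * ((ring * w) ** 2 - ((ring - 1) * w) ** 2) / 4.0
            for quad in QUADRANTS:
                got = areas.loc[(ring, quad), "area_mm2"]
                assert abs(got - analytic) / analytic < 0.01

    def test_onh_outside_mask_warns(self, small_retina):
        _, geom, _ = small_retina
        far_grid = SectorGrid(onh_xy=(50.0, 50.0))
        with pytest.warns(RuntimeWarning, match="outside"):
            sector_areas(geom, far_grid)


class TestSectorTable:
    def test_uniform_mosaic_densities_within_sampling_error(self, small_retina):
        pts, geom, grid = small_retina
        nnd = nearest_neighbour_distances(pts) * 1000.0
        table = sector_table(pts, geom, grid, nnd)
        assert len(table) == 60
        lam = len(pts) / (np.pi * 1.0**2)
        for _, row in table.iterrows():
            expected = lam * row["area_mm2"]
            # binomial sampling bound: 4 sigma, floor of 10% for large sectors
            tol = max(4 * np.sqrt(expected), 0.1 * expected)
            assert abs(row["cell_count"] - expected) <= tol

    def test_counts_partition_total(self, small_retina):
        pts, geom, grid = small_retina
        nnd = nearest_neighbour_distances(pts) * 1000.0
        table = sector_table(pts, geom, grid, nnd)
        assert table["cell_count"].sum() + table.attrs["out_of_grid_count"] == len(pts)

    def test_sparse_sector_reports_undefined_ri(self, small_retina):
        _, geom, grid = small_retina
        pts = np.array([[0.01, 0.0], [0.5, 0.5], [-0.4, 0.2], [0.2, -0.6]])
        nnd = nearest_neighbour_distances(pts) * 1000.0
        table = sector_table(pts, geom, grid, nnd).set_index(["ring", "quadrant"])
        empty = table[table["cell_count"] == 0]
        assert (empty["density_per_mm2"] == 0).all()
        assert empty["mean_nnd_um"].isna().all()
        assert table[table["cell_count"] < 3]["ri"].isna().all()

    def test_superior_clustered_deletion_lowers_superior_density(self, small_retina):
        pts, geom, grid = small_retina
        region = SectorRegion(grid=grid, quadrants=frozenset({"Superior"}))
        depleted = apply_loss(
            pts,
            LossPattern(mode="clustered", fraction_removed=0.6, region=region,
                        cluster_radius_um=80.0, seed=9),
        )
        nnd = nearest_neighbour_distances(depleted) * 1000.0
        table = sector_table(depleted, geom, grid, nnd).set_index(["ring", "quadrant"])
        lower = 0
        for ring in range(2, 14):
            sup = table.loc[(ring, "Superior"), "density_per_mm2"]
            inf = table.loc[(ring, "Inferior"), "density_per_mm2"]
            lower += sup < inf
        assert lower >= 11  # strictly below in nearly every matched ring

    def test_cells_in_zero_area_sector_rejected(self):
        # tiny central mask, but a cell gated to ring 5: geometry inconsistency
        mask = np.zeros((101, 101), bool)
        mask[45:56, 45:56] = True
        geom = RetinaGeometry(mask=mask, pixel_size_um=10.0, onh_xy_px=(50, 50))
        grid = SectorGrid(ring_width_mm=0.1, n_rings=15)
        pts = np.array([[0.45, 0.0], [0.01, 0.0], [0.02, 0.01]])
        nnd = nearest_neighbour_distances(pts) * 1000.0
        with pytest.raises(ValueError, match="zero mask area"):
            sector_table(pts, geom, grid, nnd)


class TestNNDColormapExport:
    def test_one_row_per_cell_and_lossless_roundtrip(self, tmp_path):
        pts = np.array([[0.0, 0.1], [0.2, -0.3], [-0.7, 0.4]])
        nnd = np.array([12.345678901234567, 20.0, 33.3])
        table = nnd_colormap_export(pts, nnd)
        assert len(table) == 3
        path = tmp_path / "map.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            nnd_colormap_export(np.zeros((3, 2)), np.zeros(2))

    def test_colour_rank_order_inverse_to_nnd(self):
        # jet_r maps the smallest NND to the warm (red) end
        import matplotlib.pyplot as plt

        cmap = plt.get_cmap("jet_r")
        low, high = cmap(0.0), cmap(1.0)
        assert low[0] > low[2]  # smallest NND renders red (R dominates B)
        assert high[2] > high[0]  # largest NND renders at the cool (blue) end
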
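"""Decay kinetics: one/two-phase fits, percentage loss, IOP exposure."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rgcmosaic import (
    DensityTimeSeries,
    cumulative_iop,
    fit_one_phase,
    fit_two_phase,
    percent_loss,
    predict_decay,
    round_half_away,
    sector_kinetics_map,
)
from rgcmosaic.datasets import CONTROL_DENSITY_PER_MM2, density_series, load_density_table
from rgcmosaic.kinetics import TwoPhaseFit
from rgcmosaic.segmentation import QUADRANTS

PAPER_TIMES = np.array([0.0, 3.0, 7.0, 21.0, 56.0])


def two_phase_curve(t, y0, plateau, pf, t_fast=1.7, t_slow=16.3):
    kf, ks = math.log(2) / t_fast, math.log(2) / t_slow
    f = pf / 100.0
    return plateau + (y0 - plateau) * (f * np.exp(-kf * t) + (1 - f) * np.exp(-ks * t))


class TestOnePhaseFit:
    def test_noiseless_data_recovered_to_4_significant_figures(self):
        y0, plateau, k = 1695.0, 400.0, math.log(2) / 4.0
        y = (y0 - plateau) * np.exp(-k * PAPER_TIMES) + plateau
        fit = fit_one_phase(DensityTimeSeries(PAPER_TIMES, y))
        assert fit.converged
        assert fit.y0 == pytest.approx(y0, rel=1e-4)
        assert fit.plateau == pytest.approx(plateau, rel=1e-4)
        assert fit.k_per_day == pytest.approx(k, rel=1e-4)
        assert fit.rss < 1e-6

    def test_constant_series_flagged_unidentifiable(self):
        fit = fit_one_phase(DensityTimeSeries(PAPER_TIMES, np.full(5, 1200.0)))
        assert "rate-unidentifiable" in fit.flags
        assert np.isnan(fit.k_per_day)

    def test_noisy_half_life_recovery(self):
        # 5% multiplicative noise: median recovered half-life within 15%
        y0, plateau, t_half = 1695.0, 400.0, 4.0
        k = math.log(2) / t_half
        truth = (y0 - plateau) * np.exp(-k * PAPER_TIMES) + plateau
        recovered = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = np.clip(truth * (1 + 0.05 * rng.standard_normal(5)), 0, None)
            fit = fit_one_phase(DensityTimeSeries(PAPER_TIMES, noisy))
            recovered.append(fit.half_life_days)
        assert abs(np.median(recovered) - t_half) / t_half < 0.15

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_one_phase(DensityTimeSeries(np.array([0.0, 3.0, 7.0]),
                                            np.array([1.0, 0.5, 0.3])))


class TestPredictDecay:
    def test_boundary_values_and_half_life_identity(self):
        y0, plateau, t_half = 1695.0, 400.0, 4.0
        y = (y0 - plateau) * np.exp(-math.log(2) / t_half * PAPER_TIMES) + plateau
        fit = fit_one_phase(DensityTimeSeries(PAPER_TIMES, y))
        assert predict_decay(fit, [0.0])[0] == pytest.approx(y0, rel=1e-4)
        assert predict_decay(fit, [1e6])[0] == pytest.approx(plateau, rel=1e-4)
        # at X = t_half the decaying span is exactly halved: 400 + 1295/2
        assert predict_decay(fit, [fit.half_life_days])[0] == pytest.approx(1047.5, rel=1e-4)


class TestTwoPhaseFit:
    def test_pure_fast_series_recovers_pf_100(self):
        y = two_phase_curve(PAPER_TIMES, 1695.0, 400.0, 100.0)
        fit = fit_two_phase(DensityTimeSeries(PAPER_TIMES, y))
        assert fit.pf_percent >= 99.0

    def test_pure_slow_series_recovers_pf_0(self):
        y = two_phase_curve(PAPER_TIMES, 1695.0, 400.0, 0.0)
        fit = fit_two_phase(DensityTimeSeries(PAPER_TIMES, y))
        assert fit.pf_percent <= 1.0

    def test_mixed_series_recovered_under_noise(self):
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            truth = two_phase_curve(PAPER_TIMES, 1695.0, 400.0, 65.0)
            noisy = np.clip(truth * (1 + 0.05 * rng.standard_normal(5)), 0, None)
            fit = fit_two_phase(DensityTimeSeries(PAPER_TIMES, noisy))
            errors.append(abs(fit.pf_percent - 65.0))
        assert np.median(errors) <= 10.0

    def test_pf_error_nondecreasing_in_noise(self):
        medians = []
        for noise in (0.01, 0.05, 0.10):
            errs = []
            for seed in range(40):
                rng = np.random.default_rng(1000 + seed)
                truth = two_phase_curve(PAPER_TIMES, 1695.0, 400.0, 65.0)
                noisy = np.clip(truth * (1 + noise * rng.standard_normal(5)), 0, None)
                fit = fit_two_phase(DensityTimeSeries(PAPER_TIMES, noisy))
                errs.append(abs(fit.pf_percent - 65.0))
            medians.append(np.median(errs))
        assert medians[0] <= medians[1] <= medians[2]

    @given(
        st.floats(500.0, 3000.0),
        st.floats(0.0, 400.0),
        st.floats(0.0, 100.0),
    )
    def test_span_conservation(self, y0_extra, plateau, pf):
        y0 = plateau + y0_extra
        fit = TwoPhaseFit(
            y0=y0, plateau=plateau, pf_percent=pf,
            k_fast_per_day=math.log(2) / 1.7, k_slow_per_day=math.log(2) / 16.3,
            rss=0.0, converged=True,
        )
        assert fit.span_fast + fit.span_slow == pytest.approx(y0 - plateau, rel=1e-12)
        assert fit.k_fast_per_day > fit.k_slow_per_day

    def test_invalid_half_lives_rejected(self):
        series = DensityTimeSeries(PAPER_TIMES, np.linspace(1695, 400, 5))
        with pytest.raises(ValueError, match="below"):
            fit_two_phase(series, t_half_fast_days=16.3, t_half_slow_days=1.7)
        with pytest.raises(ValueError, match="positive"):
            fit_two_phase(series, t_half_fast_days=0.0)


class TestPercentLoss:
    @pytest.mark.parametrize(
        "density, expected",
        [(491.7, 71), (1298.0, 23), (1695.0, 0)],
    )
    def test_reference_values(self, density, expected):
        loss = percent_loss(density, CONTROL_DENSITY_PER_MM2)
        assert round_half_away(loss) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            percent_loss(100.0, 0.0)

    def test_published_loss_row_reproduced_for_all_columns(self):
        table = load_density_table()
        for _, row in table.iterrows():
            loss = percent_loss(row["density"], CONTROL_DENSITY_PER_MM2)
            assert round_half_away(loss) == row["printed_loss_pct"]

    def test_whole_retina_series_has_baseline_at_day_zero(self):
        series = density_series("pONT")
        assert series.times_days[0] == 0.0
        assert series.densities[0] == CONTROL_DENSITY_PER_MM2
        with pytest.raises(ValueError, match="unknown model"):
            density_series("nope")


class TestSectorKineticsMap:
    @staticmethod
    def _series_table(make_curve):
        rows = []
        for ring in range(1, 16):
            for quad in QUADRANTS:
                for t, y in zip(PAPER_TIMES, make_curve(ring, quad)):
                    rows.append({"ring": ring, "quadrant": quad, "day": t, "density": y})
        return pd.DataFrame(rows)

    def test_shared_model_gives_flat_maps(self):
        curve = two_phase_curve(PAPER_TIMES, 1695.0, 500.0, 65.0)
        table = sector_kinetics_map(self._series_table(lambda r, q: curve))
        assert len(table) == 60
        assert table["converged"].all()
        assert table["percent_loss"].std() < 1e-6
        assert table["pf_percent"].std() < 1e-3

    def test_superior_fast_inferior_slow_design_resolved(self):
        def make_curve(ring, quad):
            t_half = 3.0 if quad == "Superior" else 12.0
            k = math.log(2) / t_half
            return (1695.0 - 400.0) * np.exp(-k * PAPER_TIMES) + 400.0

        table = sector_kinetics_map(self._series_table(make_curve))
        sup = table[table["quadrant"] == "Superior"]["half_life_days"]
        inf = table[table["quadrant"] == "Inferior"]["half_life_days"]
        assert (sup.to_numpy() < inf.to_numpy()).all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            sector_kinetics_map(pd.DataFrame({"ring": [], "day": []}))

    def test_underpowered_sector_carries_flag_not_exception(self):
        frame = pd.DataFrame(
            {"ring": [1, 1], "quadrant": ["Superior"] * 2,
             "day": [0.0, 7.0], "density": [1695.0, 900.0]}
        )
        table = sector_kinetics_map(frame)
        assert len(table) == 1
        assert not table["converged"].iloc[0]
        assert "error" in table["flags"].iloc[0]


class TestCumulativeIOP:
    def test_baseline_exposure_is_zero(self):
        t = np.array([0.0, 5.0, 10.0])
        assert cumulative_iop(t, np.full(3, 12.0), 12.0) == 0.0

    def test_constant_elevation_rectangle(self):
        t = np.array([0.0, 10.0])
        assert cumulative_iop(t, np.array([20.0, 20.0]), 12.0) == pytest.approx(80.0)

    def test_matches_dense_grid_quadrature(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 60, 15))
        t[0] = 0.0
        iop = rng.uniform(5, 30, 15)
        baseline = 12.0
        got = cumulative_iop(t, iop, baseline)
        # oracle: dense resampling of the piecewise-linear record, then clip
        tt = np.linspace(t[0], t[-1], 2_000_001)
        elev = np.clip(np.interp(tt, t, iop) - baseline, 0, None)
        expected = np.trapezoid(elev, tt)
        assert got == pytest.approx(expected, rel=1e-5)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="shape"):
            cumulative_iop(np.array([0.0, 1.0]), np.array([1.0]), 0.0)
        with pytest.raises(ValueError, match="strictly increasing"):
            cumulative_iop(np.array([0.0, 0.0]), np.array([1.0, 1.0]), 0.0)
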
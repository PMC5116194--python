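"""Weighting factors: land avoidance, wet/dry speed prior, logger SST
derivation and SST agreement; combination is multiplicative and
order-invariant."""

import numpy as np
import pandas as pd
import pytest

from twilightfix import (
    AlgorithmConfig,
    BoundaryBox,
    GridLandMask,
    ImmersionSeries,
    NoLand,
    PairType,
    PolygonLandMask,
    SSTField,
    combine_weights,
    derive_logger_sst,
    land_weight,
    speed_weight,
    sst_weight,
    wet_fraction,
)
from twilightfix.particles import ParticleCloud


def make_cloud(lons, lats, mid="2015-01-05 12:00"):
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    n = lons.size
    t = pd.Timestamp(mid).value / 1e9
    return ParticleCloud(
        step_index=0,
        mid_time=pd.Timestamp(mid),
        pair_type=PairType.RISE_THEN_SET,
        lon=lons,
        lat=lats,
        weight=np.ones(n),
        angle=np.full(n, -4.0),
        t1=np.full(n, t - 6 * 3600),
        t2=np.full(n, t + 6 * 3600),
        lat_randomized=np.zeros(n, dtype=bool),
    )


CFG = AlgorithmConfig(boundary=BoundaryBox(-60, -15, -65, -40))


class TestLandWeight:
    def test_all_sea_unchanged(self):
        cloud = make_cloud([-38, -40], [-54, -55])
        np.testing.assert_array_equal(land_weight(cloud, NoLand()), [1.0, 1.0])

    def test_land_cell_zeroed(self):
        mask = GridLandMask(
            lons=np.array([-40.0, -39.0, -38.0]),
            lats=np.array([-55.0, -54.0]),
            land=np.array([[False, False, False], [False, False, True]]),
        )
        cloud = make_cloud([-38.0, -40.0], [-54.0, -55.0])
        np.testing.assert_array_equal(land_weight(cloud, mask), [0.0, 1.0])

    def test_polygon_mask_and_terrestrial_mode(self):
        import shapely

        mask = PolygonLandMask(shapely.box(-39.0, -55.0, -37.0, -53.0))
        cloud = make_cloud([-38.0, -45.0], [-54.0, -54.0])
        np.testing.assert_array_equal(land_weight(cloud, mask, "marine"), [0.0, 1.0])
        np.testing.assert_array_equal(land_weight(cloud, mask, "terrestrial"), [1.0, 0.0])


class TestWetFraction:
    @staticmethod
    def series(states, start="2015-01-05 00:00", step_min=30):
        t = pd.date_range(start, periods=len(states), freq=f"{step_min}min")
        return ImmersionSeries(t.to_numpy(), np.asarray(states, dtype=bool))

    def test_all_dry(self):
        imm = self.series([False] * 10)
        assert wet_fraction(imm, "2015-01-05 00:00", "2015-01-05 04:00") == 0.0

    def test_all_wet(self):
        imm = self.series([True] * 10)
        assert wet_fraction(imm, "2015-01-05 00:00", "2015-01-05 04:00") == 1.0

    def test_alternating_is_half(self):
        imm = self.series([True, False] * 24)
        wf = wet_fraction(imm, "2015-01-05 00:00", "2015-01-05 12:00")
        assert wf == pytest.approx(0.5, abs=0.05)

    def test_no_data_defaults_dry(self):
        assert wet_fraction(None, "2015-01-05", "2015-01-06") == 0.0

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            wet_fraction(None, "2015-01-06", "2015-01-05")


class TestSpeedWeight:
    def test_plateau_tail_and_cap(self):
        # distances chosen so required speeds are 0, best+sd, and just over vmax
        best, sd, vmax = CFG.speed_dry.best, CFG.speed_dry.sd, CFG.speed_dry.vmax
        dt_h = 1.0
        km = lambda v: v * 3600.0 / 1000.0
        lat = -54.0
        dlon = lambda v: km(v) / (111.195 * np.cos(np.radians(lat)))
        cloud = make_cloud(
            [-38.0, -38.0 + dlon(best + sd), -38.0 + dlon(vmax + 0.5)],
            [lat, lat, lat],
        )
        w = speed_weight(-38.0, lat, cloud, dt_h, wf=0.0, cfg=CFG)
        assert w[0] == 1.0
        assert w[1] == pytest.approx(np.exp(-0.5), rel=1e-3)
        assert w[2] == 0.0

    def test_kernel_non_increasing_above_best(self):
        speeds = np.linspace(CFG.speed_dry.best, CFG.speed_dry.vmax + 5, 50)
        lat = -54.0
        dlon = speeds * 3600 / 1000 / (111.195 * np.cos(np.radians(lat)))
        cloud = make_cloud(-38.0 + dlon, np.full(50, lat))
        w = speed_weight(-38.0, lat, cloud, 1.0, 0.0, CFG)
        assert np.all(np.diff(w) <= 1e-12)

    def test_wet_blend_interpolates_triplets(self):
        # fully wet: the cap drops to the wet vmax
        lat = -54.0
        v = CFG.speed_wet.vmax + 0.5  # above wet cap, far below dry cap
        dlon = v * 3600 / 1000 / (111.195 * np.cos(np.radians(lat)))
        cloud = make_cloud([-38.0 + dlon], [lat])
        assert speed_weight(-38.0, lat, cloud, 1.0, 1.0, CFG)[0] == 0.0
        assert speed_weight(-38.0, lat, cloud, 1.0, 0.0, CFG)[0] == 1.0

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            speed_weight(-38.0, -54.0, make_cloud([-38.0], [-54.0]), 0.0, 0.0, CFG)


def small_field(value=10.0, err=None):
    times = np.array(["2015-01-05"], dtype="datetime64[D]")
    lons = np.arange(-40.0, -35.9, 0.5)
    lats = np.arange(-56.0, -51.9, 0.5)
    sst = np.full((1, lats.size, lons.size), value)
    e = np.full_like(sst, err) if err is not None else None
    return SSTField(times, lons, lats, sst, e)


class TestLoggerSST:
    @staticmethod
    def imm(times, wet):
        return ImmersionSeries(pd.to_datetime(times).to_numpy(), np.asarray(wet, dtype=bool))

    def test_constant_wet_samples(self):
        temps = pd.DataFrame({
            "time": pd.date_range("2015-01-05", periods=6, freq="4h"),
            "temp": 10.0,
        })
        imm = self.imm(["2015-01-04"], [True])
        out = derive_logger_sst(temps, imm, [pd.Timestamp("2015-01-05 12:00")])
        assert out[0] == 10.0

    def test_day_without_wet_samples_missing(self):
        temps = pd.DataFrame({"time": [pd.Timestamp("2015-01-05 08:00")], "temp": [10.0]})
        imm = self.imm(["2015-01-04"], [False])
        out = derive_logger_sst(temps, imm, [pd.Timestamp("2015-01-05 12:00")])
        assert np.isnan(out[0])

    def test_dry_sample_excluded_from_median(self):
        times = pd.to_datetime(["2015-01-05 02:00", "2015-01-05 06:00", "2015-01-05 10:00"])
        temps = pd.DataFrame({"time": times, "temp": [8.0, 9.0, 50.0]})
        imm = self.imm(["2015-01-05 00:00", "2015-01-05 09:00"], [True, False])
        out = derive_logger_sst(temps, imm, [pd.Timestamp("2015-01-05 12:00")])
        assert out[0] == pytest.approx(8.5)


class TestSSTWeight:
    def test_zero_difference_gives_one(self):
        cloud = make_cloud([-38.0], [-54.0])
        w = sst_weight(cloud, 10.0, small_field(10.0), CFG)
        assert w[0] == pytest.approx(1.0)

    def test_hard_tolerance_zeroes(self):
        cloud = make_cloud([-38.0], [-54.0])
        w = sst_weight(cloud, 10.0 + CFG.max_sst_diff + 0.01, small_field(10.0), CFG)
        assert w[0] == 0.0

    def test_one_sigma_closed_form_with_quadrature(self):
        field = small_field(10.0, err=0.4)
        sigma = np.hypot(CFG.sst_sd, 0.4)
        cloud = make_cloud([-38.0], [-54.0])
        w = sst_weight(cloud, 10.0 + sigma, field, CFG)
        assert w[0] == pytest.approx(np.exp(-0.5), rel=1e-6)

    def test_symmetric_and_non_increasing_in_difference(self):
        field = small_field(10.0)
        cloud = make_cloud([-38.0], [-54.0])
        diffs = np.linspace(0, CFG.max_sst_diff, 10)
        ws = [sst_weight(cloud, 10.0 + d, field, CFG)[0] for d in diffs]
        ws_neg = [sst_weight(cloud, 10.0 - d, field, CFG)[0] for d in diffs]
        np.testing.assert_allclose(ws, ws_neg)
        assert np.all(np.diff(ws) <= 0)

    def test_missing_logger_sst_passes_through(self):
        cloud = make_cloud([-38.0, -39.0], [-54.0, -54.5])
        np.testing.assert_array_equal(sst_weight(cloud, np.nan, small_field(), CFG), [1, 1])

    def test_missing_field_cell_zeroes(self):
        field = small_field(10.0)
        field.sst[:] = np.nan
        cloud = make_cloud([-38.0], [-54.0])
        assert sst_weight(cloud, 10.0, field, CFG)[0] == 0.0

    def test_uncovered_day_passes_through(self):
        cloud = make_cloud([-38.0], [-54.0], mid="2016-06-01 12:00")
        np.testing.assert_array_equal(sst_weight(cloud, 10.0, small_field(), CFG), [1.0])


class TestCombineWeights:
    def test_zero_factor_absorbs(self):
        cloud = make_cloud([-38.0, -39.0], [-54.0, -54.5])
        out = combine_weights(cloud, np.array([0.0, 1.0]), np.array([5.0, 0.5]))
        np.testing.assert_array_equal(out.weight, [0.0, 0.5])

    def test_order_invariant(self):
        cloud = make_cloud([-38.0, -39.0, -40.0], [-54.0, -54.5, -55.0])
        f1 = np.array([0.2, 1.0, 0.0])
        f2 = np.array([1.0, 0.5, 3.0])
        a = combine_weights(cloud, f1, f2).weight
        b = combine_weights(cloud, f2, f1).weight
        np.testing.assert_array_equal(a, b)

    def test_negative_weight_rejected(self):
        cloud = make_cloud([-38.0], [-54.0])
        with pytest.raises(ValueError):
            combine_weights(cloud, np.array([-0.1]))
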
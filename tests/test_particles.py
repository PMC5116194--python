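"""Particle clouds: twilight-error draws, solar-angle draws, cloud
generation with boundary/equinox handling, and east-west compensation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twilightfix import (
    AlgorithmConfig,
    BoundaryBox,
    GeoPosition,
    PairType,
    TwilightErrorParams,
    TwilightPair,
    east_west_compensation,
    fit_twilight_error,
    generate_cloud,
    sample_solar_angles,
    sample_twilight_offsets,
    twilight_times,
)

PUBLISHED_ERR = TwilightErrorParams(2.49, 0.94, 0.0)
TIGHT_ERR = TwilightErrorParams(-5.0, 1e-3, 0.0)  # offsets ~ exp(-5) min, effectively zero


def make_cfg(**kw):
    kw.setdefault("boundary", BoundaryBox(-60.0, -15.0, -65.0, -40.0))
    kw.setdefault("particle_number", 500)
    kw.setdefault("iteration_number", 1)
    return AlgorithmConfig(**kw)


def pair_at(pos, date, angle):
    tw = twilight_times(pos, date, angle)
    assert tw.status == "ok"
    if tw.rise <= tw.set:
        return TwilightPair(tw.rise, tw.set, PairType.RISE_THEN_SET)
    return TwilightPair(tw.set, tw.rise, PairType.SET_THEN_RISE)


class TestTwilightOffsets:
    def test_rise_offsets_nonnegative_when_no_delay(self, rng):
        off = sample_twilight_offsets(PUBLISHED_ERR, "rise", 1000, rng)
        assert np.all(off >= 0)

    def test_median_matches_lognormal_closed_form(self):
        rng = np.random.default_rng(7)
        off = sample_twilight_offsets(PUBLISHED_ERR, "rise", 100_000, rng)
        expected = np.exp(2.49)  # 12.06 min
        assert abs(np.median(off) - expected) / expected < 0.03

    def test_set_offsets_are_sign_flipped(self):
        r1 = sample_twilight_offsets(PUBLISHED_ERR, "rise", 500, np.random.default_rng(3))
        r2 = sample_twilight_offsets(PUBLISHED_ERR, "set", 500, np.random.default_rng(3))
        np.testing.assert_allclose(r1, -r2)

    def test_offset_support_with_delay(self, rng):
        params = TwilightErrorParams(2.0, 0.5, delay=4.0)
        rise = sample_twilight_offsets(params, "rise", 2000, rng)
        sets = sample_twilight_offsets(params, "set", 2000, rng)
        assert np.all(rise >= -4.0) and np.all(sets <= 4.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TwilightErrorParams(2.0, 0.0)
        with pytest.raises(ValueError):
            TwilightErrorParams(2.0, 1.0, delay=-1.0)


class TestSolarAngles:
    def test_support(self, rng):
        a = sample_solar_angles((-7.0, -1.0), 5000, rng)
        assert np.all((a >= -7.0) & (a <= -1.0))

    def test_degenerate_range(self, rng):
        a = sample_solar_angles((-5.0, -5.0), 100, rng)
        assert np.all(a == -5.0)

    def test_uniform_mean(self):
        a = sample_solar_angles((-7.0, -1.0), 100_000, np.random.default_rng(11))
        assert abs(a.mean() + 4.0) < 0.05

    def test_reversed_range_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_solar_angles((-1.0, -7.0), 10, rng)


class TestGenerateCloud:
    def test_centroid_recovers_truth_mid_season(self):
        """Tight errors + the true angle: the cloud centers on the truth."""
        pos = GeoPosition(-38.0, -54.0)
        pair = pair_at(pos, "2014-12-21", -4.0)
        cfg = make_cfg(
            sunrise_err=TIGHT_ERR, sunset_err=TIGHT_ERR,
            solar_angle_range=(-4.0, -4.0), particle_number=200,
        )
        cloud = generate_cloud(pair, cfg, np.random.default_rng(0), windows=[])
        assert cloud.n > 150
        assert abs(np.mean(cloud.lon) - pos.lon) < 1.0
        assert abs(np.mean(cloud.lat) - pos.lat) < 1.0
        assert not cloud.lat_randomized.any()

    def test_equinox_window_latitudes_uniform(self):
        pos = GeoPosition(-38.0, -54.0)
        pair = pair_at(pos, "2015-03-25", -4.0)
        cfg = make_cfg(particle_number=10_000)
        windows = [(pd.Timestamp("2015-03-01"), pd.Timestamp("2015-04-10"))]
        cloud = generate_cloud(pair, cfg, np.random.default_rng(1), windows=windows)
        assert cloud.lat_randomized.all()
        box = cfg.boundary
        u = (cloud.lat - box.lat_min) / (box.lat_max - box.lat_min)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_boundary_box_always_respected(self):
        pos = GeoPosition(-38.0, -54.0)
        pair = pair_at(pos, "2015-01-15", -4.0)
        cfg = make_cfg(particle_number=2000)
        cloud = generate_cloud(pair, cfg, np.random.default_rng(2), windows=[])
        assert cfg.boundary.contains(cloud.lon, cloud.lat).all()

    def test_box_excluding_truth_gives_empty_cloud(self):
        pos = GeoPosition(-38.0, -54.0)
        pair = pair_at(pos, "2015-01-15", -4.0)
        cfg = make_cfg(
            boundary=BoundaryBox(100.0, 120.0, 10.0, 30.0),
            sunrise_err=TIGHT_ERR, sunset_err=TIGHT_ERR,
            solar_angle_range=(-4.0, -4.0), particle_number=100,
        )
        cloud = generate_cloud(pair, cfg, np.random.default_rng(3), windows=[])
        assert cloud.is_empty

    def test_seeded_generation_bit_identical(self):
        pair = pair_at(GeoPosition(-38.0, -54.0), "2015-01-15", -4.0)
        cfg = make_cfg(particle_number=300)
        c1 = generate_cloud(pair, cfg, np.random.default_rng(42), windows=[])
        c2 = generate_cloud(pair, cfg, np.random.default_rng(42), windows=[])
        np.testing.assert_array_equal(c1.lon, c2.lon)
        np.testing.assert_array_equal(c1.lat, c2.lat)
        np.testing.assert_array_equal(c1.angle, c2.angle)

    def test_weights_initialized_to_one(self):
        pair = pair_at(GeoPosition(-38.0, -54.0), "2015-01-15", -4.0)
        cloud = generate_cloud(pair, make_cfg(), np.random.default_rng(4), windows=[])
        assert np.all(cloud.weight == 1.0)

    def test_particle_view_round_trips_arrays(self):
        pair = pair_at(GeoPosition(-38.0, -54.0), "2015-01-15", -4.0)
        cloud = generate_cloud(pair, make_cfg(particle_number=50),
                               np.random.default_rng(5), windows=[])
        p = cloud.particle(0)
        assert p.pos.lon == pytest.approx(cloud.lon[0])
        assert p.weight == 1.0 and p.perturbed_pair.type is cloud.pair_type


class TestEastWestCompensation:
    @staticmethod
    def moving_pairs(lon0, lat, start, n_days, deg_per_day, angle):
        """Daily rise/set pairs for a steadily eastward-moving animal."""
        pairs, true_mid_lons = [], []
        day = pd.Timestamp(start)
        for k in range(n_days):
            lon_noon = ((lon0 + deg_per_day * k + 180) % 360) - 180
            tw = twilight_times(GeoPosition(lon_noon, lat), day, angle)
            if tw.status != "ok":
                day += pd.Timedelta(days=1)
                continue
            # event times at the position the animal occupies at each event
            speed = deg_per_day / 24.0  # deg per hour
            rise_lon = lon_noon + speed * (tw.rise - day - pd.Timedelta(hours=12)).total_seconds() / 3600
            set_lon = lon_noon + speed * (tw.set - day - pd.Timedelta(hours=12)).total_seconds() / 3600
            tw_r = twilight_times(GeoPosition(((rise_lon + 180) % 360) - 180, lat), day, angle)
            tw_s = twilight_times(GeoPosition(((set_lon + 180) % 360) - 180, lat), day, angle)
            if tw_r.status != "ok" or tw_s.status != "ok" or not tw_r.rise < tw_s.set:
                day += pd.Timedelta(days=1)
                continue
            pairs.append(TwilightPair(tw_r.rise, tw_s.set, PairType.RISE_THEN_SET))
            true_mid_lons.append(lon_noon)
            day += pd.Timedelta(days=1)
        return pairs, true_mid_lons

    def test_eastward_transit_latitude_bias_reduced(self):
        """Movement between twilights distorts day length; compensation
        anchored on the previous longitude must shrink the latitude bias."""
        lat = 45.0
        pairs, mid_lons = self.moving_pairs(0.0, lat, "2015-05-01", 100, 7.5, -4.0)
        assert len(pairs) > 90
        cfg_on = make_cfg(
            boundary=BoundaryBox(-180.0, 179.99, 20.0, 70.0),
            sunrise_err=TIGHT_ERR, sunset_err=TIGHT_ERR,
            solar_angle_range=(-4.0, -4.0), particle_number=40,
            east_west_comp=True,
        )
        biases = {True: [], False: []}
        for comp in (True, False):
            rng = np.random.default_rng(9)
            prev_lon = mid_lons[0] - 7.5
            for pair, true_lon in zip(pairs, mid_lons):
                cloud = generate_cloud(pair, cfg_on, rng, windows=[])
                if cloud.is_empty:
                    prev_lon = true_lon
                    continue
                if comp:
                    cloud = east_west_compensation(prev_lon, cloud, cfg_on)
                if not cloud.is_empty:
                    biases[comp].append(abs(np.mean(cloud.lat) - lat))
                prev_lon = true_lon
        assert np.mean(biases[True]) < np.mean(biases[False])

    def test_stationary_cloud_unchanged(self):
        pair = pair_at(GeoPosition(-38.0, -54.0), "2015-01-15", -4.0)
        cfg = make_cfg(particle_number=100, east_west_comp=True,
                       sunrise_err=TIGHT_ERR, sunset_err=TIGHT_ERR,
                       solar_angle_range=(-4.0, -4.0))
        cloud = generate_cloud(pair, cfg, np.random.default_rng(6), windows=[])
        out = east_west_compensation(float(np.mean(cloud.lon)), cloud, cfg)
        # zero mean displacement: latitudes move by at most the tiny per-particle dlon effect
        np.testing.assert_allclose(out.lat, cloud.lat, atol=0.2)

    def test_flag_off_is_identity(self):
        pair = pair_at(GeoPosition(-38.0, -54.0), "2015-01-15", -4.0)
        cfg = make_cfg(particle_number=100, east_west_comp=False)
        cloud = generate_cloud(pair, cfg, np.random.default_rng(7), windows=[])
        out = east_west_compensation(-20.0, cloud, cfg)
        assert out is cloud


class TestErrorCalibration:
    def test_fit_recovers_generating_params(self):
        rng = np.random.default_rng(21)
        truth = TwilightErrorParams(2.49, 0.94, 0.0)
        residuals = sample_twilight_offsets(truth, "rise", 5000, rng)
        fit = fit_twilight_error(residuals)
        assert abs(fit.shape - 2.49) < 0.05
        assert abs(fit.scale - 0.94) < 0.05
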
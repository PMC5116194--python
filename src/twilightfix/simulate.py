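"""Synthetic data with the statistical structure the algorithm assumes.

Generates a correlated random walk of a fast-moving marine animal on the
sphere, twilight events perturbed by the skewed log-normal shading model,
a smooth daily SST field with a meridional gradient, 4-hourly logger
temperature samples, and a wet/dry immersion record — everything the
estimator consumes, plus the truth needed to score it. Default scenarios
mirror a mid-December (solstice) and a late-March (equinox) deployment of
a pelagic seabird at 54° S in the Southwest Atlantic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import BoundaryBox, TwilightErrorParams
from .geo import destination
from .particles import sample_twilight_offsets
from .solar import GeoPosition, PairType, TwilightPair, twilight_times
from .weighting import ImmersionSeries, SSTField

__all__ = ["Scenario", "TruthBundle", "simulate_track", "simulate_twilights",
           "simulate_sst", "simulate_immersion", "make_truth_bundle"]


@dataclass(frozen=True)
class Scenario:
    """Parameters of one synthetic deployment.

    Speeds are metres per second. The movement model is a correlated
    random walk: hourly headings follow a von Mises step with
    concentration ``turn_kappa`` and flight speed is truncated-normal;
    while the logger is wet the animal only drifts at ``drift_speed``.
    The SST field is base + meridional gradient + smooth spatial noise +
    linear temporal drift; logger samples are the field at the true
    position plus N(0, logger_temp_sd) every ``temp_interval_h`` hours.
    """

    start: GeoPosition = GeoPosition(-38.05, -54.0)
    start_date: str = "2014-12-10"
    n_days: int = 14
    mean_speed: float = 8.0          # m/s while flying (dry)
    speed_sd: float = 3.0
    turn_kappa: float = 4.0          # heading persistence of the CRW
    drift_speed: float = 0.5         # m/s while sitting on the water (wet)
    shading: TwilightErrorParams = TwilightErrorParams(2.49, 0.94, 0.0)
    true_solar_angle: float = -4.0
    sst_base: float = 4.0            # °C at the reference latitude
    sst_gradient: float = 1.0        # °C per degree latitude (toward the equator)
    sst_noise_sd: float = 0.3        # spatial noise sd, °C, smoothed
    sst_drift: float = 0.02          # °C per day uniform warming
    sst_err: float = 0.3             # satellite per-cell analysis error, °C
    logger_temp_sd: float = 0.5      # logger thermistor accuracy, °C
    temp_interval_h: float = 4.0
    wet_duty_cycle: float = 0.5
    immersion_resolution_min: float = 6.0
    region: BoundaryBox = BoundaryBox(-60.0, -15.0, -65.0, -40.0)
    land: Optional[object] = None    # shapely geometry of synthetic islands, or None
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if self.mean_speed < 0 or self.drift_speed < 0:
            raise ValueError("speeds must be >= 0")
        if not 0.0 <= self.wet_duty_cycle <= 1.0:
            raise ValueError("wet_duty_cycle must be in [0, 1]")

    @classmethod
    def solstice(cls, **kw) -> "Scenario":
        """December deployment at 54° S: latitude well constrained by day length.

        Includes a small synthetic island downstream of the release site so
        land avoidance is exercised.
        """
        import shapely

        kw.setdefault("land", shapely.box(-36.5, -55.8, -34.5, -55.0))
        return cls(**kw)

    @classmethod
    def equinox(cls, **kw) -> "Scenario":
        """Late-March deployment at 54° S: day length ≈ 12 h everywhere."""
        kw.setdefault("start_date", "2015-03-14")
        kw.setdefault("n_days", 10)
        return cls(**kw)


@dataclass
class TruthBundle:
    """Synthetic inputs plus the truth that produced them."""

    scenario: Scenario
    positions: pd.DataFrame              # hourly: time, lon, lat
    pairs: List[TwilightPair]            # observed (shading-perturbed) pairs
    twilight_table: pd.DataFrame         # tFirst, tSecond, type
    true_events: pd.DataFrame            # time, event, lon, lat (pre-noise)
    sst_field: SSTField
    temps: pd.DataFrame                  # time, temp (logger samples)
    immersion: ImmersionSeries
    release: GeoPosition = None
    release_time: pd.Timestamp = None

    def true_position_at(self, times) -> Tuple[np.ndarray, np.ndarray]:
        t = pd.to_datetime(list(times)).astype("int64").to_numpy()
        ref = pd.to_datetime(self.positions["time"]).astype("int64").to_numpy()
        lon = np.interp(t, ref, self.positions["lon"].to_numpy())
        lat = np.interp(t, ref, self.positions["lat"].to_numpy())
        return lon, lat

    @property
    def truth(self) -> pd.DataFrame:
        return self.positions.rename(columns={})[["time", "lon", "lat"]]


def simulate_immersion(sc: Scenario, rng: np.random.Generator) -> ImmersionSeries:
    """Two-state wet/dry record with the scenario's target duty cycle.

    Bout durations are geometric at the logger resolution (mean full
    wet+dry cycle ~30 min split by the duty cycle), giving alternating
    flight and on-water bouts whose long-run wet fraction matches
    ``wet_duty_cycle``; realized fractions fluctuate at the bout (not
    sample) level.
    """
    start = pd.Timestamp(sc.start_date)
    n = int(np.ceil(sc.n_days * 24 * 60 / sc.immersion_resolution_min)) + 1
    duty = sc.wet_duty_cycle
    if duty <= 0.0:
        wet = np.zeros(n, dtype=bool)
    elif duty >= 1.0:
        wet = np.ones(n, dtype=bool)
    else:
        mean_cycle_steps = 30.0 / sc.immersion_resolution_min  # ~30 min wet+dry cycle
        p_leave_dry = 1.0 / max(mean_cycle_steps * (1 - duty), 1.0)
        p_leave_wet = 1.0 / max(mean_cycle_steps * duty, 1.0)
        wet = np.empty(n, dtype=bool)
        state = rng.random() < duty
        u = rng.random(n)
        for i in range(n):
            wet[i] = state
            if state and u[i] < p_leave_wet:
                state = False
            elif not state and u[i] < p_leave_dry:
                state = True
    times = start.to_datetime64() + np.arange(n) * np.timedelta64(
        int(sc.immersion_resolution_min * 60_000_000_000 // 1), "ns"
    )
    return ImmersionSeries(times, wet)


def simulate_track(
    sc: Scenario, rng: np.random.Generator, immersion: Optional[ImmersionSeries] = None
) -> pd.DataFrame:
    """Hourly correlated random walk on the sphere.

    Heading is a von Mises random walk; hourly displacement is the blend
    of flight speed (truncated normal) and drift speed by the hour's wet
    fraction. Steps that would land on the scenario's land geometry or
    leave its region are re-drawn (reflected) up to a few tries.
    """
    start = pd.Timestamp(sc.start_date)
    n_hours = sc.n_days * 24
    times = start + pd.to_timedelta(np.arange(n_hours + 1), unit="h")
    wet_frac = np.zeros(n_hours)
    if immersion is not None:
        state = immersion.wet_at(times[:-1].to_numpy())
        wet_frac = state.astype(float)

    lons = np.empty(n_hours + 1)
    lats = np.empty(n_hours + 1)
    lons[0], lats[0] = sc.start.lon, sc.start.lat
    heading = rng.uniform(0.0, 360.0)
    land = sc.land
    if land is not None:
        import shapely

        land = shapely.union_all(np.atleast_1d(np.asarray(land, dtype=object)))
    for i in range(n_hours):
        speed = max(rng.normal(sc.mean_speed, sc.speed_sd), 0.0)
        v = (1 - wet_frac[i]) * speed + wet_frac[i] * sc.drift_speed
        dist_km = v * 3600.0 / 1000.0
        for _ in range(25):
            heading_try = np.degrees(rng.vonmises(np.radians(heading), sc.turn_kappa)) % 360.0
            lon2, lat2 = destination(lons[i], lats[i], heading_try, dist_km)
            inside = (
                sc.region.lon_min + 1 <= lon2 <= sc.region.lon_max - 1
                and sc.region.lat_min + 1 <= lat2 <= sc.region.lat_max - 1
            )
            on_land = False
            if land is not None and inside:
                import shapely

                on_land = bool(shapely.intersects_xy(land, lon2, lat2))
            if inside and not on_land:
                break
            heading = (heading + 120.0) % 360.0   # bounce away and re-draw
        lons[i + 1], lats[i + 1] = lon2, lat2
        heading = heading_try
    return pd.DataFrame({"time": times, "lon": lons, "lat": lats})


def simulate_twilights(
    positions: pd.DataFrame, sc: Scenario, rng: np.random.Generator
):
    """True twilights along the track, then shading-perturbed observations.

    For each UTC day both crossing times of the true solar angle are found
    at the position the animal actually occupies at the event (two fixed-
    point passes). Observed events add signed log-normal offsets: sunrise
    delayed, sunset advanced. Days without a crossing (polar day/night)
    are dropped. Returns ``(pairs, table, true_events)`` where consecutive
    events form overlapping pairs (the GeoLight convention, two location
    steps per full day).
    """
    t = pd.to_datetime(positions["time"])
    t_ns = t.astype("int64").to_numpy()
    lon_of = lambda u: np.interp(u, t_ns, positions["lon"].to_numpy())
    lat_of = lambda u: np.interp(u, t_ns, positions["lat"].to_numpy())

    events = []  # (time, kind, lon, lat)
    day = pd.Timestamp(sc.start_date).normalize()
    for _ in range(sc.n_days):
        noon_guess = day + pd.Timedelta(hours=12)
        pos = GeoPosition(float(lon_of(noon_guess.value)), float(lat_of(noon_guess.value)))
        tw = twilight_times(pos, day, sc.true_solar_angle)
        if tw.status == "ok":
            for kind, t_ev in (("rise", tw.rise), ("set", tw.set)):
                for _ in range(2):  # re-evaluate at the position at event time
                    pos_ev = GeoPosition(float(lon_of(t_ev.value)), float(lat_of(t_ev.value)))
                    tw2 = twilight_times(pos_ev, day, sc.true_solar_angle)
                    if tw2.status != "ok":
                        t_ev = None
                        break
                    t_ev = tw2.rise if kind == "rise" else tw2.set
                if t_ev is not None:
                    events.append((t_ev, kind, pos_ev.lon, pos_ev.lat))
        day += pd.Timedelta(days=1)
    events.sort(key=lambda e: e[0])
    true_events = pd.DataFrame(events, columns=["time", "event", "lon", "lat"])

    observed = []
    for t_ev, kind, _, _ in events:
        off = float(sample_twilight_offsets(sc.shading, kind, 1, rng)[0])
        observed.append((t_ev + pd.Timedelta(minutes=off), kind))
    observed.sort(key=lambda e: e[0])

    pairs: List[TwilightPair] = []
    rows = []
    for (t1, k1), (t2, k2) in zip(observed, observed[1:]):
        if k1 == k2 or not t2 > t1 or t2 - t1 >= pd.Timedelta(hours=24):
            continue  # mangled by noise ordering; drop the malformed pair
        ptype = PairType.RISE_THEN_SET if k1 == "rise" else PairType.SET_THEN_RISE
        pairs.append(TwilightPair(t1, t2, ptype))
        rows.append((t1, t2, ptype.value))
    table = pd.DataFrame(rows, columns=["tFirst", "tSecond", "type"])
    return pairs, table, true_events


def simulate_sst(
    sc: Scenario,
    positions: pd.DataFrame,
    immersion: Optional[ImmersionSeries],
    rng: np.random.Generator,
):
    """Daily 0.25° SST field over the scenario region, plus logger samples.

    Field: base + gradient·(lat − start lat) + frozen smooth spatial noise
    + linear drift in time. Logger samples: field value at the true
    position every ``temp_interval_h`` hours plus thermistor noise
    (those taken while dry are still recorded; the estimator is expected
    to use wet ones only).
    """
    res = 0.25
    lons = np.arange(sc.region.lon_min, sc.region.lon_max + res / 2, res)
    lats = np.arange(sc.region.lat_min, sc.region.lat_max + res / 2, res)
    start = pd.Timestamp(sc.start_date).normalize()
    days = np.arange(
        np.datetime64(start.date()), np.datetime64(start.date()) + np.timedelta64(sc.n_days + 1, "D")
    )
    noise = gaussian_filter(rng.standard_normal((lats.size, lons.size)), sigma=4.0)
    if noise.std() > 0:
        noise = noise / noise.std() * sc.sst_noise_sd
    base2d = sc.sst_base + sc.sst_gradient * (lats[:, None] - sc.start.lat) + noise
    sst = np.stack([base2d + sc.sst_drift * k for k in range(days.size)])
    sst = np.clip(sst, -1.9, 39.9)
    err = np.full_like(sst, sc.sst_err)
    field = SSTField(days, lons, lats, sst, err)

    n_samples = int(sc.n_days * 24 / sc.temp_interval_h)
    t_samp = start + pd.to_timedelta(np.arange(n_samples) * sc.temp_interval_h, unit="h")
    tlon, tlat = (
        np.interp(t_samp.astype("int64"), pd.to_datetime(positions["time"]).astype("int64"),
                  positions[c].to_numpy())
        for c in ("lon", "lat")
    )
    vals, _ = zip(*(field.lookup(ts, lo, la) for ts, lo, la in zip(t_samp, tlon, tlat)))
    vals = np.concatenate(vals) + rng.normal(0.0, sc.logger_temp_sd, size=n_samples)
    temps = pd.DataFrame({"time": t_samp, "temp": vals})
    return field, temps


def make_truth_bundle(sc: Scenario, seed: Optional[int] = None) -> TruthBundle:
    """Generate a fully consistent synthetic deployment (seed-deterministic)."""
    rng = np.random.default_rng(sc.rng_seed if seed is None else seed)
    immersion = simulate_immersion(sc, rng)
    positions = simulate_track(sc, rng, immersion)
    pairs, table, true_events = simulate_twilights(positions, sc, rng)
    field, temps = simulate_sst(sc, positions, immersion, rng)
    return TruthBundle(
        scenario=sc,
        positions=positions,
        pairs=pairs,
        twilight_table=table,
        true_events=true_events,
        sst_field=field,
        temps=temps,
        immersion=immersion,
        release=sc.start,
        release_time=pd.Timestamp(sc.start_date),
    )
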
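"""Particle clouds from twilight pairs.

Each twilight pair is replicated into a cloud of candidate positions by
perturbing the two event times with draws from the skewed (log-normal)
shading-error model and pairing each replicate with a solar elevation
angle drawn uniformly from the configured range. Replicates are then
geolocated with the threshold method; particles outside the boundary box
are removed, and during equinox windows (where day length carries no
latitude information) latitudes are replaced by uniform draws over the
box's latitude range.

Clouds are stored as flat numpy arrays for speed; ``Particle`` is a
lightweight per-index view.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import AlgorithmConfig, TwilightErrorParams, in_windows
from .geo import normalize_lon
from .solar import GeoPosition, PairType, TwilightPair, geolocate_arrays, _unix

__all__ = [
    "Particle",
    "ParticleCloud",
    "sample_twilight_offsets",
    "sample_solar_angles",
    "generate_cloud",
    "east_west_compensation",
    "fit_twilight_error",
]


@dataclass(frozen=True)
class Particle:
    """One candidate position with its perturbed twilights and weight."""

    pos: GeoPosition
    perturbed_pair: TwilightPair
    angle: float
    weight: float
    lat_randomized: bool


@dataclass(frozen=True)
class ParticleCloud:
    """All particles for one location step (column-oriented).

    ``t1``/``t2`` hold the perturbed event times as unix seconds so the
    latitude can be re-solved (east/west compensation) without touching
    pandas in the hot path.
    """

    step_index: int
    mid_time: pd.Timestamp
    pair_type: PairType
    lon: np.ndarray
    lat: np.ndarray
    weight: np.ndarray
    angle: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    lat_randomized: np.ndarray

    @property
    def n(self) -> int:
        return self.lon.size

    @property
    def is_empty(self) -> bool:
        return self.lon.size == 0

    def particle(self, i: int) -> Particle:
        ts = lambda u: pd.Timestamp(np.datetime64(int(round(u * 1e9)), "ns"))
        t1, t2 = ts(self.t1[i]), ts(self.t2[i])
        return Particle(
            pos=GeoPosition(float(self.lon[i]), float(self.lat[i])),
            perturbed_pair=TwilightPair(t1, t2, self.pair_type),
            angle=float(self.angle[i]),
            weight=float(self.weight[i]),
            lat_randomized=bool(self.lat_randomized[i]),
        )

    def subset(self, mask: np.ndarray) -> "ParticleCloud":
        return replace(
            self,
            lon=self.lon[mask],
            lat=self.lat[mask],
            weight=self.weight[mask],
            angle=self.angle[mask],
            t1=self.t1[mask],
            t2=self.t2[mask],
            lat_randomized=self.lat_randomized[mask],
        )

    def with_weight(self, weight: np.ndarray) -> "ParticleCloud":
        w = np.asarray(weight, dtype=float)
        if w.shape != self.lon.shape:
            raise ValueError("weight shape mismatch")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and non-negative")
        return replace(self, weight=w)


def sample_twilight_offsets(
    params: TwilightErrorParams, event: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Signed twilight offsets in minutes (true → observed direction).

    Raw magnitudes are LogNormal(shape, scale) minus ``delay``; shading
    delays an observed sunrise (+offset) and advances an observed sunset
    (−offset), so the returned array is already signed for ``event``
    ('rise' or 'set').
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if event not in ("rise", "set"):
        raise ValueError("event must be 'rise' or 'set'")
    raw = rng.lognormal(mean=params.shape, sigma=params.scale, size=n) - params.delay
    return raw if event == "rise" else -raw


def sample_solar_angles(angle_range, n: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform solar elevation angles on [lo, hi] degrees."""
    lo, hi = angle_range
    if lo > hi:
        raise ValueError("angle range must satisfy lo <= hi")
    return rng.uniform(lo, hi, size=n)


def _event_kinds(pair_type: PairType):
    """('rise','set') order of the two events of a pair."""
    return ("rise", "set") if pair_type is PairType.RISE_THEN_SET else ("set", "rise")


def generate_cloud(
    pair: TwilightPair,
    cfg: AlgorithmConfig,
    rng: np.random.Generator,
    step_index: int = 0,
    windows=None,
) -> ParticleCloud:
    """Replicate one twilight pair into a particle cloud (steps 2–3).

    The observed events carry shading offsets (sunrise late, sunset early),
    so each replicate *subtracts* a fresh signed offset draw to propose
    candidate true twilight times, draws a solar angle, and geolocates via
    the threshold method. Particles outside ``cfg.boundary`` are removed.
    If the pair midpoint falls inside an equinox window the latitudes of
    all particles are replaced by Uniform(lat_min, lat_max) draws
    (``lat_randomized=True``); outside windows, particles whose latitude is
    undefined get the same treatment when ``cfg.randomize_undefined_lat``
    is set, and are dropped otherwise.

    May return an empty cloud (boundary box excludes every replicate);
    the sampler treats that like an all-zero-weight cloud.
    """
    n = cfg.particle_number
    kinds = _event_kinds(pair.type)
    err_of = {"rise": cfg.sunrise_err, "set": cfg.sunset_err}
    off1 = sample_twilight_offsets(err_of[kinds[0]], kinds[0], n, rng)
    off2 = sample_twilight_offsets(err_of[kinds[1]], kinds[1], n, rng)
    t1 = _unix(pair.t_first) - off1 * 60.0   # observed − signed offset = candidate truth
    t2 = _unix(pair.t_second) - off2 * 60.0

    angle = sample_solar_angles(cfg.solar_angle_range, n, rng)
    if cfg.independent_pair_angles:
        angle2 = sample_solar_angles(cfg.solar_angle_range, n, rng)
    else:
        angle2 = None

    rising_first = np.full(n, pair.type is PairType.RISE_THEN_SET)
    if angle2 is None:
        lon, lat, lat_ok = geolocate_arrays(t1, t2, rising_first, angle)
    else:
        # per-event angles: geolocate with the mean (the closed-form solve
        # supports one angle per pair); the spread is retained via `angle`
        lon, lat, lat_ok = geolocate_arrays(t1, t2, rising_first, 0.5 * (angle + angle2))

    box = cfg.boundary
    if windows is None:
        windows = cfg.windows_for(pair.mid_time, pair.mid_time)
    in_eq = in_windows(pair.mid_time, windows)

    lat_randomized = np.zeros(n, dtype=bool)
    if in_eq:
        lat = rng.uniform(box.lat_min, box.lat_max, size=n)
        lat_randomized[:] = True
        keep = np.ones(n, dtype=bool)
    elif cfg.randomize_undefined_lat:
        bad = ~lat_ok
        if np.any(bad):
            lat = lat.copy()
            lat[bad] = rng.uniform(box.lat_min, box.lat_max, size=int(bad.sum()))
            lat_randomized[bad] = True
        keep = np.ones(n, dtype=bool)
    else:
        keep = lat_ok

    keep &= np.asarray(box.contains(lon, np.where(np.isnan(lat), box.lat_min, lat)))
    keep &= ~np.isnan(lat)

    cloud = ParticleCloud(
        step_index=step_index,
        mid_time=pair.mid_time,
        pair_type=pair.type,
        lon=lon,
        lat=lat,
        weight=np.ones(n),
        angle=angle,
        t1=t1,
        t2=t2,
        lat_randomized=lat_randomized,
    )
    return cloud.subset(keep)


def east_west_compensation(
    prev_cloud_lon: float, cloud: ParticleCloud, cfg: AlgorithmConfig
) -> ParticleCloud:
    """Correct each particle's day/night length for east–west movement.

    An animal moving east between the two twilights of a pair sees both
    events shift earlier in UTC, so the apparent interval differs from the
    stationary one by 4 min per degree of longitudinal displacement. Using
    the previous step's selected longitude as reference, the two event
    times are shifted symmetrically by ±2·Δlon minutes (midpoint — hence
    longitude — unchanged) and the latitude is re-solved. Lat-randomized
    particles keep their uniform draw; particles whose corrected latitude
    leaves the boundary box are dropped. No-op when ``cfg.east_west_comp``
    is false or the cloud is empty.
    """
    if not cfg.east_west_comp or cloud.is_empty:
        return cloud
    dlon = normalize_lon(cloud.lon - prev_cloud_lon)
    shift_min = 4.0 * dlon
    rising_first = np.full(cloud.n, cloud.pair_type is PairType.RISE_THEN_SET)
    _, lat_new, ok = geolocate_arrays(
        cloud.t1, cloud.t2, rising_first, cloud.angle, interval_shift_min=shift_min
    )
    lat = np.where(cloud.lat_randomized | ~ok, cloud.lat, lat_new)
    out = replace(cloud, lat=lat)
    keep = np.asarray(cfg.boundary.contains(out.lon, out.lat))
    return out.subset(keep) if not np.all(keep) else out


def fit_twilight_error(residual_minutes, delay: float = 0.0) -> TwilightErrorParams:
    """Fit the log-normal twilight-error model to calibration residuals.

    ``residual_minutes`` are observed-minus-predicted twilight times at a
    known site, signed so that shading makes them positive (sunrise late:
    observed − true; sunset early: true − observed). Maximum likelihood on
    log(residual + delay); non-positive residuals are dropped (they are
    outside the model's support).

    Convenience for calibration data; the defaults in
    :class:`~twilightfix.config.AlgorithmConfig` suit open-habitat species.
    """
    r = np.asarray(residual_minutes, dtype=float) + delay
    r = r[np.isfinite(r) & (r > 0)]
    if r.size < 2:
        raise ValueError("need at least 2 positive residuals")
    logs = np.log(r)
    return TwilightErrorParams(float(np.mean(logs)), float(np.std(logs, ddof=1)), delay)
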
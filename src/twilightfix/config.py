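"""Algorithm configuration.

Groups every tunable of the probabilistic geolocation algorithm in one
dataclass so a run is fully described by (inputs, config, seed). Defaults
are the published parameterization for wide-ranging pelagic seabirds:
10 000 particles, 200 iterations, log-normal twilight error with
shape 2.49 / scale 0.94 / delay 0 (log-minutes; median exp(2.49) ≈ 12 min),
solar angles uniform on [-7°, -1°], dry speed prior 12/6/45 m/s, wet
(drifting) 1/1.3/5 m/s, logger SST sd 0.5 °C and a 3 °C hard SST tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TwilightErrorParams:
    """Log-normal twilight-error parameters.

    ``shape`` and ``scale`` are the mean and sd of log(offset-minutes);
    ``delay`` (minutes) is subtracted from the raw draw as a location
    shift. The raw offset is always toward "less light": sunrise observed
    later, sunset earlier — shading can hide the sun but cannot invent it.
    """

    shape: float
    scale: float
    delay: float = 0.0

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")

    @property
    def median_minutes(self) -> float:
        """Median of the raw (unsigned) offset distribution, minutes."""
        return float(np.exp(self.shape) - self.delay)


@dataclass(frozen=True)
class SpeedPrior:
    """Travel-speed prior triplet, m/s.

    ``best`` is the fastest most-likely speed (weight 1 up to it), ``sd``
    the Gaussian decay scale above it, ``vmax`` a hard cap (weight 0 beyond).
    """

    best: float
    sd: float
    vmax: float

    def __post_init__(self):
        if not (0 < self.best <= self.vmax):
            raise ValueError("require 0 < best <= vmax")
        if not self.sd > 0:
            raise ValueError("sd must be > 0")


@dataclass(frozen=True)
class BoundaryBox:
    """Plausible lon/lat range; particles outside are removed."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self):
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("boundary box must have min < max on both axes")

    def contains(self, lon, lat):
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )


def equinox_dates(year: int) -> Tuple[pd.Timestamp, pd.Timestamp]:
    """Approximate UTC dates of the March and September equinoxes.

    Found by locating the sign change of solar declination; accurate to a
    day, which is ample for defining latitude-randomization windows.
    """
    from .solar import solar_declination

    out = []
    for start, end in ((f"{year}-03-15", f"{year}-03-25"), (f"{year}-09-17", f"{year}-09-27")):
        days = pd.date_range(start, end, freq="D")
        decl = np.atleast_1d(solar_declination(days))
        idx = int(np.argmin(np.abs(decl)))
        out.append(days[idx])
    return tuple(out)


def equinox_windows(
    t_min, t_max, days_around_spring: float = 21.0, days_around_fall: float = 21.0
) -> List[Tuple[pd.Timestamp, pd.Timestamp]]:
    """Latitude-randomization windows covering every equinox in [t_min, t_max]."""
    t_min = pd.Timestamp(t_min)
    t_max = pd.Timestamp(t_max)
    windows = []
    for year in range(t_min.year - 1, t_max.year + 2):
        spring, fall = equinox_dates(year)
        for eq, days in ((spring, days_around_spring), (fall, days_around_fall)):
            lo = eq - pd.Timedelta(days=float(days))
            hi = eq + pd.Timedelta(days=float(days))
            if hi >= t_min and lo <= t_max:
                windows.append((lo, hi))
    return windows


def in_windows(t, windows) -> bool:
    t = pd.Timestamp(t)
    return any(lo <= t <= hi for lo, hi in windows)


@dataclass(frozen=True)
class AlgorithmConfig:
    """Full parameter set of one geolocation run."""

    boundary: BoundaryBox
    particle_number: int = 10_000
    iteration_number: int = 200
    sunrise_err: TwilightErrorParams = TwilightErrorParams(2.49, 0.94, 0.0)
    sunset_err: TwilightErrorParams = TwilightErrorParams(2.49, 0.94, 0.0)
    solar_angle_range: Tuple[float, float] = (-7.0, -1.0)
    days_around_spring_equinox: float = 21.0
    days_around_fall_equinox: float = 21.0
    equinox_windows: Optional[List[Tuple[pd.Timestamp, pd.Timestamp]]] = None
    speed_dry: SpeedPrior = SpeedPrior(12.0, 6.0, 45.0)
    speed_wet: SpeedPrior = SpeedPrior(1.0, 1.3, 5.0)
    sst_sd: float = 0.5
    max_sst_diff: float = 3.0
    east_west_comp: bool = True
    # behaviour switches left open by the published description
    independent_pair_angles: bool = False   # one angle per particle (shared) vs per event
    randomize_undefined_lat: bool = True    # uniform latitude for lat-undefined fixes outside windows
    sst_error_combine: str = "quadrature"   # 'quadrature' or 'add'
    land_mode: str = "marine"               # 'marine' zeroes land, 'terrestrial' zeroes sea
    rng_seed: int = 0

    def __post_init__(self):
        if self.particle_number < 1 or self.iteration_number < 1:
            raise ValueError("particle_number and iteration_number must be >= 1")
        lo, hi = self.solar_angle_range
        if lo > hi:
            raise ValueError("solar_angle_range must be (lo, hi) with lo <= hi")
        if not self.max_sst_diff > 0:
            raise ValueError("max_sst_diff must be > 0")
        if self.sst_error_combine not in ("quadrature", "add"):
            raise ValueError("sst_error_combine must be 'quadrature' or 'add'")
        if self.land_mode not in ("marine", "terrestrial"):
            raise ValueError("land_mode must be 'marine' or 'terrestrial'")

    def windows_for(self, t_min, t_max):
        """Equinox windows: explicit if given, else derived from the days-around settings."""
        if self.equinox_windows is not None:
            return [(pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.equinox_windows]
        return equinox_windows(
            t_min, t_max, self.days_around_spring_equinox, self.days_around_fall_equinox
        )

    # --- (de)serialization for the run sidecar -------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["boundary"] = dataclasses.asdict(self.boundary)
        for k in ("sunrise_err", "sunset_err"):
            d[k] = dataclasses.asdict(getattr(self, k))
        for k in ("speed_dry", "speed_wet"):
            d[k] = dataclasses.asdict(getattr(self, k))
        d["solar_angle_range"] = list(self.solar_angle_range)
        if self.equinox_windows is not None:
            d["equinox_windows"] = [[str(a), str(b)] for a, b in self.equinox_windows]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AlgorithmConfig":
        d = dict(d)
        d["boundary"] = BoundaryBox(**d["boundary"])
        for k in ("sunrise_err", "sunset_err"):
            if k in d:
                d[k] = TwilightErrorParams(**d[k])
        for k in ("speed_dry", "speed_wet"):
            if k in d:
                d[k] = SpeedPrior(**d[k])
        if "solar_angle_range" in d:
            d["solar_angle_range"] = tuple(d["solar_angle_range"])
        if d.get("equinox_windows") is not None:
            d["equinox_windows"] = [
                (pd.Timestamp(a), pd.Timestamp(b)) for a, b in d["equinox_windows"]
            ]
        return cls(**d)
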
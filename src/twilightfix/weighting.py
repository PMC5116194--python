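"""Particle weighting: land avoidance, travel speed, and SST agreement.

Each weighting component returns a multiplicative factor per particle;
factors are combined with :func:`combine_weights`, so the order of
application never matters and a single zero factor is absorbing (the
particle can never be selected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import AlgorithmConfig, SpeedPrior
from .geo import haversine_km, normalize_lon
from .particles import ParticleCloud

__all__ = [
    "LandMask",
    "NoLand",
    "GridLandMask",
    "PolygonLandMask",
    "SSTField",
    "ImmersionSeries",
    "land_weight",
    "wet_fraction",
    "speed_weight",
    "derive_logger_sst",
    "sst_weight",
    "combine_weights",
]


# --- land masks --------------------------------------------------------------

class LandMask:
    """Total, deterministic land/sea query: is_land(lon, lat) -> bool array."""

    def is_land(self, lon, lat) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class NoLand(LandMask):
    """All-ocean mask (the open-sea default)."""

    def is_land(self, lon, lat) -> np.ndarray:
        return np.zeros(np.broadcast(np.asarray(lon), np.asarray(lat)).shape, dtype=bool)


class GridLandMask(LandMask):
    """Boolean land grid with nearest-cell lookup.

    ``land[j, i]`` is True over land for latitude ``lats[j]`` and longitude
    ``lons[i]``; axes must be strictly increasing. Points off the grid are
    treated as sea.
    """

    def __init__(self, lons: np.ndarray, lats: np.ndarray, land: np.ndarray):
        self.lons = np.asarray(lons, dtype=float)
        self.lats = np.asarray(lats, dtype=float)
        self.land = np.asarray(land, dtype=bool)
        if self.land.shape != (self.lats.size, self.lons.size):
            raise ValueError("land grid must be (nlat, nlon)")
        if np.any(np.diff(self.lons) <= 0) or np.any(np.diff(self.lats) <= 0):
            raise ValueError("grid axes must be strictly increasing")

    def is_land(self, lon, lat) -> np.ndarray:
        lon = np.atleast_1d(normalize_lon(lon))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        i = np.clip(np.searchsorted(self.lons, lon) , 0, self.lons.size - 1)
        i = np.where(
            (i > 0) & (np.abs(lon - self.lons[i - 1]) < np.abs(lon - self.lons[np.minimum(i, self.lons.size - 1)])),
            i - 1,
            np.minimum(i, self.lons.size - 1),
        )
        j = np.clip(np.searchsorted(self.lats, lat), 0, self.lats.size - 1)
        j = np.where(
            (j > 0) & (np.abs(lat - self.lats[j - 1]) < np.abs(lat - self.lats[np.minimum(j, self.lats.size - 1)])),
            j - 1,
            np.minimum(j, self.lats.size - 1),
        )
        out = self.land[j, i]
        off = (
            (lon < self.lons[0] - 0.5) | (lon > self.lons[-1] + 0.5)
            | (lat < self.lats[0] - 0.5) | (lat > self.lats[-1] + 0.5)
        )
        return np.where(off, False, out)


class PolygonLandMask(LandMask):
    """Land defined by shapely polygons (lon/lat degrees)."""

    def __init__(self, geometry):
        import shapely

        self.geometry = shapely.union_all(np.atleast_1d(np.asarray(geometry, dtype=object)))
        shapely.prepare(self.geometry)

    def is_land(self, lon, lat) -> np.ndarray:
        import shapely

        return shapely.contains_xy(
            self.geometry, np.atleast_1d(np.asarray(lon, dtype=float)), np.atleast_1d(np.asarray(lat, dtype=float))
        ) | shapely.intersects_xy(
            self.geometry, np.atleast_1d(np.asarray(lon, dtype=float)), np.atleast_1d(np.asarray(lat, dtype=float))
        )


def land_weight(cloud: ParticleCloud, mask: LandMask, mode: str = "marine") -> np.ndarray:
    """Factor 0 for particles on land (marine mode) or at sea (terrestrial)."""
    if cloud.is_empty:
        return np.ones(0)
    on_land = np.asarray(mask.is_land(cloud.lon, cloud.lat), dtype=bool)
    if mode == "marine":
        return np.where(on_land, 0.0, 1.0)
    if mode == "terrestrial":
        return np.where(on_land, 1.0, 0.0)
    raise ValueError("mode must be 'marine' or 'terrestrial'")


# --- immersion (wet/dry) -----------------------------------------------------

@dataclass(frozen=True)
class ImmersionSeries:
    """Wet/dry logger record: state is piecewise constant from each timestamp."""

    times: np.ndarray   # datetime64[ns], increasing
    wet: np.ndarray     # bool

    def __post_init__(self):
        t = np.asarray(self.times, dtype="datetime64[ns]")
        w = np.asarray(self.wet, dtype=bool)
        if t.size != w.size:
            raise ValueError("times and wet must have equal length")
        if np.any(np.diff(t).astype("int64") <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "wet", w)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ImmersionSeries":
        return cls(df["time"].to_numpy(), df["wet"].to_numpy())

    def wet_at(self, t) -> np.ndarray:
        """State at time(s) t (forward fill; dry before the first record)."""
        t = np.atleast_1d(np.asarray(t, dtype="datetime64[ns]"))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.wet[np.clip(idx, 0, None)], False)
        return out


def wet_fraction(imm: Optional[ImmersionSeries], t0, t1) -> float:
    """Time-weighted wet fraction of [t0, t1]; 0 (dry) when no data."""
    t0 = np.datetime64(pd.Timestamp(t0), "ns")
    t1 = np.datetime64(pd.Timestamp(t1), "ns")
    if not t1 > t0:
        raise ValueError("interval must satisfy t1 > t0")
    if imm is None or imm.times.size == 0:
        return 0.0
    # breakpoints: interval ends plus record times inside it
    inside = imm.times[(imm.times > t0) & (imm.times < t1)]
    edges = np.concatenate(([t0], inside, [t1]))
    states = imm.wet_at(edges[:-1])
    durations = (edges[1:] - edges[:-1]).astype("timedelta64[ns]").astype("int64")
    total = durations.sum()
    return float(durations[states].sum() / total) if total > 0 else 0.0


# --- speed -------------------------------------------------------------------

def _blend(dry: SpeedPrior, wet: SpeedPrior, wf: float):
    """Element-wise linear blend of the dry/wet speed triplets."""
    wf = float(np.clip(wf, 0.0, 1.0))
    return (
        (1 - wf) * dry.best + wf * wet.best,
        (1 - wf) * dry.sd + wf * wet.sd,
        (1 - wf) * dry.vmax + wf * wet.vmax,
    )


def speed_weight(
    prev_lon: float,
    prev_lat: float,
    cloud: ParticleCloud,
    dt_hours: float,
    wf: float,
    cfg: AlgorithmConfig,
) -> np.ndarray:
    """Travel-speed factor relative to the previously selected particle.

    Required speed s = great-circle distance / dt. The prior is flat (1)
    up to the fastest most-likely speed, decays as a Gaussian tail
    exp(−(s−best)²/(2·sd²)) up to the hard cap, and is 0 beyond it. The
    triplet is the wet-fraction blend of the dry (flying) and wet
    (drifting) priors.
    """
    if not dt_hours > 0:
        raise ValueError("dt_hours must be > 0")
    if cloud.is_empty:
        return np.ones(0)
    best, sd, vmax = _blend(cfg.speed_dry, cfg.speed_wet, wf)
    dist_km = haversine_km(prev_lon, prev_lat, cloud.lon, cloud.lat)
    s = dist_km * 1000.0 / (dt_hours * 3600.0)
    w = np.ones_like(s)
    tail = (s > best) & (s <= vmax)
    w[tail] = np.exp(-((s[tail] - best) ** 2) / (2.0 * sd**2))
    w[s > vmax] = 0.0
    return w


# --- SST ---------------------------------------------------------------------

@dataclass(frozen=True)
class SSTField:
    """Gridded daily sea-surface temperature (°C) with optional error field.

    ``sst[t, j, i]`` on strictly increasing ``lats``/``lons`` axes and
    daily ``times``; NaN marks missing cells (land/ice). ``err`` is the
    per-cell analysis error, also °C.
    """

    times: np.ndarray  # datetime64[D]
    lons: np.ndarray
    lats: np.ndarray
    sst: np.ndarray
    err: Optional[np.ndarray] = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype="datetime64[D]")
        lons = np.asarray(self.lons, dtype=float)
        lats = np.asarray(self.lats, dtype=float)
        sst = np.asarray(self.sst, dtype=float)
        if sst.shape != (t.size, lats.size, lons.size):
            raise ValueError("sst must be (ntime, nlat, nlon)")
        if np.any(np.diff(lons) <= 0) or np.any(np.diff(lats) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        with np.errstate(invalid="ignore"):
            bad = np.logical_or(sst < -2.0, sst > 40.0)
        if np.any(bad & np.isfinite(sst)):
            raise ValueError("SST values outside [-2, 40] degC (use NaN for missing)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lons", lons)
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "sst", sst)
        if self.err is not None:
            err = np.asarray(self.err, dtype=float)
            if err.shape != sst.shape:
                raise ValueError("err must match sst shape")
            object.__setattr__(self, "err", err)

    def _nearest(self, axis: np.ndarray, values: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(axis, values), 0, axis.size - 1)
        lower_closer = (idx > 0) & (
            np.abs(values - axis[np.maximum(idx - 1, 0)]) <= np.abs(values - axis[idx])
        )
        return np.where(lower_closer, idx - 1, idx)

    def covers(self, day) -> bool:
        return self.times[0] <= np.datetime64(pd.Timestamp(day).date()) <= self.times[-1]

    def lookup(self, day, lon, lat):
        """Nearest-cell (sst, err) at positions on a UTC day.

        Positions outside the grid or over missing cells return NaN sst.
        No horizontal interpolation: the native cell resolution is the
        information floor of the product.
        """
        day = np.datetime64(pd.Timestamp(day).date())
        ti = int(self._nearest(self.times.astype("int64").astype(float), np.array([day.astype("int64")], dtype=float))[0])
        lon = np.atleast_1d(normalize_lon(lon))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        i = self._nearest(self.lons, lon)
        j = self._nearest(self.lats, lat)
        half_dlon = 0.75 * np.median(np.diff(self.lons)) if self.lons.size > 1 else 1.0
        half_dlat = 0.75 * np.median(np.diff(self.lats)) if self.lats.size > 1 else 1.0
        off = (
            (lon < self.lons[0] - half_dlon) | (lon > self.lons[-1] + half_dlon)
            | (lat < self.lats[0] - half_dlat) | (lat > self.lats[-1] + half_dlat)
        )
        vals = self.sst[ti, j, i]
        vals = np.where(off, np.nan, vals)
        errs = self.err[ti, j, i] if self.err is not None else np.zeros_like(vals)
        errs = np.where(off, 0.0, errs)
        return vals, errs


def derive_logger_sst(
    temps: pd.DataFrame, imm: Optional[ImmersionSeries], step_mid_times
) -> np.ndarray:
    """Per-step logger SST: daily median of wet temperature samples.

    ``temps`` has columns ``time`` and ``temp`` (°C). A sample counts as
    water temperature only while the logger is wet (all samples count when
    no immersion record is supplied). Each step takes the median over its
    mid-time's UTC day; NaN where the day has no wet samples.
    """
    mids = pd.DatetimeIndex(pd.to_datetime(list(step_mid_times)))
    out = np.full(len(mids), np.nan)
    if temps is None or len(temps) == 0:
        return out
    t = pd.to_datetime(temps["time"])
    vals = np.asarray(temps["temp"], dtype=float)
    wet = imm.wet_at(t.to_numpy()) if imm is not None else np.ones(len(t), dtype=bool)
    days = t.dt.floor("D").to_numpy()
    for k, mid in enumerate(mids):
        sel = wet & (days == np.datetime64(mid.floor("D")))
        if np.any(sel):
            out[k] = float(np.median(vals[sel]))
    return out


def sst_weight(
    cloud: ParticleCloud,
    logger_sst: float,
    field: Optional[SSTField],
    cfg: AlgorithmConfig,
) -> np.ndarray:
    """SST-agreement factor.

    d = logger SST − satellite SST at the particle's cell on the step's
    day; the factor is the Gaussian kernel exp(−d²/(2σ²)) with
    σ² = sst_sd² + cell error² (quadrature; ``cfg.sst_error_combine='add'``
    sums the sds instead), zeroed where |d| exceeds the hard tolerance or
    the field cell is missing. Steps without a logger SST, or positions on
    days the field does not cover, leave weights unchanged (factor 1).
    """
    if cloud.is_empty:
        return np.ones(0)
    if field is None or logger_sst is None or not np.isfinite(logger_sst):
        return np.ones(cloud.n)
    if not field.covers(cloud.mid_time):
        return np.ones(cloud.n)
    sat, err = field.lookup(cloud.mid_time, cloud.lon, cloud.lat)
    if cfg.sst_error_combine == "quadrature":
        sigma = np.sqrt(cfg.sst_sd**2 + err**2)
    else:
        sigma = cfg.sst_sd + err
    d = logger_sst - sat
    with np.errstate(invalid="ignore"):
        w = np.exp(-(d**2) / (2.0 * sigma**2))
        w = np.where(np.abs(d) > cfg.max_sst_diff, 0.0, w)
    w = np.where(np.isnan(sat), 0.0, w)
    return w


def combine_weights(cloud: ParticleCloud, *factors: np.ndarray) -> ParticleCloud:
    """Multiply arbitrary weight factors onto the cloud (order-invariant)."""
    w = cloud.weight.astype(float).copy()
    for f in factors:
        f = np.asarray(f, dtype=float)
        if f.shape != w.shape:
            raise ValueError("factor shape mismatch")
        w = w * f
    return cloud.with_weight(w)
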
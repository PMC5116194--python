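"""Solar geometry and the threshold method.

Implements the astronomical core of light-level geolocation: solar
declination and the equation of time (NOAA low-accuracy formulas, Meeus
style), prediction of the UTC times at which the sun crosses a given
elevation angle at a known position (the inverse problem, also used to
back-calculate twilights from daily position logs of Lotek-style loggers),
and the threshold method itself — longitude from the midpoint of a twilight
pair interpreted as local apparent noon (rise→set) or midnight (set→rise),
latitude from the day/night length given the sun's declination and the
assumed solar elevation angle at the light threshold.

All timestamps are UTC throughout. Longitudes live in [-180, 180).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geo import normalize_lon

__all__ = [
    "PairType",
    "TwilightPair",
    "GeoPosition",
    "TwilightTimes",
    "ThresholdFix",
    "solar_declination",
    "equation_of_time",
    "twilight_times",
    "threshold_geolocate",
    "geolocate_arrays",
    "lotek_backcalculate",
]


class PairType(enum.Enum):
    """Order of events in a twilight pair."""

    RISE_THEN_SET = 1   # dawn followed by dusk: midpoint is local noon
    SET_THEN_RISE = 2   # dusk followed by dawn: midpoint is local midnight


@dataclass(frozen=True)
class TwilightPair:
    """One consecutive pair of twilight events; the unit of one location step."""

    t_first: pd.Timestamp
    t_second: pd.Timestamp
    type: PairType

    def __post_init__(self):
        t1 = pd.Timestamp(self.t_first)
        t2 = pd.Timestamp(self.t_second)
        if not t2 > t1:
            raise ValueError(f"t_second ({t2}) must be after t_first ({t1})")
        if t2 - t1 >= pd.Timedelta(hours=24):
            raise ValueError("twilight pair spans >= 24 h")
        object.__setattr__(self, "t_first", t1)
        object.__setattr__(self, "t_second", t2)

    @property
    def mid_time(self) -> pd.Timestamp:
        return self.t_first + (self.t_second - self.t_first) / 2


@dataclass(frozen=True)
class GeoPosition:
    """A point on the globe, degrees; lon normalized to [-180, 180)."""

    lon: float
    lat: float

    def __post_init__(self):
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise ValueError("position must be finite")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", float(normalize_lon(self.lon)))
        object.__setattr__(self, "lat", float(self.lat))


@dataclass(frozen=True)
class TwilightTimes:
    """Result of a twilight-time prediction for one position and UTC day.

    ``status`` is 'ok' when the sun crosses the requested elevation,
    'polar_day' when it stays above it all day (rise/set are None) and
    'polar_night' when it stays below.
    """

    rise: Optional[pd.Timestamp]
    set: Optional[pd.Timestamp]
    status: str = "ok"


@dataclass(frozen=True)
class ThresholdFix:
    """A threshold-method position estimate.

    When the observed day/night length is unattainable at any latitude for
    the given declination and solar angle (the equinox degeneracy),
    ``lat_defined`` is False and ``lat`` is NaN; the longitude remains valid.
    """

    lon: float
    lat: float
    lat_defined: bool


# --- NOAA solar position -----------------------------------------------------

_UNIX_J2000 = 946728000.0  # 2000-01-01 12:00 UTC in unix seconds


def _unix(t) -> np.ndarray:
    """Convert timestamps (scalar/array, anything datetime64-able) to unix seconds."""
    arr = pd.to_datetime(np.asarray(t)).to_numpy() if np.ndim(t) else pd.Timestamp(t).to_numpy()
    return np.asarray(arr, dtype="datetime64[ns]").astype("int64") / 1e9


def _julian_century(unix_s: np.ndarray) -> np.ndarray:
    return (unix_s - _UNIX_J2000) / (86400.0 * 36525.0)


def _solar_params(unix_s):
    """Declination (radians) and equation of time (minutes) at given times."""
    T = _julian_century(unix_s)
    L0 = np.radians((280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0)
    M = np.radians(357.52911 + T * (35999.05029 - 0.0001537 * T))
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    C = (
        np.sin(M) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * M) * (0.019993 - 0.000101 * T)
        + np.sin(3 * M) * 0.000289
    )
    true_lon = np.degrees(L0) + C
    omega = np.radians(125.04 - 1934.136 * T)
    app_lon = np.radians(true_lon - 0.00569 - 0.00478 * np.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - 0.001813 * T))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))
    decl = np.arcsin(np.clip(np.sin(eps) * np.sin(app_lon), -1.0, 1.0))
    y = np.tan(eps / 2.0) ** 2
    eot = 4.0 * np.degrees(
        y * np.sin(2 * L0)
        - 2.0 * e * np.sin(M)
        + 4.0 * e * y * np.sin(M) * np.cos(2 * L0)
        - 0.5 * y * y * np.sin(4 * L0)
        - 1.25 * e * e * np.sin(2 * M)
    )
    return decl, eot


def solar_declination(t):
    """Declination of the sun in degrees at UTC time(s) ``t``.

    NOAA low-accuracy algorithm; accurate to well under 0.05° against a
    high-accuracy ephemeris for years 1990–2100.
    """
    decl, _ = _solar_params(_unix(t))
    return np.degrees(decl)


def equation_of_time(t):
    """Apparent minus mean solar time in minutes at UTC time(s) ``t``."""
    _, eot = _solar_params(_unix(t))
    return eot


# --- twilight-time prediction (inverse problem) ------------------------------

def twilight_times(pos: GeoPosition, date, angle: float) -> TwilightTimes:
    """UTC times at which solar elevation crosses ``angle`` on a UTC calendar day.

    ``date`` is the UTC day (anything pandas parses); ``angle`` is the sun
    elevation in degrees (negative below the horizon). Uses two refinement
    passes so declination and the equation of time are evaluated near the
    event itself rather than at noon.
    """
    day0 = pd.Timestamp(date).normalize()
    lat = np.radians(pos.lat)
    sin_a = np.sin(np.radians(angle))
    # first guess: local solar noon ignoring EoT
    t_rise = t_set = _unix(day0) + (720.0 - 4.0 * pos.lon) * 60.0
    status = "ok"
    for _ in range(3):
        out = []
        for t_ev, sign in ((t_rise, -1.0), (t_set, +1.0)):
            decl, eot = _solar_params(np.asarray(t_ev))
            cos_h = (sin_a - np.sin(lat) * np.sin(decl)) / (np.cos(lat) * np.cos(decl))
            if cos_h < -1.0:
                return TwilightTimes(None, None, "polar_day")
            if cos_h > 1.0:
                return TwilightTimes(None, None, "polar_night")
            h_deg = np.degrees(np.arccos(cos_h))
            minutes = 720.0 - 4.0 * pos.lon - float(eot) + sign * 4.0 * h_deg
            out.append(_unix(day0) + minutes * 60.0)
        t_rise, t_set = out
    to_ts = lambda u: pd.Timestamp(np.datetime64(int(round(u * 1e9)), "ns"))
    return TwilightTimes(to_ts(t_rise), to_ts(t_set), status)


# --- threshold method (forward problem) --------------------------------------

def _wrap_pi(x):
    return (x + np.pi) % (2.0 * np.pi) - np.pi


def geolocate_arrays(t1, t2, rising_first, angle, interval_shift_min=None):
    """Vectorized threshold geolocation.

    Parameters
    ----------
    t1, t2
        Event times (unix seconds, declinations evaluated per event) as arrays.
    rising_first
        Boolean array: True for rise→set pairs (noon midpoint), False for
        set→rise (midnight midpoint).
    angle
        Solar elevation angle(s) in degrees, scalar or array.
    interval_shift_min
        Optional per-element correction (minutes) added to the apparent
        event interval before the latitude solve; used for longitudinal
        movement compensation. The midpoint (hence longitude) is unchanged.

    Returns
    -------
    lon, lat, lat_ok : ndarray
        Longitude (always defined), latitude in degrees (NaN where
        undefined) and a boolean mask of defined latitudes.

    Notes
    -----
    The twilight condition at each event, sinφ·sinδ + cosφ·cosδ·cosH = sin a,
    summed over the two events of a pair, has the form
    A·sinφ + B·cosφ = C and is solved in closed form. The two arcsin
    branches are disambiguated by requiring the sun above the threshold
    angle at local noon and below it at local midnight, falling back to the
    smaller day-length mismatch. |C| > sqrt(A²+B²) means no latitude can
    produce the observed day length (equinox degeneracy) → latitude undefined.
    """
    t1 = np.atleast_1d(np.asarray(t1, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2, dtype=float))
    rising_first = np.atleast_1d(rising_first).astype(bool)
    angle = np.broadcast_to(np.atleast_1d(np.asarray(angle, dtype=float)), t1.shape)

    mid = t1 + 0.5 * (t2 - t1)
    decl_mid, eot_mid = _solar_params(mid)
    utc_min_mid = (mid % 86400.0) / 60.0
    target = np.where(rising_first, 720.0, 0.0)
    lon = normalize_lon((target - utc_min_mid - eot_mid) / 4.0)

    if interval_shift_min is not None:
        half = 0.5 * np.asarray(interval_shift_min, dtype=float) * 60.0
        t1 = t1 - half
        t2 = t2 + half

    sin_a = np.sin(np.radians(angle))
    d1, eot1 = _solar_params(t1)
    d2, eot2 = _solar_params(t2)
    # event-local hour-angle offsets excluding longitude (degrees)
    g1 = ((t1 % 86400.0) / 60.0 + eot1) / 4.0 - 180.0
    g2 = ((t2 % 86400.0) / 60.0 + eot2) / 4.0 - 180.0
    # sign of the target hour angle per event: rise -> -arccos, set -> +arccos
    sign1 = np.where(rising_first, -1.0, 1.0)
    sign2 = -sign1
    observed_min = (t2 - t1) / 60.0

    def solve_lat(lon_now):
        A = np.sin(d1) + np.sin(d2)
        B = np.cos(d1) * np.cos(np.radians(g1 + lon_now)) + np.cos(d2) * np.cos(np.radians(g2 + lon_now))
        C = 2.0 * sin_a
        R = np.hypot(A, B)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = C / R
        ok = np.abs(s) <= 1.0
        base = np.arcsin(np.clip(s, -1.0, 1.0))
        psi = np.arctan2(B, A)
        cands = np.stack([_wrap_pi(base - psi), _wrap_pi(np.pi - base - psi)])  # (2, n)
        in_range = np.abs(cands) <= np.radians(89.9)
        # physical feasibility: above threshold at noon, below at midnight
        noon_above = np.cos(cands - decl_mid) >= sin_a - 1e-12
        midn_below = -np.cos(cands + decl_mid) <= sin_a + 1e-12
        feasible = in_range & noon_above & midn_below
        # day-length mismatch (minutes) for tie-breaking between branches
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_h0 = (sin_a - np.sin(cands) * np.sin(decl_mid)) / (np.cos(cands) * np.cos(decl_mid))
        h0_deg = np.degrees(np.arccos(np.clip(cos_h0, -1.0, 1.0)))
        implied_min = np.where(rising_first, 8.0 * h0_deg, (360.0 - 2.0 * h0_deg) * 4.0)
        mismatch = np.abs(implied_min - observed_min)
        mismatch = np.where(in_range, mismatch, np.inf)
        mismatch = np.where(feasible, mismatch - 1e9, mismatch)  # feasible branch wins outright
        pick = np.argmin(mismatch, axis=0)
        lat = np.degrees(np.take_along_axis(cands, pick[None, :], axis=0)[0])
        ok = ok & np.any(in_range, axis=0)
        return np.where(ok, lat, np.nan), ok

    lat, lat_ok = solve_lat(lon)

    # Refine longitude: the pair midpoint is only local noon/midnight when
    # the day is symmetric; with the solved latitude, each event pins the
    # hour angle to ±arccos(·) with its own declination, so adjust lon to
    # the mean wrapped correction and re-solve the latitude once.
    for _ in range(2):
        lat_r = np.radians(np.where(lat_ok, lat, 0.0))
        corr = np.zeros_like(lon)
        usable = lat_ok.copy()
        for g, d, sign in ((g1, d1, sign1), (g2, d2, sign2)):
            with np.errstate(invalid="ignore", divide="ignore"):
                cos_a_ev = (sin_a - np.sin(lat_r) * np.sin(d)) / (np.cos(lat_r) * np.cos(d))
            usable &= np.abs(cos_a_ev) <= 1.0
            a_deg = np.degrees(np.arccos(np.clip(cos_a_ev, -1.0, 1.0)))
            h_actual = normalize_lon(g + lon)
            corr += normalize_lon(sign * a_deg - h_actual)
        lon = np.where(usable, normalize_lon(lon + 0.5 * corr), lon)
        lat_new, ok_new = solve_lat(lon)
        lat = np.where(usable & ok_new, lat_new, lat)
        lat_ok = np.where(usable, ok_new, lat_ok)
    return lon, lat, lat_ok


def threshold_geolocate(pair: TwilightPair, angle: float) -> ThresholdFix:
    """Position from one twilight pair and one solar elevation angle.

    Longitude from the pair midpoint read as local apparent noon (rise→set)
    or local apparent midnight (set→rise), corrected by the equation of
    time; latitude from the day/night length via the closed-form solve in
    :func:`geolocate_arrays`. Returns a fix with ``lat_defined=False``
    (longitude still valid) when no latitude matches the observed interval.
    """
    lon, lat, ok = geolocate_arrays(
        _unix(pair.t_first),
        _unix(pair.t_second),
        np.array([pair.type is PairType.RISE_THEN_SET]),
        angle,
    )
    return ThresholdFix(float(lon[0]), float(lat[0]), bool(ok[0]))


def lotek_backcalculate(daylog: Sequence, angle: float):
    """Back-calculate twilight pairs from a daily position log.

    Lotek-style loggers store computed daily locations rather than raw
    light; re-deriving the twilight times that would have produced those
    locations lets such data enter the same processing chain. ``daylog``
    is a sequence of ``(date, lon, lat)`` rows (or a DataFrame with those
    columns). Days on which the sun never crosses ``angle`` (polar day or
    night) are skipped and reported.

    Returns ``(pairs, skipped)`` where ``skipped`` is a list of
    ``(date, status)`` tuples.
    """
    if isinstance(daylog, pd.DataFrame):
        rows = list(daylog[["date", "lon", "lat"]].itertuples(index=False, name=None))
    else:
        rows = [tuple(r) for r in daylog]
    pairs: list[TwilightPair] = []
    skipped: list[tuple] = []
    for date, lon, lat in rows:
        tw = twilight_times(GeoPosition(lon, lat), date, angle)
        if tw.status != "ok":
            skipped.append((pd.Timestamp(date).normalize(), tw.status))
            continue
        if tw.rise <= tw.set:
            pairs.append(TwilightPair(tw.rise, tw.set, PairType.RISE_THEN_SET))
        else:
            pairs.append(TwilightPair(tw.set, tw.rise, PairType.SET_THEN_RISE))
    return pairs, skipped
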
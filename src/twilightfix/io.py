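"""Reading and writing the tool's file formats.

Twilight tables use the GeoLight-style tFirst/tSecond/type CSV (the one
convention expressible for every logger brand); BAS .trn event lists are
adapted into it. SST grids are read from OISST-dialect NetCDF (variables
``sst`` and optional ``err`` on time/lat/lon axes, CF scale attributes
honored by xarray) or from a plain NPZ fallback. Run outputs are a track
CSV, a full-ensemble CSV, a GeoJSON LineString of the medoid track and a
JSON config sidecar from which the run can be reproduced exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path as FsPath
from typing import List, Tuple

import numpy as np
import pandas as pd

from .config import AlgorithmConfig
from .geo import normalize_lon
from .sampler import MedianTrack, PathEnsemble
from .solar import PairType, TwilightPair
from .weighting import SSTField

__all__ = [
    "read_twilight_table",
    "write_twilight_table",
    "pairs_from_table",
    "table_from_pairs",
    "read_sst_netcdf",
    "write_sst_netcdf",
    "read_sst_npz",
    "write_sst_npz",
    "write_outputs",
]


class InputError(ValueError):
    """Malformed or unreadable input file."""


# --- twilight tables ---------------------------------------------------------

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S.%fZ"


def _parse_ts(series: pd.Series, path, col: str) -> pd.Series:
    out = pd.to_datetime(series, utc=True, format="ISO8601", errors="coerce")
    bad = out.isna()
    if bad.any():
        rows = ", ".join(str(i + 2) for i in np.flatnonzero(bad.to_numpy())[:5])  # 1-based + header
        raise InputError(f"{path}: unparseable {col} timestamp at line(s) {rows}")
    return out.dt.tz_localize(None)


def read_twilight_table(path, dialect: str = "geolight_csv") -> pd.DataFrame:
    """Read a twilight-event table.

    ``geolight_csv``: columns tFirst, tSecond, type (1 = rise→set,
    2 = set→rise), ISO-8601 UTC. ``bas_trn``: one event per line,
    ``timestamp<sep>Sunrise|Sunset``; consecutive events are paired into
    the same three-column table (overlapping pairs, two steps per day).
    Rows are sorted by tFirst (with a warning if the file was unordered).
    """
    path = FsPath(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    if dialect == "geolight_csv":
        try:
            df = pd.read_csv(path)
        except Exception as e:  # includes EmptyDataError
            raise InputError(f"{path}: {e}") from e
        missing = {"tFirst", "tSecond", "type"} - set(df.columns)
        if missing:
            raise InputError(f"{path}: missing column(s) {sorted(missing)}")
        if len(df) == 0:
            raise InputError(f"{path}: empty twilight table")
        df = df[["tFirst", "tSecond", "type"]].copy()
        df["tFirst"] = _parse_ts(df["tFirst"], path, "tFirst")
        df["tSecond"] = _parse_ts(df["tSecond"], path, "tSecond")
        if not df["type"].isin([1, 2]).all():
            bad = np.flatnonzero(~df["type"].isin([1, 2]).to_numpy())[:5] + 2
            raise InputError(f"{path}: type must be 1 or 2 (line(s) {list(bad)})")
        bad = df["tSecond"] <= df["tFirst"]
        if bad.any():
            raise InputError(
                f"{path}: tSecond <= tFirst at line(s) "
                f"{list(np.flatnonzero(bad.to_numpy())[:5] + 2)}"
            )
    elif dialect == "bas_trn":
        events: List[Tuple[pd.Timestamp, str]] = []
        with open(path) as fh:
            for ln, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = [p for p in line.replace(",", " ").split() if p]
                if len(parts) < 2:
                    raise InputError(f"{path}: malformed line {ln}: {line!r}")
                kind = parts[-1].lower()
                if kind.startswith("sunr") or kind == "r":
                    ev = "rise"
                elif kind.startswith("suns") or kind == "s":
                    ev = "set"
                else:
                    raise InputError(f"{path}: unknown event {parts[-1]!r} at line {ln}")
                try:
                    ts = pd.Timestamp(" ".join(parts[:-1]))
                except Exception as e:
                    raise InputError(f"{path}: unparseable timestamp at line {ln}") from e
                events.append((ts, ev))
        if len(events) < 2:
            raise InputError(f"{path}: need at least 2 twilight events")
        events.sort(key=lambda e: e[0])
        rows = []
        for (t1, k1), (t2, k2) in zip(events, events[1:]):
            if k1 == k2 or t2 - t1 >= pd.Timedelta(hours=24):
                warnings.warn(f"{path}: skipping unpairable events at {t1} ({k1}/{k2})")
                continue
            rows.append((t1, t2, 1 if k1 == "rise" else 2))
        df = pd.DataFrame(rows, columns=["tFirst", "tSecond", "type"])
        if len(df) == 0:
            raise InputError(f"{path}: no valid twilight pairs")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not df["tFirst"].is_monotonic_increasing:
        warnings.warn(f"{path}: twilight rows were not time-ordered; sorting")
        df = df.sort_values("tFirst", kind="stable").reset_index(drop=True)
    return df.reset_index(drop=True)


def write_twilight_table(df: pd.DataFrame, path) -> None:
    """Write a twilight table as ISO-8601 UTC ('Z') CSV; round-trips exactly."""
    out = df.copy()
    for col in ("tFirst", "tSecond"):
        out[col] = pd.to_datetime(out[col]).dt.strftime(_TS_FORMAT)
    out.to_csv(path, index=False)


def pairs_from_table(df: pd.DataFrame) -> List[TwilightPair]:
    return [
        TwilightPair(r.tFirst, r.tSecond, PairType(int(r.type)))
        for r in df.itertuples(index=False)
    ]


def table_from_pairs(pairs: List[TwilightPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.t_first, p.t_second, p.type.value) for p in pairs],
        columns=["tFirst", "tSecond", "type"],
    )


# --- SST grids ---------------------------------------------------------------

def _field_from_arrays(times, lons, lats, sst, err) -> SSTField:
    lons = normalize_lon(np.asarray(lons, dtype=float))
    order = np.argsort(lons)
    lons = lons[order]
    sst = np.asarray(sst, dtype=float)[:, :, order]
    if err is not None:
        err = np.asarray(err, dtype=float)[:, :, order]
    lats = np.asarray(lats, dtype=float)
    if lats.size > 1 and lats[0] > lats[-1]:
        lats = lats[::-1]
        sst = sst[:, ::-1, :]
        if err is not None:
            err = err[:, ::-1, :]
    return SSTField(np.asarray(times, dtype="datetime64[D]"), lons, lats, sst, err)


def read_sst_netcdf(path) -> SSTField:
    """Read an OISST-dialect NetCDF file into an :class:`SSTField`.

    Requires dimensions time/lat/lon (or longitude/latitude) and a ``sst``
    variable; ``err`` is optional. CF ``scale_factor``/``add_offset``/
    ``_FillValue`` attributes are honored (xarray decoding). Longitudes on
    a 0–360 grid are rolled into [-180, 180).
    """
    import xarray as xr

    path = FsPath(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    try:
        ds = xr.open_dataset(path)
    except Exception as e:
        raise InputError(f"{path}: cannot open as NetCDF ({e})") from e
    with ds:
        names = {n.lower(): n for n in list(ds.variables)}
        if "sst" not in names:
            raise InputError(f"{path}: missing required variable 'sst'")
        lon_name = next((names[k] for k in ("lon", "longitude") if k in names), None)
        lat_name = next((names[k] for k in ("lat", "latitude") if k in names), None)
        time_name = names.get("time")
        if lon_name is None or lat_name is None or time_name is None:
            raise InputError(f"{path}: need time, lat and lon coordinates")
        def arranged(var):
            # OISST ships (time, zlev, lat, lon); drop extraneous singleton
            # axes (depth) but never the time axis itself
            extra = [d for d in var.dims if d not in (time_name, lat_name, lon_name)]
            for d in extra:
                if var.sizes[d] != 1:
                    raise InputError(f"{path}: unexpected non-singleton dimension {d!r}")
                var = var.isel({d: 0}, drop=True)
            return var.transpose(time_name, lat_name, lon_name)

        sst = arranged(ds[names["sst"]])
        err = arranged(ds[names["err"]]).values if "err" in names else None
        return _field_from_arrays(
            ds[time_name].values.astype("datetime64[D]"),
            ds[lon_name].values,
            ds[lat_name].values,
            sst.values,
            err,
        )


def write_sst_netcdf(field: SSTField, path) -> None:
    """Write an SSTField in the OISST-like layout (netCDF3 classic)."""
    import xarray as xr

    data = {"sst": (("time", "lat", "lon"), field.sst)}
    if field.err is not None:
        data["err"] = (("time", "lat", "lon"), field.err)
    ds = xr.Dataset(
        data,
        coords={
            "time": field.times.astype("datetime64[ns]"),
            "lat": field.lats,
            "lon": field.lons,
        },
    )
    ds.sst.attrs["units"] = "degC"
    ds.to_netcdf(path, engine="scipy")


def write_sst_npz(field: SSTField, path) -> None:
    """Plain NPZ fallback for SST grids (keys: times, lons, lats, sst[, err])."""
    arrays = {
        "times": field.times.astype("datetime64[D]").astype("int64"),
        "lons": field.lons,
        "lats": field.lats,
        "sst": field.sst,
    }
    if field.err is not None:
        arrays["err"] = field.err
    np.savez_compressed(path, **arrays)


def read_sst_npz(path) -> SSTField:
    path = FsPath(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    with np.load(path) as z:
        if "sst" not in z:
            raise InputError(f"{path}: missing 'sst' array")
        return _field_from_arrays(
            z["times"].astype("datetime64[D]"),
            z["lons"],
            z["lats"],
            z["sst"],
            z["err"] if "err" in z else None,
        )


# --- run outputs -------------------------------------------------------------

def write_outputs(
    ensemble: PathEnsemble, track: MedianTrack, cfg: AlgorithmConfig, out_dir
) -> dict:
    """Write track.csv, ensemble.csv, track.geojson and config.json.

    Returns the paths written. Re-running with the sidecar config (same
    inputs) reproduces every file byte for byte.
    """
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "track": out / "track.csv",
        "ensemble": out / "ensemble.csv",
        "geojson": out / "track.geojson",
        "config": out / "config.json",
    }

    t = track.table.copy()
    t["mid_time"] = pd.to_datetime(t["mid_time"]).dt.strftime(_TS_FORMAT)
    for col in ("lon", "lat", "lon_lo95", "lon_hi95", "lat_lo95", "lat_hi95"):
        t[col] = t[col].map(lambda v: f"{v:.5f}")
    for col in ("q50_km", "q95_km"):
        t[col] = t[col].map(lambda v: f"{v:.3f}")
    for col in ("retention", "lat_randomized_frac"):
        t[col] = t[col].map(lambda v: f"{v:.4f}")
    t.to_csv(paths["track"], index=False)

    e = ensemble.to_dataframe()
    e["mid_time"] = pd.to_datetime(e["mid_time"]).dt.strftime(_TS_FORMAT)
    for col in ("lon", "lat"):
        e[col] = e[col].map(lambda v: f"{v:.5f}")
    e.to_csv(paths["ensemble"], index=False)

    coords = [[round(float(lo), 5), round(float(la), 5)]
              for lo, la in zip(track.table["lon"], track.table["lat"])]
    geojson = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {"name": "geographic-medoid track", "n_steps": len(coords)},
            }
        ],
    }
    paths["geojson"].write_text(json.dumps(geojson, indent=2, sort_keys=True) + "\n")
    paths["config"].write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
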
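"""Forward probability sampling and the geographic-medoid track.

One iteration walks forward through the twilight pairs: build the particle
cloud for the step, correct day length for east–west movement relative to
the previously selected particle, weight by land / travel speed / SST,
then select one particle with probability proportional to its weight. A
cloud whose weights are all zero is judged implausible and the whole step
is discarded; the elapsed time then accumulates into the next step's
speed constraint. Many independent iterations give an ensemble of paths;
the reported track is, per step, the geographic medoid of the selected
positions (the iterated position minimizing the summed great-circle
distance to the others — always an actually computed location), with
empirical distance quantiles as the uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AlgorithmConfig
from .geo import haversine_km
from .particles import ParticleCloud, east_west_compensation, generate_cloud
from .solar import GeoPosition, TwilightPair
from .weighting import (
    ImmersionSeries,
    LandMask,
    SSTField,
    combine_weights,
    derive_logger_sst,
    land_weight,
    speed_weight,
    sst_weight,
    wet_fraction,
)

__all__ = [
    "AlgorithmInputs",
    "Path",
    "PathEnsemble",
    "MedianTrack",
    "sample_particle",
    "build_path",
    "run_algorithm",
    "geographic_medoid",
    "uncertainty_quantiles",
    "sensitivity_analysis",
    "ensemble_nearest_error_km",
    "track_error_km",
]


@dataclass
class AlgorithmInputs:
    """Everything a run needs besides the twilight pairs and the config.

    ``release`` / ``release_time`` anchor each path (the first position is
    known without error). ``logger_sst`` may be given per step directly;
    otherwise it is derived from ``temps`` (+ ``immersion``) as the daily
    median wet temperature.
    """

    release: GeoPosition
    release_time: pd.Timestamp
    land_mask: Optional[LandMask] = None
    sst_field: Optional[SSTField] = None
    immersion: Optional[ImmersionSeries] = None
    temps: Optional[pd.DataFrame] = None
    logger_sst: Optional[np.ndarray] = None

    def per_step_logger_sst(self, mid_times) -> Optional[np.ndarray]:
        if self.logger_sst is not None:
            return np.asarray(self.logger_sst, dtype=float)
        if self.temps is not None:
            return derive_logger_sst(self.temps, self.immersion, mid_times)
        return None


@dataclass
class Path:
    """One iterated movement path (selected particle per retained step)."""

    iteration_id: int
    step_indices: np.ndarray
    mid_times: pd.DatetimeIndex
    lons: np.ndarray
    lats: np.ndarray
    angles: np.ndarray
    lat_randomized: np.ndarray
    skipped_steps: List[int] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return self.step_indices.size == 0


@dataclass
class PathEnsemble:
    """All iterated paths plus per-step position collections."""

    paths: List[Path]
    n_steps: int

    def positions_at(self, step: int):
        """(iteration_ids, lons, lats, angles, randomized) of iterations retaining the step."""
        ids, lons, lats, angs, rnd = [], [], [], [], []
        for p in self.paths:
            k = np.searchsorted(p.step_indices, step)
            if k < p.step_indices.size and p.step_indices[k] == step:
                ids.append(p.iteration_id)
                lons.append(p.lons[k])
                lats.append(p.lats[k])
                angs.append(p.angles[k])
                rnd.append(p.lat_randomized[k])
        return (
            np.asarray(ids, dtype=int),
            np.asarray(lons, dtype=float),
            np.asarray(lats, dtype=float),
            np.asarray(angs, dtype=float),
            np.asarray(rnd, dtype=bool),
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.paths:
            for k in range(p.step_indices.size):
                rows.append(
                    (p.iteration_id, int(p.step_indices[k]), p.mid_times[k], p.lons[k], p.lats[k])
                )
        return pd.DataFrame(rows, columns=["iteration_id", "step_index", "mid_time", "lon", "lat"])


@dataclass
class MedianTrack:
    """Per-step geographic-medoid track with uncertainty quantiles."""

    table: pd.DataFrame  # step_index, mid_time, lon, lat, q50_km, q95_km, ... per step

    def __len__(self) -> int:
        return len(self.table)


def sample_particle(cloud: ParticleCloud, rng: np.random.Generator) -> Optional[int]:
    """Select one particle index with probability ∝ weight.

    Returns None (cloud discarded) when the cloud is empty or every weight
    is zero — the cloud as a whole is then judged unlikely.
    """
    if cloud.is_empty:
        return None
    total = cloud.weight.sum()
    if not total > 0:
        return None
    p = cloud.weight / total
    return int(rng.choice(cloud.n, p=p))


def geographic_medoid(lons, lats) -> int:
    """Index of the point minimizing the summed great-circle distance to all others.

    Ties broken by the lowest input index. O(n²) pairwise haversine, exact.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.size == 0:
        raise ValueError("medoid of empty set")
    if lons.size == 1:
        return 0
    d = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    return int(np.argmin(d.sum(axis=1)))


def uncertainty_quantiles(lons, lats, medoid_lon, medoid_lat) -> dict:
    """Empirical spread of the per-step position collection around the medoid.

    Distance quantiles use numpy's default linear interpolation; the lon /
    lat intervals are the central 50% and 95% empirical intervals.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    d = haversine_km(medoid_lon, medoid_lat, lons, lats)
    q50, q95 = np.quantile(d, [0.50, 0.95])
    lon_lo50, lon_hi50, lon_lo95, lon_hi95 = np.quantile(lons, [0.25, 0.75, 0.025, 0.975])
    lat_lo50, lat_hi50, lat_lo95, lat_hi95 = np.quantile(lats, [0.25, 0.75, 0.025, 0.975])
    return {
        "q50_km": float(q50),
        "q95_km": float(q95),
        "lon_i50": (float(lon_lo50), float(lon_hi50)),
        "lon_i95": (float(lon_lo95), float(lon_hi95)),
        "lat_i50": (float(lat_lo50), float(lat_hi50)),
        "lat_i95": (float(lat_lo95), float(lat_hi95)),
    }


def build_path(
    pairs: Sequence[TwilightPair],
    inputs: AlgorithmInputs,
    cfg: AlgorithmConfig,
    rng: np.random.Generator,
    iteration_id: int = 0,
    windows=None,
    logger_sst: Optional[np.ndarray] = None,
) -> Path:
    """Run one forward iteration over all twilight pairs (steps 1–6)."""
    mids = [p.mid_time for p in pairs]
    if any(b <= a for a, b in zip(mids, mids[1:])):
        raise ValueError("twilight pairs must be strictly time-ordered")
    if windows is None and pairs:
        windows = cfg.windows_for(mids[0], mids[-1])
    if logger_sst is None:
        logger_sst = inputs.per_step_logger_sst(mids)

    prev_lon, prev_lat = inputs.release.lon, inputs.release.lat
    prev_time = pd.Timestamp(inputs.release_time)

    idxs, lons, lats, angs, rnds, times, skipped = [], [], [], [], [], [], []
    for step, pair in enumerate(pairs):
        cloud = generate_cloud(pair, cfg, rng, step_index=step, windows=windows)
        cloud = east_west_compensation(prev_lon, cloud, cfg)
        factors = []
        if inputs.land_mask is not None:
            factors.append(land_weight(cloud, inputs.land_mask, cfg.land_mode))
        dt_h = (pair.mid_time - prev_time).total_seconds() / 3600.0
        if dt_h > 0 and not cloud.is_empty:
            wf = (
                wet_fraction(inputs.immersion, prev_time, pair.mid_time)
                if inputs.immersion is not None
                else 0.0
            )
            factors.append(speed_weight(prev_lon, prev_lat, cloud, dt_h, wf, cfg))
        if inputs.sst_field is not None and logger_sst is not None:
            factors.append(sst_weight(cloud, logger_sst[step], inputs.sst_field, cfg))
        cloud = combine_weights(cloud, *factors)
        choice = sample_particle(cloud, rng)
        if choice is None:
            skipped.append(step)   # time since last kept step keeps accumulating
            continue
        idxs.append(step)
        lons.append(float(cloud.lon[choice]))
        lats.append(float(cloud.lat[choice]))
        angs.append(float(cloud.angle[choice]))
        rnds.append(bool(cloud.lat_randomized[choice]))
        times.append(pair.mid_time)
        prev_lon, prev_lat, prev_time = lons[-1], lats[-1], pair.mid_time

    return Path(
        iteration_id=iteration_id,
        step_indices=np.asarray(idxs, dtype=int),
        mid_times=pd.DatetimeIndex(times),
        lons=np.asarray(lons, dtype=float),
        lats=np.asarray(lats, dtype=float),
        angles=np.asarray(angs, dtype=float),
        lat_randomized=np.asarray(rnds, dtype=bool),
        skipped_steps=skipped,
    )


def median_track_from_ensemble(ensemble: PathEnsemble, pairs: Sequence[TwilightPair]) -> MedianTrack:
    """Assemble the geographic-medoid track and per-step uncertainty (step 8)."""
    rows = []
    n_iter = len(ensemble.paths)
    for step, pair in enumerate(pairs):
        ids, lons, lats, angs, rnd = ensemble.positions_at(step)
        if ids.size == 0:
            continue
        m = geographic_medoid(lons, lats)
        q = uncertainty_quantiles(lons, lats, lons[m], lats[m])
        rows.append(
            {
                "step_index": step,
                "mid_time": pair.mid_time,
                "lon": lons[m],
                "lat": lats[m],
                "q50_km": q["q50_km"],
                "q95_km": q["q95_km"],
                "lon_lo95": q["lon_i95"][0],
                "lon_hi95": q["lon_i95"][1],
                "lat_lo95": q["lat_i95"][0],
                "lat_hi95": q["lat_i95"][1],
                "retention": ids.size / n_iter,
                "lat_randomized_frac": float(rnd.mean()),
                "n_positions": int(ids.size),
            }
        )
    columns = [
        "step_index", "mid_time", "lon", "lat", "q50_km", "q95_km",
        "lon_lo95", "lon_hi95", "lat_lo95", "lat_hi95",
        "retention", "lat_randomized_frac", "n_positions",
    ]
    return MedianTrack(pd.DataFrame(rows, columns=columns))


def run_algorithm(
    pairs: Sequence[TwilightPair],
    inputs: AlgorithmInputs,
    cfg: AlgorithmConfig,
):
    """Full run (steps 1–8): iterate paths, then medoid track + uncertainty.

    Each iteration draws from an independent RNG substream spawned from
    ``cfg.rng_seed``, so results are reproducible bit-for-bit for a given
    seed and independent across iterations.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no twilight pairs")
    mids = [p.mid_time for p in pairs]
    windows = cfg.windows_for(mids[0], mids[-1])
    logger_sst = inputs.per_step_logger_sst(mids)
    streams = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.iteration_number)
    paths = [
        build_path(
            pairs,
            inputs,
            cfg,
            np.random.default_rng(streams[i]),
            iteration_id=i,
            windows=windows,
            logger_sst=logger_sst,
        )
        for i in range(cfg.iteration_number)
    ]
    ensemble = PathEnsemble(paths=paths, n_steps=len(pairs))
    track = median_track_from_ensemble(ensemble, pairs)
    return ensemble, track


def sensitivity_analysis(
    pairs: Sequence[TwilightPair],
    inputs: AlgorithmInputs,
    cfg: AlgorithmConfig,
    truth: pd.DataFrame,
    particle_numbers: Sequence[int] = (),
    iteration_numbers: Sequence[int] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Median track error as particle / iteration counts vary.

    ``truth`` maps step mid-times to true positions (columns ``time``,
    ``lon``, ``lat``). One axis is varied at a time, the other held at
    ``cfg``'s value. Returns a long DataFrame with columns ``parameter, value,
    median_error_km`` (medoid-track error), ``nearest_error_km`` (closest
    iterated position per step) and ``n_steps``.
    """
    import dataclasses

    rows = []
    runs = [("particle_number", int(v)) for v in particle_numbers]
    runs += [("iteration_number", int(v)) for v in iteration_numbers]
    for param, value in runs:
        c = dataclasses.replace(cfg, **{param: value, "rng_seed": seed})
        ensemble, track = run_algorithm(pairs, inputs, c)
        err = track_error_km(track, truth)
        nearest = ensemble_nearest_error_km(ensemble, pairs, truth)
        rows.append(
            {
                "parameter": param,
                "value": value,
                "median_error_km": float(np.median(err)) if err.size else np.nan,
                "nearest_error_km": float(np.median(nearest)) if nearest.size else np.nan,
                "n_steps": int(err.size),
            }
        )
    return pd.DataFrame(rows)


def ensemble_nearest_error_km(
    ensemble: PathEnsemble, pairs: Sequence[TwilightPair], truth: pd.DataFrame
) -> np.ndarray:
    """Per-step distance from the closest iterated position to the truth.

    The iterated location cloud for a step is the set of selected particles
    across iterations; its minimum distance to the true position measures
    how well the ensemble covers the truth (the classical sensitivity
    metric for particle/iteration counts).
    """
    tt = pd.to_datetime(truth["time"]).astype("int64").to_numpy()
    order = np.argsort(tt)
    tt = tt[order]
    tlon = np.asarray(truth["lon"], dtype=float)[order]
    tlat = np.asarray(truth["lat"], dtype=float)[order]
    out = []
    for step, pair in enumerate(pairs):
        _, lons, lats, _, _ = ensemble.positions_at(step)
        if lons.size == 0:
            continue
        q = pair.mid_time.value
        lo = np.interp(q, tt, tlon)
        la = np.interp(q, tt, tlat)
        out.append(float(np.min(haversine_km(lons, lats, lo, la))))
    return np.asarray(out)


def track_error_km(track: MedianTrack, truth: pd.DataFrame) -> np.ndarray:
    """Great-circle error of each track step against interpolated truth."""
    if len(track) == 0:
        return np.zeros(0)
    tt = pd.to_datetime(truth["time"]).astype("int64").to_numpy()
    order = np.argsort(tt)
    tt = tt[order]
    tlon = np.asarray(truth["lon"], dtype=float)[order]
    tlat = np.asarray(truth["lat"], dtype=float)[order]
    q = pd.to_datetime(track.table["mid_time"]).astype("int64").to_numpy()
    lon_i = np.interp(q, tt, tlon)
    lat_i = np.interp(q, tt, tlat)
    return haversine_km(track.table["lon"].to_numpy(), track.table["lat"].to_numpy(), lon_i, lat_i)
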
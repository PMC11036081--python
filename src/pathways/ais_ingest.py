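"""Parse, validate, hourly-resolve, zone-filter and stationarity-classify AIS records.

The interchange format is a CSV with the exact columns
``mmsi, imo, name, timestamp_utc, lat, lon, course_deg, status, speed_kn,
origin_port`` (ISO-8601 UTC timestamps, WGS84 decimal degrees, speed in
knots).  Records are carried as a pandas DataFrame sorted by
``(mmsi, timestamp)``; malformed rows are dropped and counted.

Track preparation reduces each vessel's stream to at most one point per
clock hour, computes sequential great-circle displacements, flags
stationary hours (moved < 400 m over the hour *and* reported speed
< 1 kn), and keeps only vessels that entered the maritime zone at least
once.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely

from .geo import haversine_m
from .types import AIS_COLUMNS, ConfigurationError, SchemaError, StudyArea

log = logging.getLogger(__name__)

_MANDATORY = ("mmsi", "timestamp_utc", "lat", "lon", "speed_kn")


def read_ais_csv(path) -> pd.DataFrame:
    """Read and validate an AIS CSV.

    Returns records sorted by ``(mmsi, timestamp)`` with a parsed UTC
    ``timestamp`` column.  Rows with unparseable timestamps,
    out-of-range coordinates or negative speeds are dropped; the drop
    count is logged and stored in ``df.attrs["n_dropped"]``.

    Raises
    ------
    SchemaError
        If a mandatory column is missing (the message names it).
    """
    df = pd.read_csv(path, dtype={"name": str, "status": str, "origin_port": str,
                                  "imo": "object"})
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"AIS CSV is missing mandatory column {col!r}")
    for col in AIS_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in ("name", "status", "origin_port") else np.nan

    n_raw = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp_utc"], errors="coerce", utc=True)
    df["mmsi"] = pd.to_numeric(df["mmsi"], errors="coerce")
    for col in ("lat", "lon", "speed_kn", "course_deg"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ok = (df["timestamp"].notna() & df["mmsi"].notna()
          & df["lat"].between(-90.0, 90.0) & df["lon"].between(-180.0, 180.0)
          & (df["speed_kn"] >= 0.0))
    dropped = int(n_raw - ok.sum())
    if dropped:
        log.warning("read_ais_csv: dropped %d malformed row(s) of %d", dropped, n_raw)
    df = df.loc[ok].copy()
    df["mmsi"] = df["mmsi"].astype(np.int64)
    df["origin_port"] = df["origin_port"].fillna("")
    df = df.sort_values(["mmsi", "timestamp"], kind="mergesort").reset_index(drop=True)
    df.attrs["n_dropped"] = dropped
    return df


def resample_hourly(records: pd.DataFrame) -> pd.DataFrame:
    """Reduce one vessel's records to at most one point per clock hour.

    The *last* report within each hour bin is retained and stamped with
    the bin start, so hourly spacing is exact and the operation is
    idempotent.  Sequential displacements are great-circle distances
    between consecutive retained points; ``gap_h`` is the whole-hour gap
    to the previous point (NaN for the first).  Gaps are preserved, not
    interpolated.
    """
    if records.empty:
        return pd.DataFrame(columns=["mmsi", "timestamp", "lat", "lon",
                                     "reported_speed", "displacement_m", "gap_h"])
    df = records.sort_values("timestamp", kind="mergesort")
    hours = df["timestamp"].dt.floor("h")
    keep = ~hours.duplicated(keep="last")
    out = pd.DataFrame({
        "mmsi": df.loc[keep, "mmsi"].to_numpy(),
        "timestamp": hours[keep].to_numpy(),
        "lat": df.loc[keep, "lat"].to_numpy(dtype=float),
        "lon": df.loc[keep, "lon"].to_numpy(dtype=float),
        "reported_speed": df.loc[keep, "speed_kn"].to_numpy(dtype=float),
    })
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True)
    disp = np.full(len(out), np.nan)
    if len(out) > 1:
        disp[1:] = haversine_m(out["lat"].to_numpy()[:-1], out["lon"].to_numpy()[:-1],
                               out["lat"].to_numpy()[1:], out["lon"].to_numpy()[1:])
    out["displacement_m"] = disp
    gap = out["timestamp"].diff().dt.total_seconds() / 3600.0
    out["gap_h"] = gap
    return out.reset_index(drop=True)


def classify_stationary(track: pd.DataFrame, study: StudyArea | None = None) -> pd.DataFrame:
    """Flag stationary hours on one vessel's hourly track.

    A point is stationary when *both* hold: displacement over the
    preceding one-hour interval < 400 m, and reported speed < 1 kn.  The
    first point of a track has no displacement and inherits the flag
    from its speed test alone.  Across a gap of more than one hour the
    displacement is not comparable to the 400 m/h rule, so the speed
    test alone decides and the point is flagged ``is_gap``.
    """
    study = study or StudyArea()
    track = track.copy()
    if track.empty:
        track["stationary"] = pd.Series(dtype=bool)
        track["is_gap"] = pd.Series(dtype=bool)
        return track
    speed_ok = track["reported_speed"].to_numpy() < study.stationary_speed_max_kn
    disp = track["displacement_m"].to_numpy()
    gap = track["gap_h"].to_numpy()
    one_hour = np.isclose(gap, 1.0)
    disp_ok = disp < study.stationary_move_max_m
    stationary = np.where(one_hour, speed_ok & disp_ok, speed_ok)
    track["stationary"] = stationary
    track["is_gap"] = ~one_hour & ~np.isnan(gap)
    return track


def filter_zone_vessels(tracks: pd.DataFrame, study: StudyArea) -> set:
    """Vessels (MMSIs) that entered the maritime zone at least once.

    A vessel is retained iff at least one of its points falls inside the
    zone polygon; callers keep the *full* track of retained vessels.
    """
    zone = study.maritime_zone
    if zone is None or zone.is_empty or not zone.is_valid:
        raise ConfigurationError("maritime zone polygon is missing or degenerate")
    if tracks.empty:
        return set()
    inside = shapely.contains_xy(zone, tracks["lon"].to_numpy(), tracks["lat"].to_numpy())
    return set(tracks.loc[inside, "mmsi"].unique().tolist())


def prepare_tracks(records: pd.DataFrame, study: StudyArea) -> pd.DataFrame:
    """Full track preparation for a multi-vessel record stream.

    Hourly resampling and stationarity classification per vessel, then
    the zone filter.  Returns the concatenated per-vessel tracks of
    retained vessels, time-sorted within vessel.
    """
    pieces = []
    for _, grp in records.groupby("mmsi", sort=True):
        pieces.append(classify_stationary(resample_hourly(grp), study))
    if not pieces:
        return pd.DataFrame(columns=["mmsi", "timestamp", "lat", "lon", "reported_speed",
                                     "displacement_m", "gap_h", "stationary", "is_gap"])
    tracks = pd.concat(pieces, ignore_index=True)
    kept = filter_zone_vessels(tracks, study)
    n_excluded = tracks["mmsi"].nunique() - len(kept)
    if n_excluded:
        log.info("zone filter: excluded %d vessel(s) that never entered the zone", n_excluded)
    return tracks[tracks["mmsi"].isin(kept)].reset_index(drop=True)
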
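"""Shared domain types and the study-area configuration.

Bulk data (position records, track points, stop events) travels through
the pipeline as pandas DataFrames with documented column schemas; the
small, identity-like objects (vessel profiles, anchorage nodes, journey
segments, the study area) are dataclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geo import NM_TO_M

#: The nine vessel classes used throughout the analysis.
VESSEL_TYPES = ("Bulk", "Cargo", "Fishing", "Offshore", "Passenger",
                "Pilot", "Pleasure", "Tanker", "Tender")

#: Exact column order of the AIS CSV interchange format.
AIS_COLUMNS = ("mmsi", "imo", "name", "timestamp_utc", "lat", "lon",
               "course_deg", "status", "speed_kn", "origin_port")


class ConfigurationError(ValueError):
    """Raised for invalid study-area / pipeline configuration."""


class SchemaError(ValueError):
    """Raised when an input file does not match the expected schema."""


@dataclass
class StudyArea:
    """Spatial filters and stationarity thresholds of the analysis.

    The defaults describe a sub-Antarctic area of interest spanning
    68.5-45 degrees S and 77-15 degrees W, a 200 nm maritime zone used to
    select vessels, a 12 nm coastal band inside which anchorage nodes are
    formed, and the two-condition stationarity rule: a vessel is
    stationary in an hour when it moved less than 400 m *and* its
    reported speed is below 1 kn.  The 0.2 kn underway threshold is the
    speed-equivalent of 400 m/h and is kept as metadata only.
    """

    lat_min: float = -68.5
    lat_max: float = -45.0
    lon_min: float = -77.0
    lon_max: float = -15.0
    maritime_zone: Optional[object] = None  # shapely Polygon, lon/lat order
    coastal_band_nm: float = 12.0
    stationary_move_max_m: float = 400.0
    stationary_speed_max_kn: float = 1.0
    underway_speed_min_kn: float = 0.2
    node_buffer_km: float = 5.0
    cluster_link_km: float = 10.0
    rest_threshold_days: float = 30.0

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ConfigurationError("study-area bounding box is not ordered")
        for name in ("coastal_band_nm", "stationary_move_max_m",
                     "stationary_speed_max_kn", "underway_speed_min_kn",
                     "node_buffer_km", "cluster_link_km", "rest_threshold_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")

    @property
    def coastal_band_m(self) -> float:
        return self.coastal_band_nm * NM_TO_M

    def stationary_speed_equivalent_kn(self) -> float:
        """Speed (kn) equivalent to the displacement threshold over one hour.

        400 m/h is 400/1852 = 0.216 kn, i.e. ~0.2 kn: the displacement
        rule and the underway speed cut-off express the same threshold.
        """
        return self.stationary_move_max_m / NM_TO_M

    def in_bbox(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        ok = ((lat >= self.lat_min) & (lat <= self.lat_max)
              & (lon >= self.lon_min) & (lon <= self.lon_max))
        return ok if ok.ndim else bool(ok)


@dataclass
class VesselProfile:
    """Static identity and hull dimensions of one vessel.

    Missing dimensions are represented as NaN; the WSA dispatcher decides
    what each class may fall back on.
    """

    mmsi: int
    vessel_type: str
    name: str = ""
    imo: Optional[int] = None
    loa_m: float = math.nan       # length overall
    boa_m: float = math.nan       # breadth overall
    gross_tonnage: float = math.nan
    dwt_t: float = math.nan       # dead weight tonnage
    draft_m: float = math.nan
    declared_origin_port: str = ""

    def __post_init__(self) -> None:
        if self.vessel_type not in VESSEL_TYPES:
            raise ConfigurationError(
                f"unknown vessel class {self.vessel_type!r}; expected one of {VESSEL_TYPES}")
        for dim in ("loa_m", "boa_m", "gross_tonnage", "dwt_t", "draft_m"):
            v = getattr(self, dim)
            if not math.isnan(v) and v <= 0:
                raise ConfigurationError(f"{dim} must be positive or NaN (missing)")


def profiles_to_frame(profiles) -> pd.DataFrame:
    rows = [{
        "mmsi": p.mmsi, "imo": p.imo, "name": p.name, "vessel_type": p.vessel_type,
        "loa_m": p.loa_m, "boa_m": p.boa_m, "gross_tonnage": p.gross_tonnage,
        "dwt_t": p.dwt_t, "draft_m": p.draft_m,
        "declared_origin_port": p.declared_origin_port,
    } for p in profiles]
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame):
    out = []
    for row in df.itertuples(index=False):
        out.append(VesselProfile(
            mmsi=int(row.mmsi), vessel_type=row.vessel_type,
            name=getattr(row, "name", "") or "",
            imo=None if pd.isna(getattr(row, "imo", None)) else int(row.imo),
            loa_m=float(row.loa_m), boa_m=float(row.boa_m),
            gross_tonnage=float(row.gross_tonnage), dwt_t=float(row.dwt_t),
            draft_m=float(row.draft_m),
            declared_origin_port=(row.declared_origin_port
                                  if isinstance(row.declared_origin_port, str) else ""),
        ))
    return out


@dataclass
class AnchorageNode:
    """A clustered stop location (port or anchorage) or an external origin port."""

    node_id: str
    lat: float
    lon: float
    label: str
    country: str = "UNKNOWN"
    is_external: bool = False
    n_member_stops: int = 0


@dataclass
class JourneySegment:
    """One vessel's extended multi-stop journey.

    Bounded by rests longer than the configured threshold: the long stop
    terminates the journey it ends (and is included in ``event_index``),
    and its node seeds the next journey (``seed_node_id``).
    ``n_active_stops`` counts the stops short enough to be port calls,
    i.e. excludes the terminating rest.
    """

    mmsi: int
    node_ids: list = field(default_factory=list)
    event_index: list = field(default_factory=list)
    start: Optional[pd.Timestamp] = None
    end: Optional[pd.Timestamp] = None
    seed_node_id: Optional[str] = None

    @property
    def n_stops(self) -> int:
        return len(self.node_ids)
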
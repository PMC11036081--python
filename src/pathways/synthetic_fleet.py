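"""Synthetic AIS fleet simulator with a ground-truth event log.

The study's raw vessel-tracking data are confidential, so this module
generates an AIS-style record stream whose every stop, journey and
transit is known exactly, letting the pipeline be verified by
ground-truth recovery instead of against unavailable data.

The default configuration emulates the structure of a sub-Antarctic
fleet: nine vessel classes with class-specific abundance (passenger and
fishing vessels plus their tenders dominate), hull-size distributions,
a small number of extended journeys per year separated by month-plus
rests in a home port, class seasonality (summer-heavy passenger
traffic, spring-only tankers and cargo), and cross-territory routing
through a mandatory South Georgia port of call.  Parameter values are
user-set study conditions, not measured quantities.

Timing is constructed to be exactly recoverable at hourly resolution:
stop durations are floored at 3 h (shorter stops cannot be resolved by
hourly sampling) and capped safely below the 30-day journey-split
threshold, rests between journeys always exceed 32 days, consecutive
stops never repeat a port, and default ports are mutually >= 25 km
apart so each maps to its own anchorage node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import shapely

from .geo import NM_TO_M, destination, gc_interpolate, haversine_m, initial_bearing_deg
from .types import AIS_COLUMNS, ConfigurationError, VesselProfile

HOUR = pd.Timedelta(hours=1)

# --------------------------------------------------------------------------
# default geography: ports, land boxes, territories, 200 nm maritime zone

DEFAULT_PORTS = [
    # name, lat, lon, territory code
    ("King Edward Point", -54.28, -36.49, "SG"),
    ("Stromness Bay", -54.10, -36.85, "SG"),
    ("Bay of Isles", -54.02, -37.33, "SG"),
    ("St Andrews Bay", -54.43, -36.18, "SG"),
    ("Gold Harbour", -54.62, -35.93, "SG"),
    ("Cooper Bay", -54.86, -35.72, "SG"),
    ("Saunders Anchorage", -57.79, -26.45, "SS"),
    ("Stanley", -51.69, -57.86, "FK"),
    ("Ushuaia", -54.80, -68.30, "AR"),
    ("Punta Arenas", -53.16, -70.91, "CL"),
    ("Esperanza Station", -63.40, -56.98, "AQ"),
]

#: Declared ports of origin outside the area of interest.
EXTERNAL_PORTS = [
    ("Montevideo", -34.90, -56.21, "UY"),
    ("Cape Town", -33.91, 18.43, "ZA"),
    ("Las Palmas", 28.13, -15.43, "ES"),
]

_LAND_BOXES = {
    "SG": (-38.3, -55.2, -35.0, -53.7),
    "SS": (-28.0, -59.8, -25.5, -56.2),
    "FK": (-59.5, -52.5, -57.0, -51.0),
    "AR": (-69.5, -55.3, -67.5, -54.2),
    "CL": (-71.8, -53.8, -70.0, -52.6),
    "AQ": (-58.0, -64.0, -56.0, -63.0),
}


@dataclass
class Geography:
    """Polygons and lookup tables the pipeline consumes (all WGS84 lon/lat)."""

    coastline: list
    territories: list           # (code, Polygon)
    zone: shapely.Polygon       # 200 nm maritime zone
    gazetteer: pd.DataFrame     # name, lat, lon, country
    world_ports: pd.DataFrame   # gazetteer plus external origin ports
    home_code: str = "SG"


def synthetic_geography(zone_center=(-54.4, -36.3), zone_radius_nm=200.0) -> Geography:
    """Synthetic study geography matching the default port catalog.

    Land masses are rectangles around each territory's ports, the
    territory table reuses them (South Georgia and the South Sandwich
    Islands carry distinct codes), and the maritime zone is a 200 nm
    circle built point-by-point with the spherical destination formula.
    """
    coastline = [shapely.box(*b) for b in _LAND_BOXES.values()]
    territories = [(code, shapely.box(*b)) for code, b in _LAND_BOXES.items()]
    az = np.linspace(0.0, 360.0, 73)[:-1]
    la, lo = destination(zone_center[0], zone_center[1], az, zone_radius_nm * NM_TO_M)
    zone = shapely.Polygon(np.column_stack([lo, la]))
    gaz = pd.DataFrame(DEFAULT_PORTS, columns=["name", "lat", "lon", "country"])
    world = pd.concat([gaz, pd.DataFrame(EXTERNAL_PORTS, columns=gaz.columns)],
                      ignore_index=True)
    return Geography(coastline=coastline, territories=territories, zone=zone,
                     gazetteer=gaz, world_ports=world)


# --------------------------------------------------------------------------
# fleet configuration

@dataclass
class ClassParams:
    """Behavioural and hull-size parameters for one vessel class."""

    n_vessels: int
    journeys_per_year: float
    stops_per_journey: float
    stop_duration_mean_h: float
    stop_duration_sigma: float = 0.6
    season_months: tuple = tuple(range(1, 13))
    cruise_kn: float = 11.0
    loa_m: float = 50.0          # median; draws are lognormal around medians
    boa_m: float = 9.0
    gross_tonnage: float = 1000.0
    dwt_t: float = 1500.0
    draft_m: float = 4.0
    size_sigma: float = 0.15
    dwt_missing_prob: float = 0.0
    home_ports: tuple = (("Stanley", 1.0),)
    visit_pool: tuple = ("King Edward Point", "Stromness Bay", "Bay of Isles",
                         "St Andrews Bay", "Gold Harbour", "Cooper Bay")
    declare_origin_prob: float = 0.0


_SUMMER = (10, 11, 12, 1, 2, 3)
_SG_POOL = ("King Edward Point", "Stromness Bay", "Bay of Isles",
            "St Andrews Bay", "Gold Harbour", "Cooper Bay")

# Journey rates are chosen jointly with the season windows so that the
# configured number of journeys (plus the >32-day rests between them)
# always fits inside each class's season: the realised class mean then
# equals the configured rate up to rare end-of-study truncation.
DEFAULT_CLASSES = {
    "Bulk": ClassParams(1, 1.0, 1.0, 8.0, season_months=(11,), cruise_kn=11,
                        loa_m=180, boa_m=30, gross_tonnage=35000, dwt_t=40000,
                        draft_m=11, home_ports=(("Stanley", 1.0),)),
    "Cargo": ClassParams(4, 1.8, 6.0, 45.0, season_months=(9, 10, 11), cruise_kn=12,
                         loa_m=120, boa_m=19, gross_tonnage=7000, dwt_t=8000,
                         draft_m=7, home_ports=(("Stanley", 0.7), ("Punta Arenas", 0.3)),
                         declare_origin_prob=0.4),
    "Fishing": ClassParams(20, 2.3, 6.0, 71.0,
                           season_months=(3, 4, 5, 6, 7, 8, 9, 10), cruise_kn=9,
                           loa_m=45, boa_m=10, gross_tonnage=900, dwt_t=1200,
                           draft_m=5, dwt_missing_prob=0.3,
                           home_ports=(("Stanley", 0.5), ("King Edward Point", 0.25),
                                       ("Punta Arenas", 0.25)),
                           visit_pool=_SG_POOL + ("Saunders Anchorage",)),
    "Offshore": ClassParams(10, 1.9, 8.0, 19.0,
                            season_months=(1, 2, 3, 4, 5, 6, 7, 8, 12), cruise_kn=11,
                            loa_m=70, boa_m=14, gross_tonnage=2200, dwt_t=2500,
                            draft_m=5, dwt_missing_prob=0.3,
                            home_ports=(("Stanley", 0.6), ("Esperanza Station", 0.4))),
    "Passenger": ClassParams(26, 2.0, 12.0, 6.0, season_months=_SUMMER, cruise_kn=14,
                             loa_m=180, boa_m=25, gross_tonnage=30000, dwt_t=5000,
                             draft_m=7, dwt_missing_prob=0.2,
                             home_ports=(("Ushuaia", 0.8), ("Stanley", 0.2)),
                             declare_origin_prob=0.3),
    "Pilot": ClassParams(2, 2.5, 3.0, 15.0, cruise_kn=9,
                         loa_m=15, boa_m=4.5, gross_tonnage=40, dwt_t=20, draft_m=1.8,
                         dwt_missing_prob=0.5, home_ports=(("King Edward Point", 1.0),)),
    "Pleasure": ClassParams(10, 2.3, 8.0, 20.0, season_months=_SUMMER, cruise_kn=8,
                            loa_m=22, boa_m=5.5, gross_tonnage=60, dwt_t=float("nan"),
                            draft_m=2.5, size_sigma=0.45, dwt_missing_prob=1.0,
                            home_ports=(("Stanley", 0.5), ("Ushuaia", 0.5))),
    "Tanker": ClassParams(3, 2.0, 4.0, 25.0, season_months=(9, 10, 11), cruise_kn=12,
                          loa_m=150, boa_m=24, gross_tonnage=25000, dwt_t=30000,
                          draft_m=10, home_ports=(("Punta Arenas", 1.0),),
                          declare_origin_prob=0.4),
    # tenders mirror a mother passenger vessel's routing; journeys/stops follow hers
    "Tender": ClassParams(25, 2.0, 12.0, 4.0, stop_duration_sigma=0.3, cruise_kn=9,
                          loa_m=5, boa_m=2, gross_tonnage=2, dwt_t=float("nan"),
                          draft_m=0.6, dwt_missing_prob=1.0,
                          home_ports=(("Ushuaia", 1.0),)),
}


@dataclass
class FleetConfig:
    """Study conditions of the simulated fleet.

    ``min_stop_h``/``max_stop_h`` bound drawn stop durations (hourly
    resolution floor; cap safely below the rest threshold), and
    ``rest_min_days`` keeps inter-journey rests above the >1 month
    journey-split rule.  A fixed seed gives byte-identical output.
    """

    n_years: int = 2
    start: str = "2017-07-01"
    classes: dict = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    port_catalog: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(DEFAULT_PORTS,
                                             columns=["name", "lat", "lon", "country"]))
    seed: int = 0
    jitter_sigma_m: float = 0.0   # optional AIS positional noise
    dropout_prob: float = 0.0     # optional record-loss probability
    min_stop_h: float = 3.0
    max_stop_h: float = 300.0
    rest_min_days: float = 32.0
    max_journeys_per_year: int = 4

    def __post_init__(self):
        if len(self.port_catalog) == 0:
            raise ConfigurationError("port catalog must not be empty")
        for cls, p in self.classes.items():
            if p.n_vessels < 0:
                raise ConfigurationError(f"{cls}: vessel count must be >= 0")
            if not set(p.season_months) <= set(range(1, 13)):
                raise ConfigurationError(f"{cls}: season months must lie in 1..12")
        if self.n_years < 0:
            raise ConfigurationError("n_years must be >= 0")

    @property
    def study_start(self) -> pd.Timestamp:
        return pd.Timestamp(self.start, tz="UTC")

    @property
    def study_end(self) -> pd.Timestamp:
        return self.study_start + pd.Timedelta(days=365 * self.n_years)

    def port_location(self, name: str):
        row = self.port_catalog[self.port_catalog["name"] == name]
        if row.empty:
            raise ConfigurationError(f"port {name!r} not in catalog")
        return float(row["lat"].iloc[0]), float(row["lon"].iloc[0])


@dataclass
class TruthLog:
    """Ground truth of the simulated fleet.

    ``stops`` has one row per true stationary episode (kind ``call`` for
    port calls during a journey, ``rest`` for month-plus lay-ups);
    ``journeys`` lists each extended journey's ordered port calls; and
    ``transits`` the underway legs between consecutive stops.
    """

    stops: pd.DataFrame
    journeys: list
    transits: pd.DataFrame

    @property
    def port_calls(self) -> pd.DataFrame:
        return self.stops[self.stops["kind"] == "call"]

    def to_json(self, path) -> None:
        payload = {
            "stops": [
                {"mmsi": int(r.mmsi), "port": r.port, "kind": r.kind,
                 "start": r.start.isoformat(), "end": r.end.isoformat()}
                for r in self.stops.itertuples(index=False)],
            "journeys": [
                {"mmsi": int(j["mmsi"]), "ports": list(j["ports"]),
                 "start": j["start"].isoformat(), "end": j["end"].isoformat()}
                for j in self.journeys],
            "transits": [
                {"mmsi": int(r.mmsi), "from_port": r.from_port, "to_port": r.to_port,
                 "dep": r.dep.isoformat(), "arr": r.arr.isoformat()}
                for r in self.transits.itertuples(index=False)],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthLog":
        with open(path) as fh:
            payload = json.load(fh)
        stops = pd.DataFrame(payload["stops"], columns=_STOP_COLS)
        for col in ("start", "end"):
            stops[col] = pd.to_datetime(stops[col], utc=True, format="ISO8601")
        journeys = [{"mmsi": j["mmsi"], "ports": j["ports"],
                     "start": pd.Timestamp(j["start"]), "end": pd.Timestamp(j["end"])}
                    for j in payload["journeys"]]
        transits = pd.DataFrame(payload["transits"], columns=_TRANSIT_COLS)
        for col in ("dep", "arr"):
            transits[col] = pd.to_datetime(transits[col], utc=True, format="ISO8601")
        return cls(stops=stops, journeys=journeys, transits=transits)

    def transition_counts(self) -> dict:
        """True directed port-to-port trip counts over all vessels.

        Consecutive distinct-port stop pairs per vessel -- the quantity
        the voyage network's edge weights must recover.
        """
        counts: dict = {}
        for _, grp in self.stops.groupby("mmsi", sort=True):
            ports = grp.sort_values("start")["port"].tolist()
            for a, b in zip(ports[:-1], ports[1:]):
                if a != b:
                    counts[(a, b)] = counts.get((a, b), 0) + 1
        return counts


_STOP_COLS = ["mmsi", "port", "kind", "start", "end"]
_TRANSIT_COLS = ["mmsi", "from_port", "to_port", "dep", "arr"]


# --------------------------------------------------------------------------
# generation

class _BalancedCounter:
    """Integer sequence with base floor(mean) and Bresenham-spread extras.

    Successive calls return floor(mean) or floor(mean)+1 such that the
    running mean equals ``mean`` to within 1/k after k calls.  Used for
    journey and stop counts so class-level parameter recovery is a sharp
    check rather than a sampling-noise one; the *composition* of each
    journey (ports, durations, timing) stays random.
    """

    def __init__(self, mean: float):
        self.base = int(np.floor(mean))
        self.frac = mean - self.base
        self.k = 0

    def __call__(self) -> int:
        self.k += 1
        extra = int(np.floor(self.k * self.frac) - np.floor((self.k - 1) * self.frac))
        return max(1, self.base + extra)


def _draw_duration_h(rng, params: ClassParams, cfg: FleetConfig) -> float:
    mu = np.log(params.stop_duration_mean_h) - params.stop_duration_sigma ** 2 / 2.0
    d = float(np.exp(rng.normal(mu, params.stop_duration_sigma)))
    return float(np.clip(d, cfg.min_stop_h, cfg.max_stop_h))


def _advance_to_season(t: pd.Timestamp, months, study_end: pd.Timestamp, rng=None):
    """First instant at or after ``t`` whose month is in the season window.

    When the month jumps, a random offset within the target month keeps
    departures from piling up on the first of the month.
    """
    jumped = False
    while t.month not in months:
        t = (t + pd.offsets.MonthBegin(1)).normalize() + pd.Timedelta(hours=6)
        jumped = True
        if t >= study_end:
            return None
    if jumped and rng is not None:
        month_end = (t + pd.offsets.MonthBegin(1)).normalize()
        max_off_h = max((month_end - t) / HOUR - 24.0, 0.0)
        t = t + pd.Timedelta(hours=float(rng.uniform(0.0, min(18 * 24.0, max_off_h))))
    return t if t < study_end else None


def _build_route(rng, k: int, pool, home: str):
    """k port calls, first one the mandatory entry port where available,
    no consecutive repeats, endpoints different from the home port."""
    pool = [p for p in pool]
    first = "King Edward Point" if "King Edward Point" in pool else pool[0]
    if first == home:
        others = [p for p in pool if p != home]
        first = others[int(rng.integers(len(others)))] if others else first
    route = [first]
    while len(route) < k:
        last = len(route) == k - 1
        cands = [p for p in pool if p != route[-1] and not (last and p == home)]
        if not cands:
            cands = [p for p in pool if p != route[-1]]
        if not cands:
            break  # degenerate single-port pool: shorter route
        route.append(cands[int(rng.integers(len(cands)))])
    return route


def _travel_h(cfg: FleetConfig, a: str, b: str, cruise_kn: float) -> float:
    la1, lo1 = cfg.port_location(a)
    la2, lo2 = cfg.port_location(b)
    d = haversine_m(la1, lo1, la2, lo2)
    return d / NM_TO_M / cruise_kn


def _draw_size(rng, median: float, sigma: float) -> float:
    if np.isnan(median):
        return float("nan")
    return float(median * np.exp(rng.normal(0.0, sigma)))


def _make_profile(rng, mmsi: int, cls: str, params: ClassParams, origin: str) -> VesselProfile:
    dwt = _draw_size(rng, params.dwt_t, params.size_sigma)
    if rng.random() < params.dwt_missing_prob:
        dwt = float("nan")
    loa = _draw_size(rng, params.loa_m, params.size_sigma)
    if cls == "Pleasure":
        loa = float(np.clip(loa, 14.0, 69.0))
    return VesselProfile(
        mmsi=mmsi, vessel_type=cls, name=f"{cls.upper()} {mmsi % 1000:03d}",
        imo=7_000_000 + mmsi % 1_000_000,
        loa_m=loa, boa_m=_draw_size(rng, params.boa_m, params.size_sigma),
        gross_tonnage=_draw_size(rng, params.gross_tonnage, params.size_sigma),
        dwt_t=dwt, draft_m=_draw_size(rng, params.draft_m, params.size_sigma),
        declared_origin_port=origin)


def _schedule_vessel(rng, cfg: FleetConfig, params: ClassParams, mmsi: int,
                     n_journeys_fn, n_stops_fn, routes: Optional[list] = None):
    """Stops/journeys/transits for one vessel.

    ``routes`` overrides the drawn routes (used to tie tenders to a
    mother ship's itinerary).  Returns (stops, journeys, transits) with
    stops as (port, kind, start, end) tuples.
    """
    stops, journeys, transits = [], [], []
    home = _weighted_choice(rng, params.home_ports)
    pending_home_arrival = None
    t = cfg.study_start + pd.Timedelta(hours=float(rng.uniform(0, 72)))
    route_iter = iter(routes) if routes is not None else None
    for year in range(cfg.n_years):
        # journeys allocated to a study year are scheduled within it
        year_start = cfg.study_start + pd.Timedelta(days=365 * year)
        if t < year_start:
            t = year_start + pd.Timedelta(hours=float(rng.uniform(0, 72)))
        n_j = int(np.ceil(len(routes) / max(cfg.n_years, 1))) if route_iter is not None \
            else min(n_journeys_fn(), cfg.max_journeys_per_year)
        for _ in range(n_j):
            dep = _advance_to_season(t, params.season_months, cfg.study_end, rng)
            if dep is None:
                break
            if route_iter is not None:
                route = next(route_iter, None)
                if route is None:
                    break
                route = [p for p in route if p != home] or [route[0]]
                route = [p for i, p in enumerate(route) if i == 0 or p != route[i - 1]]
            else:
                k = n_stops_fn()
                route = _build_route(rng, k, params.visit_pool, home)
            # tentative schedule for the whole journey
            legs, calls = [], []
            cur, cur_t = home, dep
            for port in route:
                travel = pd.Timedelta(hours=_travel_h(cfg, cur, port, params.cruise_kn))
                arr = cur_t + travel
                dur = pd.Timedelta(hours=_draw_duration_h(rng, params, cfg))
                legs.append((cur, port, cur_t, arr))
                calls.append((port, arr, arr + dur))
                cur, cur_t = port, arr + dur
            travel = pd.Timedelta(hours=_travel_h(cfg, cur, home, params.cruise_kn))
            arr_home = cur_t + travel
            if arr_home > cfg.study_end - pd.Timedelta(hours=72):
                break  # journey would overrun the study window: drop it
            if pending_home_arrival is not None:
                stops.append((home, "rest", pending_home_arrival, dep))
            for frm, to, t0, t1 in legs:
                transits.append((frm, to, t0, t1))
            for port, a, b in calls:
                stops.append((port, "call", a, b))
            transits.append((cur, home, cur_t, arr_home))
            journeys.append({"mmsi": mmsi, "ports": [c[0] for c in calls],
                             "start": dep, "end": arr_home})
            pending_home_arrival = arr_home
            t = arr_home + pd.Timedelta(days=float(cfg.rest_min_days + rng.uniform(0, 10)))
    if pending_home_arrival is not None \
            and cfg.study_end - pending_home_arrival >= pd.Timedelta(hours=cfg.min_stop_h):
        stops.append((home, "rest", pending_home_arrival, cfg.study_end))
    return stops, journeys, transits


def _weighted_choice(rng, weighted):
    names = [n for n, _ in weighted]
    w = np.array([w for _, w in weighted], dtype=float)
    return names[int(rng.choice(len(names), p=w / w.sum()))]


def generate_fleet(config: FleetConfig):
    """Generate vessel profiles and the ground-truth event log.

    One profile per requested vessel; journeys respect class seasonality
    windows and stop-duration distributions; tenders replicate the
    routing of a mother passenger vessel (or fishing vessel if no
    passenger exists).  Deterministic under a fixed seed.
    """
    profiles: list[VesselProfile] = []
    stop_rows, journey_list, transit_rows = [], [], []
    mother_routes: list[tuple[int, list]] = []  # (mmsi, journey routes) of candidates

    order = [c for c in config.classes if c != "Tender"] + \
            (["Tender"] if "Tender" in config.classes else [])
    vessel_idx = 0
    for cls in order:
        params = config.classes[cls]
        n_journeys_fn = _BalancedCounter(params.journeys_per_year)
        n_stops_fn = _BalancedCounter(params.stops_per_journey)
        for _ in range(params.n_vessels):
            rng = np.random.default_rng([max(config.seed, 0), vessel_idx])
            mmsi = 200_000_000 + vessel_idx
            origin = ""
            if rng.random() < params.declare_origin_prob:
                ext = EXTERNAL_PORTS[int(rng.integers(len(EXTERNAL_PORTS)))]
                origin = ext[0]
            profiles.append(_make_profile(rng, mmsi, cls, params, origin))
            routes = None
            if cls == "Tender" and mother_routes:
                _, mroutes = mother_routes[int(rng.integers(len(mother_routes)))]
                routes = [list(r) for r in mroutes]
            stops, journeys, transits = _schedule_vessel(
                rng, config, params, mmsi, n_journeys_fn, n_stops_fn, routes)
            if cls in ("Passenger", "Fishing") and journeys:
                mother_routes.append((mmsi, [j["ports"] for j in journeys]))
            for port, kind, a, b in stops:
                stop_rows.append({"mmsi": mmsi, "port": port, "kind": kind,
                                  "start": a, "end": b})
            journey_list.extend(journeys)
            for frm, to, t0, t1 in transits:
                transit_rows.append({"mmsi": mmsi, "from_port": frm, "to_port": to,
                                     "dep": t0, "arr": t1})
            vessel_idx += 1

    stops = pd.DataFrame(stop_rows, columns=_STOP_COLS)
    transits = pd.DataFrame(transit_rows, columns=_TRANSIT_COLS)
    if len(stops):
        stops = stops.sort_values(["mmsi", "start"], kind="mergesort").reset_index(drop=True)
        transits = transits.sort_values(["mmsi", "dep"], kind="mergesort").reset_index(drop=True)
    return profiles, TruthLog(stops=stops, journeys=journey_list, transits=transits)


# --------------------------------------------------------------------------
# track emission

def simulate_tracks(profiles, truth: TruthLog, config: FleetConfig,
                    step_h: float = 1.0) -> pd.DataFrame:
    """Emit AIS position records for the fleet at a fixed time step.

    During a true stop the vessel sits at the port coordinate (plus
    optional Gaussian jitter) with near-zero speed; between consecutive
    stops it moves along the great-circle leg at the implied speed.
    Records are emitted on whole multiples of ``step_h`` from the start
    of each vessel's first stop, time-sorted per vessel.
    """
    if step_h <= 0:
        raise ConfigurationError("step_h must be positive")
    if truth.stops.empty:
        return pd.DataFrame(columns=list(AIS_COLUMNS) + ["timestamp"])
    prof_of = {p.mmsi: p for p in profiles}
    coords = {name: config.port_location(name)
              for name in truth.stops["port"].unique()}
    rng = np.random.default_rng([max(config.seed, 0), 999_983])
    frames = []
    for mmsi, grp in truth.stops.groupby("mmsi", sort=True):
        p = prof_of.get(mmsi)
        grp = grp.sort_values("start")
        rows = _emit_vessel(grp, coords, step_h)
        if rows is None:
            continue
        ts, lats, lons, speeds, courses, statuses = rows
        if config.jitter_sigma_m > 0:
            dlat = rng.normal(0, config.jitter_sigma_m / 111_320.0, len(lats))
            dlon = rng.normal(0, config.jitter_sigma_m / 111_320.0, len(lats)) \
                / np.cos(np.radians(lats))
            lats = lats + dlat
            lons = lons + dlon
        df = pd.DataFrame({
            "mmsi": mmsi,
            "imo": p.imo if p else "",
            "name": p.name if p else "",
            "timestamp": ts,
            "lat": lats, "lon": lons,
            "course_deg": courses,
            "status": statuses,
            "speed_kn": speeds,
            "origin_port": p.declared_origin_port if p else "",
        })
        if config.dropout_prob > 0:
            df = df[rng.random(len(df)) >= config.dropout_prob]
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=list(AIS_COLUMNS) + ["timestamp"])
    out = pd.concat(frames, ignore_index=True)
    out["timestamp_utc"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    return out[list(AIS_COLUMNS) + ["timestamp"]]


def _emit_vessel(stops: pd.DataFrame, coords: dict, step_h: float):
    first = stops["start"].iloc[0].ceil("h")
    last = stops["end"].iloc[-1].floor("h")
    if last < first:
        return None
    times = pd.date_range(first, last, freq=pd.Timedelta(hours=step_h))
    starts = stops["start"].dt.tz_convert("UTC").dt.tz_localize(None).to_numpy()
    ends = stops["end"].dt.tz_convert("UTC").dt.tz_localize(None).to_numpy()
    ports = stops["port"].tolist()
    tvals = times.tz_convert("UTC").tz_localize(None).to_numpy()
    # index of the last stop that started at or before each time
    si = np.searchsorted(starts, tvals, side="right") - 1
    lats = np.empty(len(times))
    lons = np.empty(len(times))
    speeds = np.zeros(len(times))
    courses = np.zeros(len(times))
    statuses = np.empty(len(times), dtype=object)
    in_stop = tvals <= ends[si]
    for k in np.where(in_stop)[0]:
        la, lo = coords[ports[si[k]]]
        lats[k], lons[k] = la, lo
        statuses[k] = "moored"
    # transits: group consecutive times between stop si and si+1
    trans_idx = np.where(~in_stop)[0]
    for i in np.unique(si[trans_idx]):
        sel = trans_idx[si[trans_idx] == i]
        if i + 1 >= len(ports):
            # after the final stop: hold position (floor() should prevent this)
            la, lo = coords[ports[i]]
            lats[sel], lons[sel] = la, lo
            statuses[sel] = "moored"
            continue
        a, b = coords[ports[i]], coords[ports[i + 1]]
        t0 = ends[i]
        t1 = starts[i + 1]
        span_h = (t1 - t0) / np.timedelta64(3600, "s")
        dist_m = haversine_m(a[0], a[1], b[0], b[1])
        if span_h <= 0 or dist_m == 0:
            lats[sel], lons[sel] = a
            statuses[sel] = "moored"
            continue
        f = ((tvals[sel] - t0) / np.timedelta64(3600, "s")) / span_h
        la, lo = gc_interpolate(a[0], a[1], b[0], b[1], f)
        lats[sel], lons[sel] = la, lo
        speeds[sel] = dist_m / NM_TO_M / span_h
        courses[sel] = initial_bearing_deg(a[0], a[1], b[0], b[1])
        statuses[sel] = "underway"
    return times, lats, lons, speeds, courses, statuses


def write_ais_csv(records: pd.DataFrame, path) -> None:
    """Write records in the exact AIS CSV interchange schema."""
    out = records.copy()
    if "timestamp_utc" not in out.columns and "timestamp" in out.columns:
        out["timestamp_utc"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out[list(AIS_COLUMNS)].to_csv(path, index=False)
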
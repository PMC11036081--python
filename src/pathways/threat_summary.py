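"""Summary surfaces: per-class annual metrics, monthly visit profiles and
per-location introduction factors.

The per-class table reports, for each vessel type, annual means with
standard errors across the configured study years: number of active
vessels, cumulative wetted surface area of distinct active hulls,
extended journeys per vessel, port calls per journey, per-event stop
time, distinct countries of origin and trans-national trips per vessel.
The per-location table reports the introduction-likelihood factors for
each anchorage (visits, anchor hours, cumulative WSA of visiting hulls,
in/out links, number of vessel types) and ranks locations by the mean of
per-factor ranks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .journey_network import degree_summary, n_active_stops
from .types import ConfigurationError

TYPE_METRICS = ("vessel_number", "cumulative_wsa", "n_journeys", "stops_per_journey",
                "stop_time_h", "n_origin_countries", "n_transnational_trips")


def proportion_pct(numerator: int, denominator: int) -> int:
    """A share as a whole-number percentage (e.g. 123 of 143 -> 86)."""
    if denominator <= 0:
        raise ConfigurationError("proportion denominator must be positive")
    return round(100.0 * numerator / denominator)


def study_year_windows(start="2017-07-01", n_years=2):
    """Consecutive 365-day study years from a start date (default Jul-Jun)."""
    if n_years <= 0:
        raise ConfigurationError("at least one study year must be configured")
    start = pd.Timestamp(start, tz="UTC")
    edges = [start + pd.Timedelta(days=365 * i) for i in range(n_years + 1)]
    return [(edges[i], edges[i + 1]) for i in range(n_years)]


def _year_index(ts: pd.Series, windows) -> pd.Series:
    out = pd.Series(np.full(len(ts), -1), index=ts.index)
    for i, (a, b) in enumerate(windows):
        out[(ts >= a) & (ts < b)] = i
    return out


def _mean_se(values) -> tuple:
    vals = np.asarray(values, dtype=float)
    mean = float(vals.mean())
    se = 0.0 if len(vals) < 2 else float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return mean, se


def summarise_types(events: pd.DataFrame, journeys, wsa: pd.DataFrame,
                    profiles, year_windows, transnational: pd.DataFrame,
                    node_countries: dict | None = None,
                    rest_threshold_days: float = 30.0) -> pd.DataFrame:
    """Annual per-vessel-class metrics, mean and SE across study years.

    Each metric is computed per study year and then averaged across
    years; SE is the sample standard deviation of the yearly values over
    the square root of the number of years (with two years this is half
    the absolute difference).  Classes with no activity in any year are
    omitted rather than zero-filled.
    """
    if not year_windows:
        raise ConfigurationError("at least one study year must be configured")
    node_countries = node_countries or {}
    type_of = {p.mmsi: p.vessel_type for p in profiles}
    origin_of = {p.mmsi: (p.declared_origin_port or "").strip() for p in profiles}
    wsa_of = dict(zip(wsa["mmsi"], wsa["wsa_m2"])) if len(wsa) else {}

    ev = events[~events["is_origin"]].copy()
    ev["year"] = _year_index(ev["start"], year_windows)
    ev = ev[ev["year"] >= 0]
    ev["vessel_type"] = ev["mmsi"].map(type_of)

    jrows = []
    for j in journeys:
        jrows.append({"mmsi": j.mmsi, "start": j.start,
                      "n_active": n_active_stops(j, events, rest_threshold_days)})
    jdf = pd.DataFrame(jrows, columns=["mmsi", "start", "n_active"])
    if len(jdf):
        jdf["year"] = _year_index(jdf["start"], year_windows)
        jdf = jdf[jdf["year"] >= 0]
        jdf["vessel_type"] = jdf["mmsi"].map(type_of)

    tn = transnational.copy()
    if len(tn):
        tn["vessel_type"] = tn["mmsi"].map(type_of)

    records = []
    n_years = len(year_windows)
    for vtype in sorted(set(type_of.values())):
        yearly = {m: [] for m in TYPE_METRICS}
        active_any = False
        for y in range(n_years):
            ey = ev[(ev["vessel_type"] == vtype) & (ev["year"] == y)]
            active = ey["mmsi"].unique()
            if len(active) == 0:
                for m in TYPE_METRICS:
                    yearly[m].append(0.0)
                continue
            active_any = True
            yearly["vessel_number"].append(float(len(active)))
            yearly["cumulative_wsa"].append(float(sum(wsa_of.get(m, np.nan) for m in active)))
            jy = jdf[(jdf["vessel_type"] == vtype) & (jdf["year"] == y)] if len(jdf) else jdf
            per_vessel = jy.groupby("mmsi").size() if len(jy) else pd.Series(dtype=float)
            yearly["n_journeys"].append(float(per_vessel.mean()) if len(per_vessel) else 0.0)
            yearly["stops_per_journey"].append(float(jy["n_active"].mean()) if len(jy) else 0.0)
            yearly["stop_time_h"].append(float(ey["duration_h"].mean()))
            origins = set()
            first_node = ey.sort_values("start").groupby("mmsi").first()["node_id"]
            for m in active:
                declared = origin_of.get(m, "")
                if declared:
                    origins.add(declared)
                elif m in first_node.index and first_node[m] is not None:
                    origins.add(node_countries.get(first_node[m], "UNKNOWN"))
            yearly["n_origin_countries"].append(float(len(origins)))
            ty = tn[(tn["vessel_type"] == vtype) & (tn["year"] == y)] if len(tn) else tn
            total_cross = float(ty["n_transnational"].sum()) if len(ty) else 0.0
            yearly["n_transnational_trips"].append(total_cross / len(active))
        if not active_any:
            continue
        row = {"vessel_type": vtype}
        for m in TYPE_METRICS:
            mean, se = _mean_se(yearly[m])
            row[f"{m}_mean"] = mean
            row[f"{m}_se"] = se
        records.append(row)
    return pd.DataFrame(records)


def monthly_visits(events: pd.DataFrame, year_windows, profiles) -> pd.DataFrame:
    """Mean visits per calendar month and vessel class across study years.

    A visit is one stop event, counted in the month of its start
    timestamp.  Returns one row per (vessel_type, month 1..12) plus an
    ``ALL`` vessel-type total, with mean and SE over years.
    """
    type_of = {p.mmsi: p.vessel_type for p in profiles}
    classes = sorted(set(type_of.values()))
    ev = events[~events["is_origin"]].copy()
    ev["year"] = _year_index(ev["start"], year_windows)
    ev = ev[ev["year"] >= 0]
    ev["month"] = ev["start"].dt.month
    ev["vessel_type"] = ev["mmsi"].map(type_of)

    rows = []
    n_years = len(year_windows)
    for vtype in classes + ["ALL"]:
        sub = ev if vtype == "ALL" else ev[ev["vessel_type"] == vtype]
        for month in range(1, 13):
            counts = [float(((sub["month"] == month) & (sub["year"] == y)).sum())
                      for y in range(n_years)]
            mean, se = _mean_se(counts)
            rows.append({"vessel_type": vtype, "month": month,
                         "mean_visits": mean, "se": se})
    return pd.DataFrame(rows)


def location_factors(network, events: pd.DataFrame, wsa: pd.DataFrame,
                     profiles, nodes) -> pd.DataFrame:
    """Introduction-likelihood factors per anchorage node, ranked.

    Per node: total visits, total anchor hours, cumulative WSA of
    visiting hulls (a vessel's WSA counts once per visit), distinct
    in/out links, and the number of distinct vessel types.  The overall
    ranking is the mean of the per-factor descending ranks, ties broken
    by visits then label; it is an explicit composite stand-in for a
    qualitative heat map.
    """
    type_of = {p.mmsi: p.vessel_type for p in profiles}
    wsa_of = dict(zip(wsa["mmsi"], wsa["wsa_m2"])) if len(wsa) else {}
    meta = {n.node_id: n for n in nodes}
    deg = degree_summary(network).set_index("node_id")

    ev = events[events["node_id"].notna() & ~events["is_origin"]]
    missing = set(ev["node_id"]) - set(network.nodes)
    if missing:
        raise ConfigurationError(
            f"events reference nodes absent from the network: {sorted(missing)}")

    rows = []
    for nid in network.nodes:
        sub = ev[ev["node_id"] == nid]
        n = meta.get(nid)
        rows.append({
            "node_id": nid,
            "label": n.label if n else nid,
            "country": n.country if n else "UNKNOWN",
            "is_external": bool(n.is_external) if n else False,
            "total_visits": int(len(sub)),
            "total_anchor_hours": float(sub["duration_h"].sum()),
            "cumulative_wsa_m2": float(sub["mmsi"].map(wsa_of).sum()),
            "in_links": int(deg.loc[nid, "in_links"]),
            "out_links": int(deg.loc[nid, "out_links"]),
            "n_vessel_types": int(sub["mmsi"].map(type_of).nunique()),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    factors = ["total_visits", "total_anchor_hours", "cumulative_wsa_m2",
               "in_links", "out_links", "n_vessel_types"]
    ranks = pd.concat([df[f].rank(ascending=False, method="min") for f in factors], axis=1)
    df["composite_rank"] = ranks.mean(axis=1)
    df = df.sort_values(["composite_rank", "total_visits", "label"],
                        ascending=[True, False, True], kind="mergesort")
    return df.reset_index(drop=True)


def entry_points(events: pd.DataFrame, journeys, node_countries: dict,
                 home_code: str = "SG") -> pd.DataFrame:
    """Initial-entry (first port-of-call) stop counts per node.

    For each journey, the first stop inside the home territory counts as
    an initial entry when the immediately preceding stop in the vessel's
    sequence (or its declared origin) lies in a different country.  A
    journey that opens the record with no known previous location is not
    counted.
    """
    ev = events[events["node_id"].notna()].sort_values(["mmsi", "start"], kind="mergesort")
    position = {idx: k for k, idx in enumerate(ev.index)}
    idx_list = list(ev.index)
    counts: dict[str, int] = {}
    for j in journeys:
        for idx in j.event_index:
            if idx not in position:
                continue
            row = ev.loc[idx]
            country = node_countries.get(row["node_id"], "UNKNOWN")
            if country != home_code:
                continue
            k = position[idx]
            if k == 0:
                break
            prev = ev.loc[idx_list[k - 1]]
            if prev["mmsi"] != row["mmsi"]:
                break  # first stop in the record: origin unknown
            prev_country = node_countries.get(prev["node_id"], "UNKNOWN")
            if prev_country not in (home_code, "UNKNOWN"):
                counts[row["node_id"]] = counts.get(row["node_id"], 0) + 1
            break  # only the first home-territory stop of the journey
    rows = [{"node_id": nid, "n_initial_entries": c} for nid, c in counts.items()]
    df = pd.DataFrame(rows, columns=["node_id", "n_initial_entries"])
    return df.sort_values(["n_initial_entries", "node_id"],
                          ascending=[False, True]).reset_index(drop=True)
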
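"""Journey segmentation, the directed voyage network, and degree metrics.

A journey is a consecutive multi-stop voyage with no prolonged rest in
the middle: any single stop longer than the rest threshold (default
30 days, the ">1 month" rule) terminates the journey, and its location
seeds the next one.  The voyage network is a directed graph whose nodes
are anchorages sized by total visits and whose edge weights count unique
vessel trips along each port-to-port route; re-anchoring at the same
node is a visit, not a trip, so there are no self-loops.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .types import JourneySegment

log = logging.getLogger(__name__)


def segment_journeys(events: pd.DataFrame, rest_threshold_days: float = 30.0):
    """Split one vessel's time-ordered stop events into extended journeys.

    A new journey starts at track start and after any stop whose
    duration exceeds ``rest_threshold_days``.  The long stop terminates
    the journey it ends and its node seeds the next journey.  Origin
    events (zero duration) never split.
    """
    events = events.sort_values("start", kind="mergesort")
    journeys: list[JourneySegment] = []
    current: JourneySegment | None = None
    seed = None
    threshold_h = rest_threshold_days * 24.0
    for idx, ev in events.iterrows():
        if current is None:
            current = JourneySegment(mmsi=int(ev["mmsi"]), seed_node_id=seed,
                                     start=ev["start"])
        current.node_ids.append(ev["node_id"])
        current.event_index.append(idx)
        current.end = ev["end"]
        if ev["duration_h"] > threshold_h:
            seed = ev["node_id"]
            journeys.append(current)
            current = None
    if current is not None:
        journeys.append(current)
    return journeys


def segment_all_journeys(events: pd.DataFrame, rest_threshold_days: float = 30.0):
    out = []
    for _, grp in events.groupby("mmsi", sort=True):
        out.extend(segment_journeys(grp, rest_threshold_days))
    return out


def n_active_stops(journey: JourneySegment, events: pd.DataFrame,
                   rest_threshold_days: float = 30.0) -> int:
    """Port calls within a journey: stops no longer than the rest threshold.

    Excludes the terminating rest and any origin pseudo-events.
    """
    sub = events.loc[journey.event_index]
    return int(((sub["duration_h"] <= rest_threshold_days * 24.0)
                & ~sub["is_origin"]).sum())


def build_network(events: pd.DataFrame) -> nx.DiGraph:
    """Directed voyage network from node-assigned event sequences.

    For each vessel, every ordered pair of consecutive *distinct* nodes
    adds one trip to that edge's weight.  Consecutive repeats of the
    same node increment the node's ``total_visits`` but add no
    self-edge.  Origin pseudo-events contribute edges (the inbound link
    from the declared origin) but no visits.
    """
    g = nx.DiGraph()
    ev = events[events["node_id"].notna()]
    for _, grp in ev.groupby("mmsi", sort=True):
        grp = grp.sort_values("start", kind="mergesort")
        prev = None
        for row in grp.itertuples(index=False):
            nid = row.node_id
            if nid not in g:
                g.add_node(nid, total_visits=0)
            if not row.is_origin:
                g.nodes[nid]["total_visits"] += 1
            if prev is not None and prev != nid:
                if g.has_edge(prev, nid):
                    g[prev][nid]["weight"] += 1
                else:
                    g.add_edge(prev, nid, weight=1)
            prev = nid
    return g


def degree_summary(g: nx.DiGraph) -> pd.DataFrame:
    """Per-node distinct-neighbour link counts and total visits.

    ``in_links``/``out_links`` count distinct adjacent nodes, not edge
    weights.  Rows are ordered busiest-first by ``total_visits``, ties
    broken by node id so the report is deterministic.
    """
    rows = [{
        "node_id": n,
        "in_links": g.in_degree(n),
        "out_links": g.out_degree(n),
        "total_visits": g.nodes[n].get("total_visits", 0),
    } for n in g.nodes]
    df = pd.DataFrame(rows, columns=["node_id", "in_links", "out_links", "total_visits"])
    return df.sort_values(["total_visits", "node_id"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


def transnational_trips(events: pd.DataFrame, node_countries: dict,
                        year_windows) -> pd.DataFrame:
    """Count trans-national trips per vessel-year.

    A trans-national trip is a consecutive stop pair whose country codes
    differ; pairs touching an UNKNOWN country are skipped (logged).  A
    crossing is attributed to the study year of the arriving stop.
    Returns a DataFrame ``(mmsi, year, n_transnational)``.
    """
    counts: dict[tuple, int] = {}
    skipped = 0
    ev = events[events["node_id"].notna()]
    for mmsi, grp in ev.groupby("mmsi", sort=True):
        grp = grp.sort_values("start", kind="mergesort")
        prev_country = None
        for row in grp.itertuples(index=False):
            country = node_countries.get(row.node_id, "UNKNOWN")
            if prev_country is not None:
                if "UNKNOWN" in (prev_country, country):
                    skipped += 1
                elif prev_country != country:
                    year = _year_of(row.start, year_windows)
                    if year is not None:
                        counts[(mmsi, year)] = counts.get((mmsi, year), 0) + 1
            prev_country = country
    if skipped:
        log.info("transnational_trips: skipped %d pair(s) with UNKNOWN country", skipped)
    rows = [{"mmsi": m, "year": y, "n_transnational": c} for (m, y), c in counts.items()]
    return pd.DataFrame(rows, columns=["mmsi", "year", "n_transnational"])


def _year_of(ts, year_windows):
    for i, (start, end) in enumerate(year_windows):
        if start <= ts < end:
            return i
    return None


def export_edge_list(g: nx.DiGraph, path) -> None:
    rows = [{"from_id": u, "to_id": v, "weight": d["weight"]}
            for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["from_id", "to_id", "weight"]).to_csv(path, index=False)


def export_graphml(g: nx.DiGraph, nodes, path) -> None:
    h = g.copy()
    meta = {n.node_id: n for n in nodes}
    for nid in h.nodes:
        n = meta.get(nid)
        if n is not None:
            h.nodes[nid].update(label=n.label, country=n.country,
                                is_external=bool(n.is_external),
                                lat=n.lat, lon=n.lon)
    deg = degree_summary(g).set_index("node_id")
    for nid in h.nodes:
        h.nodes[nid]["in_links"] = int(deg.loc[nid, "in_links"])
        h.nodes[nid]["out_links"] = int(deg.loc[nid, "out_links"])
    nx.write_graphml(h, path)
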
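"""Stop events, anchorage-node clustering, origin ports and country assignment.

Maximal runs of stationary hours become stop events.  Events within the
12 nm coastal band are clustered into anchorage nodes by single linkage:
two stops join when their 5 km buffers overlap (centre distance <= 10 km),
and clusters are the connected components of that graph.  Buffers are
defined under an azimuthal equidistant projection, under which distances
from the projection centre are exactly great-circle distances, so the
KD-tree great-circle linkage used here is the same rule.

Declared ports of origin outside the area of interest add external nodes
and zero-duration origin events at the head of a vessel's sequence; every
node is then assigned a country/territory code.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

from .geo import aeqd_project, chord_m, ecef_unit, haversine_m
from .types import AnchorageNode, StudyArea

log = logging.getLogger(__name__)

EVENT_COLUMNS = ["mmsi", "start", "end", "duration_h", "lat", "lon",
                 "n_points", "is_origin"]


def build_stop_events(track: pd.DataFrame) -> pd.DataFrame:
    """Contiguous stationary runs of one vessel's flagged track.

    Each maximal run of consecutive stationary points becomes one event
    whose duration is the span between its first and last timestamps; a
    single stationary point counts one hour (one sampling interval,
    which is the resolution floor).  The event position is the mean of
    the member positions.
    """
    if track.empty or not track["stationary"].any():
        return pd.DataFrame(columns=EVENT_COLUMNS)
    flags = track["stationary"].to_numpy()
    run_id = np.cumsum(np.concatenate([[0], np.abs(np.diff(flags.astype(int)))]))
    rows = []
    for rid in np.unique(run_id[flags]):
        member = track[(run_id == rid) & flags]
        start = member["timestamp"].iloc[0]
        end = member["timestamp"].iloc[-1]
        span_h = (end - start).total_seconds() / 3600.0
        rows.append({
            "mmsi": int(member["mmsi"].iloc[0]),
            "start": start, "end": end,
            "duration_h": max(span_h, 1.0),
            "lat": float(member["lat"].mean()),
            "lon": float(member["lon"].mean()),
            "n_points": int(len(member)),
            "is_origin": False,
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def build_all_stop_events(tracks: pd.DataFrame) -> pd.DataFrame:
    pieces = [build_stop_events(grp) for _, grp in tracks.groupby("mmsi", sort=True)]
    pieces = [p for p in pieces if not p.empty]
    if not pieces:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(pieces, ignore_index=True)


def distance_to_coast_m(lats, lons, coastline) -> np.ndarray:
    """Great-circle distance from each point to the nearest coastline geometry.

    Each point is evaluated in a local azimuthal equidistant projection
    centred on itself, where planar distance to the (projected) coastline
    equals great-circle distance.  Points on land are at distance 0.
    """
    geoms = list(coastline) if not isinstance(coastline, shapely.Geometry) else [coastline]
    out = np.empty(len(lats))
    boundaries = [(g, np.asarray(g.exterior.coords)) for g in geoms]
    for i, (la, lo) in enumerate(zip(lats, lons)):
        best = np.inf
        for geom, coords in boundaries:
            if geom.contains(shapely.Point(lo, la)):
                best = 0.0
                break
            x, y = aeqd_project(la, lo, coords[:, 1], coords[:, 0])
            ring = shapely.LinearRing(np.column_stack([x, y]))
            best = min(best, ring.distance(shapely.Point(0.0, 0.0)))
        out[i] = best
    return out


def _connected_components(n: int, pairs) -> np.ndarray:
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    return np.array([find(i) for i in range(n)])


def cluster_nodes(events: pd.DataFrame, coastline, study: StudyArea,
                  gazetteer: pd.DataFrame | None = None):
    """Cluster coastal stop events into anchorage nodes.

    Only stops within the coastal band (12 nm of land) form nodes; the
    rest are logged and left unassigned.  Single-linkage: stops whose
    5 km buffers overlap (distance <= ``cluster_link_km``) join, and the
    node is a connected component.  The node centroid is the mean of the
    member positions; its label is the nearest gazetteer port if within
    the buffer radius, else a synthetic id.  Node ids are assigned in
    (lat, lon) centroid order, so the clustering is invariant to input
    permutation.

    Returns ``(nodes, events)`` where ``events`` has a ``node_id``
    column (None for offshore stops).
    """
    events = events.reset_index(drop=True).copy()
    events["node_id"] = None
    if events.empty:
        return [], events

    lats = events["lat"].to_numpy(dtype=float)
    lons = events["lon"].to_numpy(dtype=float)
    d_coast = distance_to_coast_m(lats, lons, coastline)
    coastal = d_coast <= study.coastal_band_m
    n_off = int((~coastal).sum())
    if n_off:
        log.info("cluster_nodes: %d stop(s) beyond %.0f nm of land excluded",
                 n_off, study.coastal_band_nm)
    idx = np.where(coastal)[0]
    if idx.size == 0:
        return [], events

    pts = ecef_unit(lats[idx], lons[idx]) * 6_371_000.0
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=chord_m(study.cluster_link_km * 1000.0), output_type="ndarray")
    comp = _connected_components(idx.size, pairs)

    # order components by centroid for deterministic ids
    cents = []
    for cid in np.unique(comp):
        m = comp == cid
        cents.append((float(lats[idx][m].mean()), float(lons[idx][m].mean()), cid))
    cents.sort(key=lambda t: (t[0], t[1]))

    nodes = []
    node_of_comp = {}
    for k, (cla, clo, cid) in enumerate(cents):
        node_id = f"N{k + 1:03d}"
        node_of_comp[cid] = node_id
        label = node_id
        if gazetteer is not None and len(gazetteer):
            d = haversine_m(cla, clo, gazetteer["lat"].to_numpy(), gazetteer["lon"].to_numpy())
            order = np.lexsort((gazetteer["name"].to_numpy(), d))  # ties alphabetical
            if d[order[0]] <= study.node_buffer_km * 1000.0:
                label = str(gazetteer["name"].iloc[order[0]])
        nodes.append(AnchorageNode(node_id=node_id, lat=cla, lon=clo, label=label,
                                   n_member_stops=int((comp == cid).sum())))
    events.loc[idx, "node_id"] = [node_of_comp[c] for c in comp]
    return nodes, events


def attach_origin_ports(events: pd.DataFrame, profiles, world_ports: pd.DataFrame,
                        nodes, study: StudyArea):
    """Prepend declared-origin events for vessels arriving from outside the AOI.

    When a vessel declares a port of origin that resolves in the
    world-port lookup, lies outside the area of interest, and differs
    from its first observed node, an external node is created (or
    reused) and a zero-duration origin event is prepended to the
    vessel's sequence.  Unresolvable names are logged and skipped.
    Origin events carry ``is_origin=True``: they add network links but
    do not count as visits or stop time.
    """
    nodes = list(nodes)
    lookup = {str(r.name): r for r in world_ports.itertuples(index=False)} \
        if world_ports is not None else {}
    new_rows = []
    for p in profiles:
        origin = (p.declared_origin_port or "").strip()
        if not origin:
            continue
        port = lookup.get(origin)
        if port is None:
            log.warning("attach_origin_ports: unresolvable port of origin %r (mmsi %s)",
                        origin, p.mmsi)
            continue
        if study.in_bbox(float(port.lat), float(port.lon)):
            continue  # origin inside the AOI: already captured by AIS analysis
        vessel_events = events[(events["mmsi"] == p.mmsi) & events["node_id"].notna()]
        if vessel_events.empty:
            continue
        first = vessel_events.sort_values("start").iloc[0]
        first_label = next((n.label for n in nodes if n.node_id == first["node_id"]), None)
        if first_label == origin:
            continue
        ext_id = f"EXT_{origin.replace(' ', '_')}"
        if ext_id not in {n.node_id for n in nodes}:
            nodes.append(AnchorageNode(
                node_id=ext_id, lat=float(port.lat), lon=float(port.lon),
                label=origin, country=str(port.country), is_external=True))
        new_rows.append({
            "mmsi": p.mmsi, "start": first["start"], "end": first["start"],
            "duration_h": 0.0, "lat": float(port.lat), "lon": float(port.lon),
            "n_points": 0, "is_origin": True, "node_id": ext_id,
        })
    if new_rows:
        events = pd.concat([events, pd.DataFrame(new_rows)], ignore_index=True)
        events = events.sort_values(["mmsi", "start", "is_origin"],
                                    ascending=[True, True, False],
                                    kind="mergesort").reset_index(drop=True)
    return nodes, events


def assign_country(nodes, territories, port_countries: dict | None = None):
    """Assign exactly one country/territory code to every node.

    ``territories`` is a list of ``(code, shapely Polygon)`` in lon/lat
    order.  External nodes keep the code from the port table.  Internal
    nodes take the code of the polygon containing their centroid, else a
    gazetteer name match, else ``UNKNOWN`` (logged).
    """
    port_countries = port_countries or {}
    for n in nodes:
        if n.is_external and n.country != "UNKNOWN":
            continue
        code = None
        for terr_code, poly in territories:
            if shapely.contains_xy(poly, n.lon, n.lat):
                code = terr_code
                break
        if code is None:
            code = port_countries.get(n.label)
        if code is None:
            code = "UNKNOWN"
            log.warning("assign_country: node %s (%s) matched no territory", n.node_id, n.label)
        n.country = code
    return nodes
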
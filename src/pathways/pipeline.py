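"""End-to-end orchestration: records -> tracks -> stops -> nodes -> network -> summaries."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from . import ais_ingest, journey_network, node_builder, threat_summary, wsa
from .types import StudyArea


@dataclass
class PipelineResult:
    tracks: pd.DataFrame
    events: pd.DataFrame
    nodes: list
    network: object
    journeys: list
    wsa: pd.DataFrame
    type_summary: pd.DataFrame
    monthly: pd.DataFrame
    location_factors: pd.DataFrame
    entry_points: pd.DataFrame
    counters: dict = field(default_factory=dict)

    @property
    def node_countries(self) -> dict:
        return {n.node_id: n.country for n in self.nodes}


def run_pipeline(records: pd.DataFrame, profiles, geography,
                 study: StudyArea | None = None, year_windows=None,
                 wsa_table: dict | None = None,
                 attach_origins: bool = True,
                 rest_threshold_days: float | None = None) -> PipelineResult:
    """Run the full introduction-pathway analysis on an AIS record stream.

    ``geography`` provides coastline and territory polygons, the
    maritime-zone polygon, the port gazetteer and the world-port lookup
    (see ``synthetic_fleet.Geography``).  ``year_windows`` defaults to
    two July-June study years.
    """
    study = study or StudyArea()
    if study.maritime_zone is None:
        study.maritime_zone = geography.zone
    year_windows = year_windows or threat_summary.study_year_windows()
    rest_days = rest_threshold_days if rest_threshold_days is not None \
        else study.rest_threshold_days

    tracks = ais_ingest.prepare_tracks(records, study)
    events = node_builder.build_all_stop_events(tracks)
    nodes, events = node_builder.cluster_nodes(events, geography.coastline, study,
                                               geography.gazetteer)
    if attach_origins:
        nodes, events = node_builder.attach_origin_ports(
            events, profiles, geography.world_ports, nodes, study)
    port_countries = dict(zip(geography.gazetteer["name"], geography.gazetteer["country"]))
    nodes = node_builder.assign_country(nodes, geography.territories, port_countries)
    node_countries = {n.node_id: n.country for n in nodes}

    active = set(events["mmsi"].unique())
    active_profiles = [p for p in profiles if p.mmsi in active]
    wsa_df = wsa.fleet_wsa(active_profiles, wsa_table)

    journeys = journey_network.segment_all_journeys(events, rest_days)
    network = journey_network.build_network(events)
    transnational = journey_network.transnational_trips(events, node_countries, year_windows)

    type_summary = threat_summary.summarise_types(
        events, journeys, wsa_df, active_profiles, year_windows, transnational,
        node_countries, rest_days)
    monthly = threat_summary.monthly_visits(events, year_windows, active_profiles)
    factors = threat_summary.location_factors(network, events, wsa_df,
                                              active_profiles, nodes)
    entries = threat_summary.entry_points(events, journeys, node_countries,
                                          geography.home_code)
    counters = {
        "n_records": int(len(records)),
        "n_vessels_in_zone": int(tracks["mmsi"].nunique()) if len(tracks) else 0,
        "n_stop_events": int((~events["is_origin"]).sum()) if len(events) else 0,
        "n_nodes": len(nodes),
    }
    return PipelineResult(tracks=tracks, events=events, nodes=nodes, network=network,
                          journeys=journeys, wsa=wsa_df, type_summary=type_summary,
                          monthly=monthly, location_factors=factors,
                          entry_points=entries, counters=counters)


def nodes_to_geojson(nodes, deg: pd.DataFrame | None = None) -> dict:
    """GeoJSON FeatureCollection of anchorage nodes (lon/lat points)."""
    deg_map = deg.set_index("node_id").to_dict("index") if deg is not None else {}
    feats = []
    for n in nodes:
        props = {"node_id": n.node_id, "label": n.label, "country": n.country,
                 "is_external": bool(n.is_external)}
        props.update({k: int(v) for k, v in deg_map.get(n.node_id, {}).items()})
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [n.lon, n.lat]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": feats}


def write_outputs(result: PipelineResult, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.type_summary.to_csv(out / "type_summary.csv", index=False)
    result.monthly.to_csv(out / "monthly_profile.csv", index=False)
    result.location_factors.to_csv(out / "location_factors.csv", index=False)
    result.entry_points.to_csv(out / "entry_points.csv", index=False)
    result.wsa.to_csv(out / "wsa.csv", index=False)
    journey_network.export_edge_list(result.network, out / "edges.csv")
    journey_network.export_graphml(result.network, result.nodes, out / "network.graphml")
    with open(out / "nodes.geojson", "w") as fh:
        json.dump(nodes_to_geojson(
            result.nodes, journey_network.degree_summary(result.network)), fh, indent=1)
    with open(out / "run.log", "w") as fh:
        for k, v in result.counters.items():
            fh.write(f"{k}: {v}\n")
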
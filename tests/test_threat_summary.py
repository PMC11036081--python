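"""Summary tables: yearly means and SEs, monthly profiles, location factors."""

import numpy as np
import pandas as pd
import pytest

from pathways import journey_network as jn
from pathways import threat_summary as ts
from pathways.types import AnchorageNode, ConfigurationError, VesselProfile

WINDOWS = ts.study_year_windows("2017-07-01", 2)


def _event(mmsi, node, start, dur_h):
    start = pd.Timestamp(start, tz="UTC")
    return {"mmsi": mmsi, "start": start, "end": start + pd.Timedelta(hours=dur_h),
            "duration_h": float(dur_h), "lat": -54.0, "lon": -36.0,
            "n_points": int(dur_h), "is_origin": False, "node_id": node}


def _profiles(mmsis, vt="Fishing"):
    return [VesselProfile(mmsi=m, vessel_type=vt, dwt_t=1000.0) for m in mmsis]


def test_proportion_pct_matches_worked_share():
    assert ts.proportion_pct(123, 143) == 86


def test_identical_years_give_zero_se():
    events = pd.DataFrame([_event(1, "A", "2017-10-01", 5),
                           _event(1, "A", "2018-10-01", 5)])
    journeys = jn.segment_all_journeys(events)
    wsa = pd.DataFrame({"mmsi": [1], "wsa_m2": [100.0]})
    out = ts.summarise_types(events, journeys, wsa, _profiles([1]), WINDOWS,
                             pd.DataFrame(columns=["mmsi", "year", "n_transnational"]))
    row = out.iloc[0]
    assert row["vessel_number_mean"] == 1.0 and row["vessel_number_se"] == 0.0
    assert row["cumulative_wsa_mean"] == 100.0


def test_se_is_half_absolute_difference_over_two_years():
    # 4 vessels active in year one, 5 in year two -> mean 4.5, SE 0.5
    events = [
        *[_event(m, "A", "2017-10-01", 5) for m in (1, 2, 3, 4)],
        *[_event(m, "A", "2018-10-01", 5) for m in (1, 2, 3, 4, 5)],
    ]
    events = pd.DataFrame(events)
    journeys = jn.segment_all_journeys(events)
    wsa = pd.DataFrame({"mmsi": range(1, 6), "wsa_m2": 10.0})
    out = ts.summarise_types(events, journeys, wsa, _profiles(range(1, 6)), WINDOWS,
                             pd.DataFrame(columns=["mmsi", "year", "n_transnational"]))
    row = out.iloc[0]
    assert row["vessel_number_mean"] == 4.5
    assert row["vessel_number_se"] == 0.5


def test_class_absent_both_years_omitted():
    events = pd.DataFrame([_event(1, "A", "2017-10-01", 5)])
    journeys = jn.segment_all_journeys(events)
    wsa = pd.DataFrame({"mmsi": [1, 2], "wsa_m2": [10.0, 20.0]})
    profiles = _profiles([1]) + _profiles([2], vt="Tanker")  # tanker has no events
    out = ts.summarise_types(events, journeys, wsa, profiles, WINDOWS,
                             pd.DataFrame(columns=["mmsi", "year", "n_transnational"]))
    assert out["vessel_type"].tolist() == ["Fishing"]


def test_zero_year_windows_rejected():
    with pytest.raises(ConfigurationError):
        ts.study_year_windows("2017-07-01", 0)


def test_monthly_visit_counted_in_start_month():
    events = pd.DataFrame([
        _event(1, "A", "2017-11-15", 5),
        _event(1, "A", "2017-11-28", 5 * 24),   # spans into December: November only
    ])
    prof = _profiles([1])
    out = ts.monthly_visits(events, WINDOWS, prof)
    fish = out[out["vessel_type"] == "Fishing"].set_index("month")
    assert fish.loc[11, "mean_visits"] == 1.0  # two visits over two years
    assert fish.loc[12, "mean_visits"] == 0.0


def test_monthly_profile_conserves_event_totals(result, fleet):
    profiles, _ = fleet
    total_events = result.counters["n_stop_events"]
    alls = result.monthly[result.monthly["vessel_type"] == "ALL"]
    assert alls["mean_visits"].sum() * 2 == pytest.approx(total_events)


def test_empty_events_give_all_zero_profile():
    events = pd.DataFrame(columns=["mmsi", "start", "end", "duration_h",
                                   "is_origin", "node_id"]).astype({"is_origin": bool})
    events["start"] = pd.to_datetime(events["start"], utc=True)
    out = ts.monthly_visits(events, WINDOWS, _profiles([1]))
    assert (out["mean_visits"] == 0).all()


def test_location_factor_aggregation_by_hand():
    events = pd.DataFrame([
        _event(1, "A", "2017-10-01", 10),
        _event(2, "A", "2017-10-02", 10),
        _event(3, "A", "2017-10-03", 10),
    ])
    profiles = _profiles([1, 2]) + _profiles([3], vt="Tanker")
    wsa = pd.DataFrame({"mmsi": [1, 2, 3], "wsa_m2": [100.0, 100.0, 200.0]})
    g = jn.build_network(events)
    nodes = [AnchorageNode("A", -54.0, -36.0, "A", country="SG")]
    out = ts.location_factors(g, events, wsa, profiles, nodes).iloc[0]
    assert out["total_visits"] == 3
    assert out["total_anchor_hours"] == 30.0
    assert out["cumulative_wsa_m2"] == 400.0
    assert out["n_vessel_types"] == 2


def test_location_factors_reject_inconsistent_node_universe():
    events = pd.DataFrame([_event(1, "GHOST", "2017-10-01", 10)])
    g = jn.build_network(events.iloc[0:0])
    with pytest.raises(ConfigurationError):
        ts.location_factors(g, events, pd.DataFrame({"mmsi": [], "wsa_m2": []}),
                            _profiles([1]), [])


def test_external_node_has_zero_hours_but_links(result_with_origins):
    lf = result_with_origins.location_factors
    ext = lf[lf["is_external"]]
    if len(ext):
        assert (ext["total_anchor_hours"] == 0).all()
        assert (ext["out_links"] >= 1).all()


def test_entry_points_rule_by_hand():
    countries = {"F": "FK", "X": "SG", "Y": "SG"}
    events = pd.DataFrame([
        _event(1, "F", "2017-10-01", 5),
        _event(1, "X", "2017-10-05", 5),
        _event(1, "Y", "2017-10-08", 5),
    ])
    journeys = jn.segment_all_journeys(events)
    out = ts.entry_points(events, journeys, countries, home_code="SG")
    assert out.set_index("node_id")["n_initial_entries"].to_dict() == {"X": 1}


def test_entry_points_zero_for_domestic_journeys():
    countries = {"X": "SG", "Y": "SG"}
    events = pd.DataFrame([_event(1, "X", "2017-10-01", 5),
                           _event(1, "Y", "2017-10-05", 5)])
    journeys = jn.segment_all_journeys(events)
    assert ts.entry_points(events, journeys, countries).empty


def test_declared_origin_counts_as_entry_source():
    countries = {"O": "AR", "X": "SG"}
    start = pd.Timestamp("2017-10-01", tz="UTC")
    events = pd.DataFrame([
        {"mmsi": 1, "start": start, "end": start, "duration_h": 0.0, "lat": -54.8,
         "lon": -68.3, "n_points": 0, "is_origin": True, "node_id": "O"},
        _event(1, "X", "2017-10-02", 5),
    ])
    journeys = jn.segment_all_journeys(events)
    out = ts.entry_points(events, journeys, countries)
    assert out.set_index("node_id")["n_initial_entries"].to_dict() == {"X": 1}


def test_column_sums_reconcile_with_event_totals(result):
    lf = result.location_factors
    assert lf["total_visits"].sum() == result.counters["n_stop_events"]
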
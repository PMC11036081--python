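"""Reader validation, hourly resampling and the two-condition stationarity rule."""

import io

import numpy as np
import pandas as pd
import pytest
import shapely

from pathways import ais_ingest as ai
from pathways.types import SchemaError, ConfigurationError, StudyArea, AIS_COLUMNS

HEADER = ",".join(AIS_COLUMNS)


def _read(text):
    return ai.read_ais_csv(io.StringIO(text))


def test_empty_file_with_header_gives_empty_frame():
    df = _read(HEADER + "\n")
    assert df.empty
    assert df.attrs["n_dropped"] == 0


def test_out_of_range_latitude_row_is_dropped_and_counted():
    rows = [
        "1,,V,2018-01-01T00:00:00Z,91.0,-36.0,0,moored,0.0,",
        "1,,V,2018-01-01T01:00:00Z,-54.0,-36.0,0,moored,0.0,",
    ]
    df = _read(HEADER + "\n" + "\n".join(rows) + "\n")
    assert len(df) == 1
    assert df.attrs["n_dropped"] == 1


def test_missing_mandatory_column_names_it():
    cols = [c for c in AIS_COLUMNS if c != "lat"]
    with pytest.raises(SchemaError, match="lat"):
        _read(",".join(cols) + "\n")


def test_records_sorted_by_vessel_then_time():
    rows = [
        "2,,B,2018-01-01T05:00:00Z,-54.0,-36.0,0,underway,5.0,",
        "1,,A,2018-01-01T03:00:00Z,-54.0,-36.0,0,underway,5.0,",
        "1,,A,2018-01-01T01:00:00Z,-54.0,-36.0,0,underway,5.0,",
    ]
    df = _read(HEADER + "\n" + "\n".join(rows) + "\n")
    assert df["mmsi"].tolist() == [1, 1, 2]
    assert df["timestamp"].is_monotonic_increasing or df["mmsi"].nunique() > 1


def _records(times, lats, lons, speeds, mmsi=1):
    return pd.DataFrame({
        "mmsi": mmsi,
        "timestamp": pd.to_datetime(times, utc=True),
        "lat": lats, "lon": lons, "speed_kn": speeds,
    })


def test_resample_keeps_one_point_per_hour():
    df = _records([f"2018-01-01T00:{m:02d}:00Z" for m in (0, 10, 30, 50)],
                  [-54.0] * 4, [-36.0] * 4, [0.1] * 4)
    track = ai.resample_hourly(df)
    assert len(track) == 1
    assert np.isnan(track["displacement_m"].iloc[0])


def test_resample_zero_displacement_for_static_vessel():
    df = _records(["2018-01-01T00:00:00Z", "2018-01-01T01:00:00Z"],
                  [-54.0, -54.0], [-36.0, -36.0], [0.1, 0.1])
    track = ai.resample_hourly(df)
    assert track["displacement_m"].iloc[1] == 0.0
    assert track["gap_h"].iloc[1] == 1.0


def test_resample_is_idempotent(records):
    one = records[records["mmsi"] == records["mmsi"].iloc[0]]
    t1 = ai.resample_hourly(one)
    t2 = ai.resample_hourly(t1.rename(columns={"reported_speed": "speed_kn"}))
    pd.testing.assert_frame_equal(t1, t2)


def test_resample_preserves_gaps_without_interpolation():
    df = _records(["2018-01-01T00:00:00Z", "2018-01-01T05:00:00Z"],
                  [-54.0, -54.2], [-36.0, -36.0], [5.0, 5.0])
    track = ai.resample_hourly(df)
    assert len(track) == 2
    assert track["gap_h"].iloc[1] == 5.0


@pytest.mark.parametrize("disp,speed,expected", [
    (300.0, 0.1, True),    # both conditions met
    (400.0, 0.1, False),   # displacement not strictly under 400 m
    (200.0, 1.5, False),   # reported speed too high
    (399.9, 0.99, True),
    (50.0, 1.0, False),    # speed not strictly under 1 kn
])
def test_stationarity_requires_both_conditions(disp, speed, expected):
    track = pd.DataFrame({
        "mmsi": [1, 1],
        "timestamp": pd.to_datetime(["2018-01-01T00:00:00Z", "2018-01-01T01:00:00Z"],
                                    utc=True),
        "lat": [-54.0, -54.0], "lon": [-36.0, -36.0],
        "reported_speed": [5.0, speed],
        "displacement_m": [np.nan, disp],
        "gap_h": [np.nan, 1.0],
    })
    out = ai.classify_stationary(track)
    assert bool(out["stationary"].iloc[1]) is expected


def test_first_point_classified_by_speed_alone():
    track = pd.DataFrame({
        "mmsi": [1], "timestamp": pd.to_datetime(["2018-01-01T00:00:00Z"], utc=True),
        "lat": [-54.0], "lon": [-36.0], "reported_speed": [0.3],
        "displacement_m": [np.nan], "gap_h": [np.nan],
    })
    assert bool(ai.classify_stationary(track)["stationary"].iloc[0]) is True


def test_multi_hour_gap_uses_speed_alone_and_is_flagged():
    track = pd.DataFrame({
        "mmsi": [1, 1],
        "timestamp": pd.to_datetime(["2018-01-01T00:00:00Z", "2018-01-01T04:00:00Z"],
                                    utc=True),
        "lat": [-54.0, -54.5], "lon": [-36.0, -36.0],
        "reported_speed": [0.1, 0.1],
        "displacement_m": [np.nan, 55_000.0],
        "gap_h": [np.nan, 4.0],
    })
    out = ai.classify_stationary(track)
    assert bool(out["stationary"].iloc[1]) is True
    assert bool(out["is_gap"].iloc[1]) is True


def _track(mmsi, lat, lon):
    return pd.DataFrame({
        "mmsi": [mmsi], "timestamp": pd.to_datetime(["2018-01-01T00:00:00Z"], utc=True),
        "lat": [lat], "lon": [lon], "reported_speed": [0.0],
        "displacement_m": [np.nan], "gap_h": [np.nan],
    })


def test_zone_filter_retains_only_vessels_that_entered():
    zone = shapely.box(-38.0, -55.0, -34.0, -53.0)
    study = StudyArea(maritime_zone=zone)
    tracks = pd.concat([_track(1, -54.0, -36.0), _track(2, -50.0, -60.0)],
                       ignore_index=True)
    assert ai.filter_zone_vessels(tracks, study) == {1}
    assert ai.filter_zone_vessels(tracks.iloc[0:0], study) == set()


def test_zone_filter_keeps_full_track_of_entering_vessel(records, fleet, geography):
    profiles, _ = fleet
    study = StudyArea(maritime_zone=geography.zone)
    tracks = ai.prepare_tracks(records, study)
    # every test vessel calls at South Georgia, so all are retained in full
    assert tracks["mmsi"].nunique() == len(profiles)
    one = tracks[tracks["mmsi"] == profiles[0].mmsi]
    raw = ai.resample_hourly(records[records["mmsi"] == profiles[0].mmsi])
    assert len(one) == len(raw)


def test_zone_filter_monotone_in_zone_size():
    study_small = StudyArea(maritime_zone=shapely.box(-37.0, -54.5, -36.5, -54.2))
    study_big = StudyArea(maritime_zone=shapely.box(-60.0, -56.0, -30.0, -50.0))
    tracks = pd.concat([_track(1, -54.3, -36.6), _track(2, -51.7, -57.9),
                        _track(3, -54.28, -36.9)], ignore_index=True)
    small = ai.filter_zone_vessels(tracks, study_small)
    big = ai.filter_zone_vessels(tracks, study_big)
    assert small <= big


def test_degenerate_zone_polygon_rejected():
    with pytest.raises(ConfigurationError):
        ai.filter_zone_vessels(_track(1, -54.0, -36.0),
                               StudyArea(maritime_zone=shapely.Polygon()))


def test_transit_displacements_match_leg_speed(records, fleet, fleet_config):
    # per-hour displacement on a transit leg equals leg length / duration
    _, truth = fleet
    legs = truth.transits
    leg = legs[(legs["arr"] - legs["dep"]) > pd.Timedelta(hours=5)].iloc[0]
    one = records[records["mmsi"] == leg["mmsi"]]
    track = ai.resample_hourly(one)
    mid = track[(track["timestamp"] > leg["dep"] + pd.Timedelta(hours=1))
                & (track["timestamp"] < leg["arr"])]
    la1, lo1 = fleet_config.port_location(leg["from_port"])
    la2, lo2 = fleet_config.port_location(leg["to_port"])
    from pathways.geo import haversine_m
    leg_m = haversine_m(la1, lo1, la2, lo2)
    hours = (leg["arr"] - leg["dep"]).total_seconds() / 3600
    expected = leg_m / hours
    assert np.allclose(mid["displacement_m"], expected, rtol=0.01)
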
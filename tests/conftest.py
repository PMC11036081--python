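"""Shared fixtures: a reduced synthetic fleet spanning all nine classes.

Everything is generated programmatically; the session-scoped fixtures
keep the fleet small (25 vessels, 2 study years) so the whole suite runs
quickly while still exercising every class, seasonality window and
routing pattern.
"""

from __future__ import annotations

import dataclasses

import pytest

from pathways import synthetic_fleet as sf
from pathways.pipeline import run_pipeline

TEST_COUNTS = {"Bulk": 1, "Cargo": 2, "Fishing": 5, "Offshore": 3, "Passenger": 5,
               "Pilot": 1, "Pleasure": 3, "Tanker": 2, "Tender": 3}


@pytest.fixture(scope="session")
def fleet_config() -> sf.FleetConfig:
    classes = {k: dataclasses.replace(v, n_vessels=TEST_COUNTS[k])
               for k, v in sf.DEFAULT_CLASSES.items()}
    return sf.FleetConfig(seed=0, classes=classes)


@pytest.fixture(scope="session")
def fleet(fleet_config):
    profiles, truth = sf.generate_fleet(fleet_config)
    return profiles, truth


@pytest.fixture(scope="session")
def records(fleet, fleet_config):
    profiles, truth = fleet
    return sf.simulate_tracks(profiles, truth, fleet_config)


@pytest.fixture(scope="session")
def geography():
    return sf.synthetic_geography()


@pytest.fixture(scope="session")
def result(records, fleet, geography):
    """Pipeline run without declared-origin augmentation: pure AIS recovery."""
    profiles, _ = fleet
    return run_pipeline(records, profiles, geography, attach_origins=False)


@pytest.fixture(scope="session")
def result_with_origins(records, fleet, geography):
    profiles, _ = fleet
    return run_pipeline(records, profiles, geography, attach_origins=True)
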
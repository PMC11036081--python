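# pathways

Marine-invasion introduction-pathway analysis from vessel-tracking data.

Biofouling on ship hulls is a major vector for marine non-native species,
and remote, high-endemism archipelagos such as the sub-Antarctic islands
are increasingly exposed as vessel traffic grows.  `pathways` turns raw
AIS-style position reports into the quantities a biosecurity manager
needs: where vessels stop and for how long, how anchorages are linked by
voyages, how much submerged hull area moves between territories, and
which vessel classes and locations concentrate introduction likelihood.

Because real AIS feeds are confidential, the package ships a synthetic
fleet simulator with a complete ground-truth event log, so every stage
of the pipeline is verifiable by exact recovery of known stops, journeys
and routes.

## The analysis

Given hourly position reports for each vessel (MMSI-keyed), the pipeline:

1. **Cleans and classifies tracks** — resamples to at most one point per
   clock hour, computes sequential great-circle (haversine, R = 6371 km)
   displacements, keeps only vessels that entered the 200 nm maritime
   zone, and flags a vessel *stationary* in an hour when it moved
   < 400 m **and** reported < 1 kn (400 m/h ≈ 0.2 kn, the underway
   threshold).
2. **Builds stop events and anchorage nodes** — maximal stationary runs
   become stop events; events within 12 nm of land are clustered by
   single linkage (5 km buffers, i.e. centres ≤ 10 km join) into nodes,
   labelled from a port gazetteer and assigned a country/territory code.
   Declared ports of origin outside the area of interest add external
   nodes.
3. **Segments journeys and builds the voyage network** — an extended
   journey is a multi-stop voyage bounded by rests > 30 days; the
   directed network weights each port-to-port edge by the number of
   unique vessel trips, and node size is total visits.
4. **Estimates hull Wetted Surface Area (WSA)** — power law
   WSA = a·DWT^b per class with breadth/length fallbacks, the
   Denny–Mumford small-craft formula WSA = 1.7·L_OA·T + V/T for
   pleasure craft < 26 m, and a 9.9 m² constant for tenders.
5. **Summarises threat factors** — per-class annual means ± SE (vessel
   numbers, cumulative WSA, journeys, stops, stop time, origin
   countries, trans-national trips), monthly visit profiles, and ranked
   per-location factor tables (visits, anchor hours, WSA, links, vessel
   types).

## Worked example

```python
from pathways import synthetic_fleet as sf
from pathways.pipeline import run_pipeline

cfg = sf.FleetConfig(seed=1)                 # 101 vessels, 9 classes, 2 years
profiles, truth = sf.generate_fleet(cfg)
records = sf.simulate_tracks(profiles, truth, cfg)
result = run_pipeline(records, profiles, sf.synthetic_geography(),
                      attach_origins=False)

print(f"{len(profiles)} vessels, {len(records)} hourly records")
print(f"recovered {result.counters['n_stop_events']} of {len(truth.stops)} "
      f"true stops at {result.counters['n_nodes']} anchorage nodes")
top = result.location_factors.iloc[0]
print(f"busiest location: {top['label']} ({top['country']}), "
      f"{top['total_visits']} visits, {top['cumulative_wsa_m2']:.0f} m2 hull area")
```

prints

```
101 vessels, 1655461 hourly records
recovered 4013 of 4013 true stops at 11 anchorage nodes
busiest location: King Edward Point (SG), 891 visits, 586132 m2 hull area
```

Every true stop in the simulator's log is recovered and assigned to the
correct anchorage; the busiest node is the mandatory port of call, which
accumulates the most visits and the largest cumulative hull area — the
profile of a high-likelihood introduction and dispersion hub.

There is also a CLI:

```bash
pathways simulate --seed 3 --out-dir sim/      # ais.csv, vessels.csv, truth.json
pathways run --ais sim/ais.csv --profiles sim/vessels.csv --out-dir out/
```

producing `type_summary.csv`, `monthly_profile.csv`,
`location_factors.csv`, `entry_points.csv`, `edges.csv`,
`network.graphml`, `nodes.geojson` and `run.log`.

## Notes

The WSA power-law coefficients ship as an editable CSV
(`src/pathways/data/wsa_coefficients.csv`) with illustrative default
values; substitute fitted regression coefficients for production use.
See `docs/methods.md` for the model, parameter and design documentation.
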
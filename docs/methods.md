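# Methods

## Scope and model

The package quantifies the likelihood that vessel traffic introduces
marine non-native species into a remote archipelago via hull biofouling.
It does not model organisms: the analysis assumes a uniform degree of
hull fouling across vessels and treats vessel *design* (submerged hull
area) and *behaviour* (where, how long and how often vessels stop, and
how anchorages are linked) as proxies for propagule and colonisation
pressure.  Ballast water is excluded, as is the wetted area of internal
seawater systems.

The pipeline is deterministic given its inputs.  Its stages and the
constants that define them:

- **Hourly resolution.**  Position streams are reduced to at most one
  report per vessel per clock hour (the last report in each hour bin,
  stamped with the bin start).  The last-in-bin choice puts the retained
  point closest to the following displacement interval; hourly spacing
  between bins makes the 400 m displacement rule directly comparable to
  a speed.  Resampling is idempotent and never interpolates across gaps.
- **Zone filter.**  Only vessels with at least one point inside the
  maritime-zone polygon (an administrative 200 nm limit supplied as
  geometry, not computed) are analysed; retained vessels keep their full
  tracks.
- **Stationarity.**  A point is stationary iff it moved < 400 m over the
  preceding one-hour interval *and* its reported speed is < 1 kn.  Both
  conditions are required so that an error in either the position or the
  speed field cannot fabricate a stop.  400 m/h equals 400/1852 ≈
  0.216 ≈ 0.2 kn, the underway threshold, which is retained as metadata.
  The first point of a track, and points across gaps > 1 h (where the
  displacement is not a 1-h displacement), are classified by the speed
  test alone; gap points are flagged.
- **Stop events.**  Maximal runs of stationary hours.  Duration is the
  span from first to last stationary timestamp; a single stationary
  point counts one hour, the sampling-resolution floor.  Event position
  is the mean of member positions.
- **Anchorage nodes.**  Only stops within 12 nm (22.224 km, 1 nm =
  1852 m) of the coastline form nodes.  Distance to land is evaluated in
  a local azimuthal equidistant projection centred on each stop, where
  planar distance equals great-circle distance; node clustering uses
  single linkage joining stops whose 5 km buffers overlap (centre
  distance ≤ `cluster_link_km` = 10 km), implemented as connected
  components over a KD-tree on unit-sphere coordinates with the
  equivalent chord radius.  Transitive (single-linkage) merging is a
  documented choice; the algorithm is permutation-invariant because
  node identifiers are assigned in centroid order.  Labels come from the
  nearest gazetteer port within the 5 km buffer (ties alphabetical),
  else a synthetic id.
- **Origins and countries.**  A declared port of origin that resolves in
  the world-port table, lies outside the area of interest and differs
  from the vessel's first observed node adds an external node and a
  zero-duration origin event at the head of the vessel's sequence.
  Origin events create inbound network links but count neither as visits
  nor as stop time (`origin_counts_as_visit = false` in spirit).  Every
  node receives exactly one country/territory code from territory
  polygons, falling back to the gazetteer, else `UNKNOWN` (logged);
  South Georgia (SG) and the South Sandwich Islands (SS) are distinct
  codes.
- **Journeys.**  A new extended journey starts at track start and after
  any stop longer than `rest_threshold_days` = 30 days (the ">1 month"
  rest rule; the month length is fixed at 30 days by configuration).
  The long rest terminates the journey it ends and its node seeds the
  next.  The *stops per journey* metric counts only port calls — stops
  no longer than the rest threshold — because a month-plus lay-up is not
  a call made during a voyage.
- **Voyage network.**  Directed edges between consecutive distinct
  nodes, weighted by unique vessel trips; re-anchoring at the same node
  is a visit, not a trip (no self-loops).  `in_links`/`out_links` count
  distinct neighbour nodes, not weights.  External origin nodes have
  out-edges into the area of interest only.
- **Wetted surface area.**  Power law WSA = a·dim^b on dead-weight
  tonnage; if DWT is missing, breadth overall for the fishing,
  tugs-and-supply and passenger categories and length overall for the
  "Other" category (research vessels map to "Other"; pilot boats to
  tugs-and-supply).  Pleasure craft < 26 m L_OA use Denny–Mumford
  WSA = 1.7·L_OA·T + V/T; larger pleasure craft use the fishing
  coefficients.  All tenders are assigned 9.9 m² regardless of recorded
  length (small-craft value for 4–6 m hulls).  Units: m² from m, tonnes
  and gross tonnage as supplied — no conversions inside formulas.  The
  numeric (a, b) pairs are an *editable input table*; the shipped CSV
  carries illustrative defaults of plausible magnitude, clearly marked,
  because fitted regression values are external to this package.  Every
  result records the method and category used, and a vessel with no
  usable dimension raises a typed error rather than defaulting.
- **Summaries.**  Each per-class metric is computed per study year and
  averaged; SE is the sample standard deviation of the yearly values
  over √(n_years) (with two years, half the absolute difference).
  A visit is attributed to the start month of its stop event.  "Countries
  of origin" counts distinct declared-or-derived origin countries per
  class-year.  Stop time is the per-event mean (a per-vessel variant is
  a trivial aggregation away).  Location ranking uses the mean of
  per-factor descending ranks (ties by visits, then label) — an
  explicit, configurable stand-in for a qualitative heat map.

## The synthetic fleet

The simulator emulates the *structure* of sub-Antarctic traffic rather
than any measured dataset: nine classes with class-specific abundance
(passenger and fishing vessels and their tenders dominate), lognormal
hull dimensions, a small number of extended journeys per year separated
by month-plus rests at a home port, summer-heavy passenger seasonality
against spring-only cargo/tanker windows, and cross-territory routing in
which every non-pilot journey calls first at the mandatory entry port
(King Edward Point).  Parameter values are user-set study conditions.

Design choices made for exact recoverability at hourly resolution:

- stop durations are drawn lognormal per class but floored at 3 h
  (hourly sampling cannot resolve shorter stops) and capped at 300 h,
  safely below the 30-day journey-split threshold;
- rests between journeys are ≥ 32 days, safely above it;
- consecutive stops never repeat a port, and the default ports are
  mutually ≥ 25 km apart, so each visited port maps to exactly one
  anchorage node;
- journey and stop counts use a balanced (Bresenham) integer allocation
  whose class mean equals the configured rate exactly, making
  parameter-recovery tests sharp; the composition of each journey
  (ports, durations, timing) remains random;
- tenders replicate the routing of a mother passenger/fishing vessel on
  their own schedule, reflecting their tie to mother ships;
- optional Gaussian positional jitter and record dropout default to 0
  (noise-free), so recovery tests are exact.

What the simulator does **not** emulate: real coastline geometry (land
masses are rectangles), weather and ice routing, AIS message-level
artefacts (NMEA decoding, MMSI changes, class-B reporting rates), or
behavioural realism beyond the statistical structure the pipeline
consumes.  Passing recovery tests therefore demonstrates the pipeline's
correctness on well-formed hourly streams, not robustness to the full
messiness of real AIS feeds (dropout and jitter switches exist for
stress-testing).

## Numerical choices

- Geodesy is spherical (R = 6,371,000 m); haversine is used for
  distances (stable at small separations), checked in tests against an
  independent spherical Vincenty/law-of-cosines oracle to < 0.1 m.
- Longitudes normalise to (−180, 180]; the study box does not cross the
  dateline, so the bounding-box test needs no wraparound logic.
- Clustering radii convert great-circle to chord distance for the
  KD-tree; at 10 km the two differ by well under a millimetre.
- Degenerate inputs: empty fleets, empty events, zero-length transits
  between co-located ports, single-record tracks and all-missing hull
  dimensions are all exercised in tests; errors are typed
  (`SchemaError`, `ConfigurationError`, `MissingDimensionError`) and
  name the offending field.

## Problem sizes

The default fleet (101 vessels, 2 study years, ~1.7 M hourly records,
~4,000 stop events) runs through the full pipeline in well under a
minute; the test suite uses a 25-vessel fleet spanning all nine classes
and finishes in seconds.  These sizes were chosen as the smallest
configurations that exercise every class, season window and routing
pattern while keeping iteration fast.

## Known limitations

- The shipped WSA coefficients are placeholders; class-level WSA
  magnitudes are only meaningful relative to the table supplied.
- Country assignment relies on supplied polygons/gazetteers; there is no
  reverse geocoding.
- The stationarity rule follows the stated thresholds only; any further
  transit-simplification heuristics beyond them are out of scope.
- Whether declared-origin links should count toward per-node link totals
  is a modelling choice; here they do, and external nodes are
  distinguishable via `is_external`.
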
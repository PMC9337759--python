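# Methods

This note documents the models and procedures implemented in `firetrack`,
the assumptions behind them, and the numerical and design choices made where
the design was genuinely open.

## Gridding and the analysis grid

Detections are binned onto a regular 0.005° lon/lat grid (~550 m at the
study latitudes), chosen to accommodate understory fire spread rates of
100–400 m/day and to damp residual geolocation error in the persistence
metric. The grid is anchored at integer degrees, so a point falls in the
same cell regardless of the processing extent; cells are half-open
`[k·res, (k+1)·res)` rectangles. "Day" is the UTC acquisition date.
Detections from both satellites are pooled before gridding; the satellite id
survives only as a tie-break in the earliest-detection ordering (day, then
acquisition time, then satellite id). Cell areas use the spherical
approximation `(res·111.32 km)²·cos(lat)`, adequate within ~25° of the
equator. Zero-FRP detections are kept for footprint and persistence but
excluded from FRP means, since they are missing retrievals rather than
zero-power fires.

## Event clustering and the linking window

Two 8-adjacent cells belong to the same fire iff some detection day of one
lies within the linking window (default 5 days) of some detection day of the
other; events are the transitive closure of these links. Three alternative
readings of the "≤ 5 days after the last detection" rule were considered:

* a *symmetric interval* predicate (either cell's first day within the
  window of the other's last day) is vacuously true for any adjacent pair,
  because the earlier-starting cell's first day always precedes the other's
  last day — it cannot be what the rule means;
* a *directional* predicate (later cell's first day ≤ earlier cell's last
  day + window) matches the common case but is **not** equivalent to daily
  incremental tracking when a cell lies dormant longer than the window and
  then re-ignites;
* the *detection-day gap* predicate used here is symmetric,
  order-independent, and provably identical to the day-by-day tracker —
  when the later of any within-window detection pair arrives, the earlier
  cell's event is still open and the union happens then.

For fires with temporally contiguous activity (every archetype the
generator produces, and all but pathological real fires) the three readings
agree; the gap predicate is preferred because batch/incremental equivalence
is the property the near-real-time product rests on. One consequence is
that a "closed" event (no activity for more than the window) is re-opened
if one of its own cells re-ignites: open/closed is a function of the
current state, not a ratchet.

8-connectivity (rather than 4) is used because diagonal spread across 550-m
cells is physically routine. When a new cell bridges two open events they
merge; the merged event keeps the smaller event id and hence the earlier
ignition history.

## Ignition estimation

Per-cell burn dates (first detection day) are smoothed with a 3×3 median
filter restricted to the event footprint (lower median on even counts),
suppressing single-cell date outliers; the exact filter used by the
operational fire atlases is not published, and the median is the documented
stand-in. The ignition cell minimizes the filtered date, with ties broken
by the earliest raw detection timestamp and then by (row, col); the
ignition day is that cell's raw first day. On simulated front-spread fires
this recovers the seeded ignition within one cell in well over 95% of runs.

## Static-source exclusion

An event is discarded when any of its cells shows more than 20 detections
in at least 3 of the 7 historic years (a gas flare, volcano or industrial
site signature). The thresholds are config keys
(`static_detections_per_year`, `static_min_years`, `historic_years`).

## Metrics and the daily cumulative view

All event metrics accept a cutoff day and use only detections acquired on
or before it, which makes the end-of-season and near-real-time views the
same code path. Persistence counts *distinct active days* per cell (not
detection counts — the generator and classifier both assume day-presence
semantics, and the choice is isolated behind `cell_persistence`). Mean FRP
weights all detections equally; per-cell metrics are averaged with equal
weight per cell. Duration is inclusive of both end days. The 2014
tree-cover layer is the 2000 baseline zeroed wherever loss was recorded in
2000–2013; at the ~550-m cell scale the loss is treated as whole-cell
(the sampling operation accepts precomputed fractional layers when
available).

## Classification

The decision flow runs daily on cumulative per-event averages, so a fire
that ignites in savanna and grows into forest flips type when its mean tree
cover crosses 50%. The five-indicator vote applies only to large fires that
escaped the primary rules; its default cutpoints are `frp_high = 15 MW`
(deforestation fires average ~15–16 MW against ~11–12 for the other types),
`persistence_high = 2` days, `day_fraction_high = 0.7`, and
`density_high = 10` detections/km² (typical of dense understory-fire point
clouds). The published sources specify the indicator list but not the
numeric cutpoints, so all five live in `ClassifierConfig` and are never
hard-coded. Intermediate score bands (4 → medium and 3 → low deforestation,
2 → low and 1 → medium forest) are likewise configurable: the confidence
ladder is symmetric around the 5/0 extremes, which the sources do fix. In
the dry (< 120 t/ha) regime the FRP and day-fraction votes invert, because
dry forest fires behave like savanna fires — higher FRP, faster spread,
pronounced daytime diurnal cycle. "Small" is defined as the complement of
"large" (≤ 5 detections *or* persistence ≤ 1): the two published phrasings
conflict, and the large-fire definition is taken as authoritative.

A structural consequence of the flow: on its first day every event has
persistence 1, so fires not caught by the savanna or historic-deforestation
rules are necessarily "small" at a 1-day lag. Lag-agreement curves (the
fraction of detections whose classification after L days of data matches
the final type) therefore start low for forest fires and converge within a
week, which matches the operational experience the product mirrors.

## Burned-area calibration

Reference burn clusters are maximal 8-connected components of burned cells.
Each cluster takes the type of the event with the largest intersecting
area (ties toward the earlier ignition); zero-overlap clusters become
savanna below 50% tree cover, else a diagnostic `residual` class excluded
from fitting and emissions. Scaling factors are per 0.5° cell and per type
(savanna, deforestation): reference area over footprint area where both
exceed 50 km², with unresolved cells pooled at 1°, 2°, 4°, then a single
continental factor. An event's factor is looked up at its *ignition* cell
— the same attribution used during fitting — so within every natively
resolved cell the summed scaled burned area reproduces the reference
exactly, by construction. If the continental pool still lacks support but
both totals are positive, the pooled ratio is used regardless (the final
region is unconditional); a nonzero reference with zero footprint raises.
Footprint area in the ratios counts full cell areas, not detection-weighted
areas. Small fires burn far below the 375-m pixel scale and use the fixed
0.1 factor; burned-area products systematically miss understory fires under
dense canopy, so forest footprints pass through unscaled. When no reference
raster is supplied the pipeline downgrades explicitly: savanna and
deforestation factors become 1.0 with a warning, the small and forest rules
being unaffected.

## Fuel consumption and emissions

Event FRP density is the total detection FRP over burned area (MW/ha). The
q-q calibration evaluates both empirical distributions at the field
observations' plotting positions `(i − 0.5)/n` with linear interpolation
between order statistics (Hazen convention), fits ordinary least squares on
the log₁₀ pairs whose density quantile lies inside the 2–98 percentile
band, and back-transforms the band-edge predictions into hard caps. Fuel
consumption is predicted from density (FC on FRPd — the prediction
direction), base-10 logs throughout. Zero-density events floor at `fc_min`:
zero-FRP retrievals are sensor dropouts, not zero-fuel fires. Types with a
single field observation (forest) use mean matching — identity slope in log
space, intercept from the ratio of means — with more conservative 10–90%
caps; the pipeline also falls back to mean matching when a type has fewer
than ten event densities, which a q-q fit cannot support. The packaged
field observation sets are synthetic lognormal draws with the historical
campaign sample sizes (8 savanna, 19 deforestation, 4 pasture, 1 forest)
and literature-scale means (6.5 / 95 / 23 / 40 t/ha); they are clearly
labelled stand-ins and replaceable by a two-column CSV. Carbon is dry
matter × EF/1000 with EFs of 491/491/480/488 g C per kg dry matter
(deforestation and forest share a factor, as the underlying inventory does
not separate them).

## Synthetic seasons: what they emulate, and what they do not

The generator paints a block landscape (forest blocks ≥ 50% cover with
moist biomass ≥ 120 t/ha, savanna blocks below 50%) and lays one event per
lattice block with margins, so the true partition of detections into events
is unambiguous and recovery can be scored exactly. Archetype parameters:
deforestation fires burn 2–3 cells for 3–8 days at ~15.5 MW on
historic-deforestation patches; forest fires advance a circular front at
180–380 m/day for 8–18 days at ~10 MW with 2–4 detections per newly burned
cell plus next-day smoldering (spread held above ~180 m/day so a 550-m
diagonal step never exceeds the 5-day window — slower fronts would
legitimately fragment); small fires are ≤ 5 detections on one day; savanna
fires sweep a 2–3-cell-wide ribbon at 1.4–3.3 km/day for 1–4 days with a
0.85 daytime fraction; static sources recur in one cell for 3–6 weeks with
planted historic counts. The reference burned-area raster includes all
savanna/deforestation footprint cells, 10% of small-fire cells, and no
forest cells (dense-canopy omission). FRP means are anchored to the
published per-type contrasts as calibration, not ground truth.

What passing tests on these seasons shows: the clustering, filtering,
classification, scaling and emission machinery implement their rules
exactly and recover well-separated archetypes essentially perfectly. What
they do not show: performance on real landscapes with overlapping and
ambiguous fires, mixed cover within events, cloud-obscured days, dry-forest
regimes (the generator paints forest moist; the dry branch is exercised by
targeted unit tests), or classifier cutpoints tuned against real reference
fires. Real-data accuracy claims require the independent validation the
original analysis performed.

## Desk-scale problem sizes

Default suites run seasons of ~45 events on a 1°×1° grid and the recovery
experiment at 50 events per archetype on 2°×2° (~26 000 detections); the
equivalence oracles use 100 random scenes of up to 50×50 cells and 300
detections. These sizes were chosen so the whole suite completes in well
under a minute while every code path, including the coarse levels of the
region-growing fit, is exercised.

## Worked-example table and rounding

The packaged 2019 southern-Amazon summary reproduces the published share
figures under two documented rounding conventions: complete compositions
(the four detection shares) use largest-remainder rounding so integers sum
to 100 — plain half-away rounding of 38.68/11.53/17.52/32.26 would print
39/12/18/32 and sum to 101 — while standalone quantities (emission and
burned-area shares, detections per event, the size ratio) round half away
from zero. Mean event size in summaries is total burned area over event
count, which for forest fires equals the footprint-based mean because their
scaling factor is identity.
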
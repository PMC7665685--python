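# peskas

Analytics for small-scale fisheries monitoring: catch-weight estimation
from length, quality-control flagging, fisher-hour CPUE, vessel activity
coefficients from GPS tracks, national catch raising, and nearest-neighbour
imputation of gear and habitat for tracked-but-unobserved trips.

## Who this is for

Small-scale fisheries (canoes, small motorboats, shore-based gleaning) land
a huge share of the world's catch but are rarely weighed, logged or
assessed. A practical monitoring system pairs **enumerators at landing
sites** — who record species group, fork length, count, price, gear,
habitat and trip effort — with **solar GPS trackers** on a subset of boats
pinging every ~5 seconds. This package is the analytics core for such a
deployment: it turns raw landings CSVs and track point streams into clean
records, CPUE series, effort maps, and a monthly national catch estimate,
with every suspect record flagged for curation instead of silently used or
silently dropped.

## The statistics at the core

**Weight from length.** Catch is not weighed at the beach; record weight is
estimated from the allometric length-weight relationship, per taxon:

    W (kg) = n · a · L^b / 1000        (L = fork length in cm; a, b in the cm→g convention)

**Effort and CPUE.** Effort is standardised to *fisher-hours* (trip
duration × people fishing). Stratified CPUE is the ratio of totals
Σcatch / Σeffort (kg per fisher-hour); zero-catch trips contribute effort.

**National raising.** The monthly national catch (tonnes) raises sampled
per-trip statistics to the fleet census:

    C = Σ_b  CPUE_b · EPT_b · VAC_b · N_b · 0.001

over boat types *b* (canoe, motor; shore-based fishing is excluded), where
EPT_b is the median effort per trip, VAC_b the vessel activity coefficient
(mean trips per boat per month, counted from GPS tracks) and N_b the census
fleet count.

**Gear/habitat imputation.** Trips that are tracked but not met by an
enumerator lack gear and habitat. Each track is summarised by 10 positions
at even time intervals (km in a local equirectangular frame, a
20-dimensional feature); labels are copied from the Euclidean-nearest
*linked* trip (one with both a track and a catch record), but only when
that donor lies within 0.20 km in feature space. Accuracy is estimated by
repeated 80/20 hold-out splits of the linked set.

A synthetic-fishery generator (`peskas.simulate`) produces all four inputs
with exact ground-truth bookkeeping, so the whole chain is testable without
any field data.

## Worked example

```sh
peskas simulate --seed 17 --out demo/in
peskas ingest  --landings demo/in/landings.csv --tracks demo/in/tracks.csv \
               --species demo/in/species.csv --out demo/store
peskas report  --in demo/store/clean_store.csv --species demo/in/species.csv \
               --tracks demo/in/tracks.csv --census demo/in/census.csv \
               --month 2019-01 --out demo/report
peskas validate --in demo/store/clean_store.csv --species demo/in/species.csv \
                --tracks demo/in/tracks.csv --iterations 100 --seed 1
```

prints

```
wrote synthetic fishery (40 observed trips, 40 tracks) to demo/in
40 trips in, 40 clean, 0 flag rows, 0 parse errors
2019-01: 8 summary rows, national estimate 0.444 t -> demo/report
gear accuracy 93.9% (SD 7.8), habitat accuracy 93.9% (SD 7.8) over 100 iterations on 40 linked trips
```

and `demo/report/fleet_estimate.csv` holds the raising components:

```
month,boat_type,cpue_kg_per_fisher_h,ept_fisher_h,vac_trips_per_boat,n_boats,catch_tonnes
2019-01,canoe,0.9496827406047224,10.0,4.0,6,0.22792385774513338
2019-01,motor,0.9010442925968,15.0,4.0,4,0.216250630223232
2019-01,TOTAL,,,,,0.44417448796836534
```

Reading the numbers: the simulated fleet (6 canoes, 4 motorboats, 4 trips
per boat in January, constant effort per trip) truly landed 444.17 kg —
the generator's `truth.json` records it — and the estimate recovers
0.44417 t exactly, because with constant effort per trip the median-effort
term introduces no approximation. The hold-out accuracy of ~94% reflects
40 linked trips spread over four fishing grounds: most queries find a
within-cutoff donor from their own ground.

## Landings CSV schema

One row per landing record; trip-level columns repeat across a trip's rows.

| column | meaning |
|---|---|
| trip_id, site, municipality, date | trip identity; ISO-8601 date |
| boat_type | `canoe`, `motor`, or `shore` |
| gear | gill net, seine net, beach seine, hand line, long line, spearfishing, trap, gleaning |
| habitat | reef, FAD, deep, shore, mangrove |
| n_fishers, duration_h | effort components (fisher-hours = product) |
| unit_id | GPS tracker unit on the boat, if any |
| record_id, taxon_code | landing identity and species group |
| fork_length_cm, n_individuals | size (nearest cm) and count |
| price, price_basis | optional sale price, `per_kg` or `per_fish` |

Tracks are CSV (`unit_id,timestamp,lat,lon[,boat_type]`) or a GeoJSON
FeatureCollection of Points with the same properties. Species parameters
(`taxon_code,name,a,b,length_min_cm,length_max_cm,price_min,price_max`) and
the fleet census (`boat_type,n_boats`) are small CSVs.

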
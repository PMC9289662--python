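# parkflux

Builds weighted bipartite networks linking census tracts to parks from daily
mobility trajectories, and analyzes them: exposure/demand strengths, weighted
neighbor averages, predominant-group labeling, homophily, Barber bipartite
modularity with leading-eigenvector community detection, and mutual-information
permutation tests between demographic and community labels.

The pipeline consumes three inputs, all in a planar metric coordinate system
(meters):

* **tracts** — GeoJSON polygons with per-group population counts
  (`White`, `Black`, `Asian`, `Hispanic`, `Other`), either as feature
  properties or joined from a CSV keyed by `tract_id`;
* **parks** — GeoJSON polygons, optionally raw tagged records
  (`leisure=park|dog_park|playground|garden|golf_course`,
  `landuse=recreation_ground|nature_reserve`, `natural=beach`,
  `boundary=protected_area`) that are filtered and dissolved into a spatially
  disjoint set;
* **trajectories** — CSV with columns `agent_id, kind∈{home,other}, x, y,
  slot`; one home row per agent.

Each *other*-type activity exposes the agent to every park within 200 m
(configurable) of the activity point; the exposure is credited to the tract
containing the agent's home, producing an integer tract×park incidence matrix.

## CLI

```bash
# generate a synthetic city (tracts.geojson, parks.geojson, trajectories.csv)
parkflux simulate --seed 7 --out city/

# dissolve overlapping park polygons (optionally filter raw tagged records)
parkflux merge-parks --parks raw.geojson --filter-tags --out parks.geojson

# build the incidence network (MatrixMarket + row/col id maps)
parkflux build-network --tracts city/tracts.geojson --parks city/parks.geojson \
    --trajectories city/trajectories.csv --radius 200 --out net.mtx

# strengths, labels, homophily, crosstabs
parkflux metrics --network net.mtx --tracts city/tracts.geojson \
    --parks city/parks.geojson --out-dir metrics/

# bipartite-modularity communities
parkflux communities --network net.mtx --seed 0 --out communities.csv

# log-binned densities and log-normal fits
parkflux distributions --network net.mtx --parks city/parks.geojson --out-dir dist/

# full pipeline from a JSON config (RunConfig fields)
parkflux report --config run.json
```

A minimal `run.json`:

```json
{
  "tracts_path": "city/tracts.geojson",
  "parks_path": "city/parks.geojson",
  "trajectories_path": "city/trajectories.csv",
  "out_dir": "out",
  "radius_m": 200,
  "n_permutations": 5000,
  "seed": 0
}
```

## Package layout

| module | contents |
|---|---|
| `parkflux.geo_core` | tract/park data model, tag filter, overlap dissolve, point-to-tract assignment, park-area fractions |
| `parkflux.exposure` | activity/trajectory model, radius exposure test, incidence construction, network summaries |
| `parkflux.node_metrics` | strengths, weighted neighbor averages, group labels, homophily, crosstabs |
| `parkflux.communities` | bipartite modularity, leading-eigenvector detection, mutual information + permutation null |
| `parkflux.distributions` | log-binned densities, log-normal fits, mean visited-park area, median travel distance |
| `parkflux.synthetic_city` | seedable city/trajectory generator, worked-example fixture, planted-partition networks |
| `parkflux.io` | GeoJSON / CSV / MatrixMarket readers and writers |
| `parkflux.report`, `parkflux.cli` | pipeline orchestration and the `parkflux` command |
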
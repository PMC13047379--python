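# specimenflow

Analysis pipeline for the global geography of natural-history specimen
holdings: country-to-country directed, weighted specimen-flow networks built
from Darwin-Core-style occurrence tables, per family × time-period slice.

The package covers:

- **Synthetic data** (`specimenflow.synthetic`) — a GBIF-like occurrence
  generator with tunable holdings concentration (symmetric Dirichlet),
  reciprocity, domestic (self-loop) fraction, temporal spread and
  mutually-exclusive row defects, plus registry and country-lookup tables,
  so the entire pipeline is testable offline.
- **Ingest** (`specimenflow.ingest`) — parsing, ISO 3166-1 alpha-3 country
  standardisation, institution-code → holding-country resolution and an
  ordered filter-rule chain with an exact audit log (every input row is
  attributed to the first rule it fails, or survives).
- **Flow networks** (`specimenflow.network`) — per-slice edge aggregation
  (edge weight = specimen count), a separate domestic ledger excluded from
  topology, and six slice metrics: nodes, edges, density, reciprocity,
  giant weakly-connected component fraction, and Louvain modularity on the
  undirected weight-summed projection.
- **Inequality** (`specimenflow.inequality`) — holdings distributions
  (in-strength + domestic) and Gini coefficients with participants-only /
  include-zeros variants and population / sample-corrected estimators.
- **Trends** (`specimenflow.trends`) — linear fits on period midpoints
  (1915, 1945, 1975, 2005), quadratic-vs-linear nested-model F tests,
  Welch early-vs-recent comparisons, Pearson couplings, an edges~nodes
  model, an additive two-way ANOVA on Gini, and a sensitivity sweep over
  edge-weight thresholds, Gini variants and alternative binnings.
- **Rankings** (`specimenflow.rankings`) — per-slice net importer/exporter
  tables (net = in − out; normalised balance (in−out)/(in+out)) and top-k
  lists, per family or pooled.
- **Pipeline + CLI** (`specimenflow.pipeline`, `specimenflow.cli`) —
  deterministic end-to-end runs producing a checksummed artefact bundle.

## CLI

```sh
# synthesise a dataset
specimenflow simulate --seed 1 --n-records 5000 --out data/

# filter with audit log
specimenflow filter --input data/occurrences.csv --registry data/registry.csv \
    --country-lookup data/country_lookup.csv \
    --filter-log out/filter_log.json --out out/records.csv

# per-slice outputs
specimenflow metrics  --records out/records.csv --out out/metrics.csv
specimenflow gini     --records out/records.csv --out out/gini.csv
specimenflow rankings --records out/records.csv --out out/rankings.csv
specimenflow trends   --records out/records.csv --out out/trends.csv

# everything at once (synthetic by default, or --config run.yaml)
specimenflow run-all --seed 1 --out out/
```

`run-all` writes eight artefacts (filter log, cleaned records, edge lists,
metrics, Gini, rankings, trends, sensitivity) plus a `manifest.json` with a
config hash and SHA-256 checksum per file; reruns with the same seed and
config are byte-identical.

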
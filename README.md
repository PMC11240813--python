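# herdrank

Analysis chain linking social hierarchy in group-housed pigs to feeding
behaviour, growth, and faecal microbiota — implemented end-to-end on
synthetic cohorts with planted effects.

The package covers:

- **`herdrank.simulate`** — synthetic cohorts: 8 pens × 8 animals
  (4 castrated males + 4 females), control vs. stress treatments with two
  mixing events (days 61 and 83), Bradley–Terry bout outcomes,
  electronic-feeder event logs, growth trajectories from ~18 kg to
  ~140 kg, and genus-level abundance matrices with 5 planted differential
  genera (3 dominant-enriched, 2 submissive-enriched) carrying both an
  abundance shift and class-specific co-occurrence rewiring.
- **`herdrank.dominance`** — round-robin tournament scheduling (circle
  method: 28 pairings over 7 days of 4 disjoint pairs for a pen of 8),
  bout scoring (+1 winner / −0.5 loser, confirmed tally, draws neutral,
  inconclusive bouts excluded), ranking score
  `dominant_mean / 2 + confirmed_mean`, top-2 / middle-4 / bottom-2
  classification, Better/Worse/Same change labels and transition tables.
- **`herdrank.feeding`** — per-animal-day metrics from raw feeder events
  (intake, visits, durations, feed rate, six 4-h time slots with pro-rata
  splitting), pen-relative normalization by the same-day pen median
  (mixing-aware), and per-phase aggregation (medians; means for slots;
  median of daily medians for session duration).
- **`herdrank.stats`** — OLS with treatment coding and coefficient
  t-tests, a profiled-REML random-intercept model for repeated weights,
  and Pearson chi-square tests for transition counts.
- **`herdrank.microbiome`** — rarefaction, Shannon alpha, Bray–Curtis and
  Whittaker beta diversity, SparCC-style compositional basis
  correlations, thresholded co-occurrence networks, topological-overlap
  module detection, module-transition ("driving force") scores between
  the dominant and submissive networks, FDR-gated biomarker calling, and
  stratified 5-fold cross-validated AUC of the called panel.
- **`herdrank.pipeline`** — one-seed reproducible orchestration with all
  intermediates persisted as CSV/TSV plus a JSON report, and a replicate
  harness for sign-agreement/recovery summaries.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (tournament
structure, 2/4/2 classification totals, ranking arithmetic to 1e-12,
exact rarefaction depth 31,731, planted-biomarker recovery and panel AUC
over 20 replicates, type-I error calibration, and module-transition
score sanity against a shortest-path oracle).

## CLI

```bash
herdrank run --seed 1 --outdir out            # full pipeline
herdrank replicate -n 20 --seed 1             # replicate summary
herdrank schedule --n-animals 8               # tournament schedule
herdrank rank out/bouts.csv --phase 1         # ranking scores
herdrank classify ranking.csv out/animals.csv
herdrank transitions hier1.csv hier2.csv
herdrank feeding summarize out/feeding_events.csv
herdrank microbiome rarefy out/abundance.tsv --depth 31731
herdrank microbiome biomarkers out/abundance.tsv out/metadata.csv
herdrank microbiome roc out/abundance.tsv out/metadata.csv --panel g01,g02,g03,g04,g05
```

`herdrank run --config run.yaml` accepts a YAML file mirroring
`herdrank.config.RunConfig` (cohort layout, effect sizes, microbiome
parameters, stage toggles, seed).

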
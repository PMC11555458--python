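# disdrift

Detection, initial characterization and semantic characterization of
temporal data drifts in health care event data, as a tested library +
CLI, with a seeded synthetic cohort generator so every stage is
exercisable without access to real (credentialed) clinical data.

## What it does

A cohort is split into ordered temporal chunks; the first chunk is the
reference slice. Three analysis stages run against it:

1. **Detection** — five chunk-vs-reference drift metrics:
   Jensen-Shannon divergence over token frequencies, centroid cosine
   distance, PCA reconstruction error, autoencoder reconstruction
   error, and two-chunk classifier separability (balanced accuracy).
   Signals are min-max normalized and flagged when a raw value exceeds
   `mean + k·SD` of a reference window (default `k = 2`).
2. **Initial characterization** — outcome prevalence over time,
   per-chunk feature-outcome Pearson/Spearman correlations, seeded
   random-forest importances, and per-outcome-class centroid drift
   against the reference chunk.
3. **Semantic characterization** — skip-gram embeddings of event
   tokens trained jointly with chunk-tagged outcome tokens (e.g.
   `deceased@2020`), so a token's change in cosine similarity to the
   outcome between the first and last chunk can be ranked and
   aggregated by chapter. Low-granularity (one-row-per-patient)
   cohorts are first discretized into attribute tokens and embedded
   via random walks on a bipartite patient-attribute graph. A
   TF-IDF + spectral-clustering comparator is included as the
   non-semantic baseline.

Two data modes are supported: *high granularity* (ordered event
sequences per patient, chunked by a label column) and *low granularity*
(one attribute snapshot per patient, chunked by admission date).

The `disdrift.synthetic` module generates seeded cohorts in both modes
with injectable drifts (sudden / incremental / gradual / reoccurring)
targeting token frequencies, outcome prevalence, token- or
feature-outcome associations, and numeric outliers. The injected
schedule is exported as a ground-truth sidecar for recovery testing.

## CLI

```bash
# generate a synthetic cohort (+ ground-truth sidecar)
dis simulate --mode high --n-chunks 5 --n-patients 300 --seed 7 --out cohort.csv

# drift detection
dis detect --input cohort.csv --metric all --k-sd 2 --out signals.csv

# initial characterization tables
dis characterize --input cohort.csv --outcome deceased \
    --stats prevalence,pearson,importance,centroid --out tables/

# semantic similarity deltas
dis semantic --input cohort.csv --outcome deceased --dims 64 --seed 7 --out deltas.csv

# full gated pipeline (semantic stage runs only if drift was flagged)
dis run --input cohort.csv --seed 7 --out run_out/
```

Exit codes: 0 ok, 1 validation error, 2 runtime error. `dis run`
writes `report.json`, `report.md`, per-metric signal plots and a config
snapshot sufficient to reproduce the run.

## Reproducibility

Every stochastic component (cohort generation, autoencoder training,
classifier cross-validation, skip-gram training, random walks) flows
through a single seed and runs single-threaded; identical seeds produce
byte-identical CSV/JSON outputs.
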
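# netreconfig

Dynamic functional-network reconfiguration analysis for multichannel
electrophysiological recordings: windowed phase-locking connectivity,
statistically validated multilayer community detection, and network
reconfiguration metrics, with group-level statistics and classifier
benchmarking. A synthetic oscillatory-cohort generator with planted
ground truth drives the test suite end to end.

## Pipeline

1. **signal_io** — read recordings (plain EDF or delimited matrix +
   JSON sidecar), notch out power-line interference, 1 Hz high-pass,
   zero-phase Butterworth decomposition into delta/theta/alpha/beta/gamma,
   segmentation into non-overlapping 2 s windows.
2. **connectivity** — analytic-signal phases, pairwise phase locking
   values (PLV) per window, assembly into one multilayer network per
   band (layer = window).
3. **dynamic_communities** — per-layer Louvain modularity optimization;
   100 degree-preserving, weight-multiset-preserving surrogates per layer
   with a Bonferroni-corrected empirical validation test; greedy Jaccard
   label alignment; temporally regularized consensus (ordinal inter-layer
   coupling ω, best of 100 seeded optimizations).
4. **reconfiguration** — per node: flexibility, disjointedness, cohesive
   fraction (f = c + d exactly), cohesion matrix and cohesion strength;
   per subject × band: community cohesion, community disjointedness and
   community change (= cohesion + disjointedness exactly).
5. **group_analysis** — Kruskal–Wallis omnibus per metric × band × site,
   Dunn post-hoc pairwise tests with Benjamini–Hochberg FDR, significance
   matrices per group pair, and a repeated matched-subsampling benchmark
   of six classifiers (SVM-RBF, random forest, gradient boosting, MLP,
   KNN, naive Bayes) on site × band cohesion-strength features.
6. **synthetic** — community schedules, planted stochastic-block
   multilayer networks, and multichannel oscillatory recordings in which
   channels sharing a community carry a common band-limited carrier;
   cohorts with a planted per-group coupling deficit that lowers
   downstream cohesion strength.

## Command line

```bash
# write a two-group synthetic cohort (recordings, ground truth, manifest)
netreconfig simulate --out cohort/ --seed 1 --n-subjects 10

# recordings -> tidy reconfiguration metric table
netreconfig metrics --manifest cohort/manifest.csv --out metrics.csv \
    --seed 1 --omega 1.0 --gamma 1.0 --n-surrogates 100 --n-init 100

# classifier benchmark on cohesion-strength features
netreconfig classify --table metrics.csv --target-group patient \
    --reps 1000 --seed 1 --out classification.csv

# everything from a YAML config (simulate -> metrics -> stats -> classify)
netreconfig run --config cfg.yaml
```

## Data formats

- Recordings: plain EDF, or tab-delimited matrix (header row of channel
  labels, one row per channel) with `<name>.json` sidecar (`fs`,
  `labels`, optional `subject_id` / `group`).
- Multilayer networks: text blocks of layer matrices + JSON metadata.
- Partition sequences: TSV (node × layer labels) + JSON sidecar
  (per-layer modularity, validation flags, parameters).
- Metric tables: tidy CSV (`subject_id, group, band, site, metric,
  value`).
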
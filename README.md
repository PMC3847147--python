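# aliasclust

Technical-alias clustering for SELDI-TOF protein-profiling peak tables.

## The problem

Protein-profiling biomarker studies (SELDI-TOF-MS) export tables of peak
intensities in which one protein typically appears as **several peaks**:
at charge states z = 2 or 3 (apparent m/z ≈ mass/z), as dimers or trimers,
and again in spectra acquired at other laser energies, on other array
surfaces, or in other chromatographic fractions.  These *technical
aliases* are strongly correlated columns that inflate the number of
statistical tests, distort FDR estimates, and clutter the candidate list
a biochemist must triage.

`aliasclust` identifies alias groups and replaces each with a single
centroid feature:

1. **Candidate search.**  Peak pairs whose masses are integer multiples
   (m ≤ 3) of each other, or equal across acquisition conditions, are
   candidates.  Because mass accuracy is modest, a match is accepted
   inside a window centered at the expected mass whose total width is a
   mass-dependent percentage (0.1% below 10 kDa, 0.15% to 30 kDa, 0.5%
   to 100 kDa, 1% above).  Example: for a parent at m/z 66,000 the z = 2
   window is **32,918–33,082 Da** (0.5% of 33,000).  The search widens in
   four steps: within one condition, across laser energies, across
   surfaces, across fractions.
2. **Ratio CV test.**  For a candidate pair the per-sample intensity
   ratio rᵢ = aᵢ/bᵢ is formed; the pair is accepted iff
   CV(r) = sd(r)/mean(r) falls strictly below a user threshold.  True
   aliases are proportional across samples, so CV(r) ≈ 0.
3. **Centroids.**  Accepted pairs form a graph whose connected
   components are clusters.  Each feature is a mean-centered unit vector
   over samples; a cluster's centroid is the weighted member average
   (re-centered, re-normalized) with weights
   wᵢ ∝ 1 / (σ²ᵢ + ‖vᵢ − c‖²) — replicate-measurement noise plus
   lack-of-fit — normalized to sum to 1.

Downstream, features are compared between groups with the two-sided
Mann–Whitney U test and Benjamini–Hochberg FDR.  A synthetic-data module
generates peak tables with planted aliases and performs the
sample-identity randomization experiments used to validate the method.

## Worked example

```sh
aliasclust simulate --seed 7 --n-samples 20 --n-proteins 12 --out-dir demo
aliasclust run --input demo/peak_table.tsv --design demo/design.tsv \
    --threshold 0.3 --out-dir demo/run
```

prints

```
INFO aliasclust: wrote 23 peaks (11 planted alias pairs)
INFO aliasclust: step 3 skipped (not applicable to this table)
INFO aliasclust: step 4 skipped (not applicable to this table)
INFO aliasclust: single surface, unfractionated: analysis finished after steps 1-2
INFO aliasclust: peaks in: 23; clusters: 6; peaks clustered: 17; features out: 12
```

23 peaks enter; 17 of them collapse into 6 clusters, so 12 features
remain (23 − 17 + 6 = 12: feature conservation).  The cluster report
lists each member with its weight and noise, e.g.

```
cluster_id   member                  ...  mass_da  weight  replicate_variance
cluster_001  Fx0_CM10_high_C011549_  ...  11549.0  0.3013  8.59e-05
cluster_001  Fx0_CM10_high_C023095_  ...  23095.0  0.6987  6.83e-05
```

— an 11.5 kDa peak identified as the z = 2 alias of the 23.1 kDa parent;
weights within a cluster sum to 1.  `demo/run/` also holds the
pre-clustering normalized table and the post-clustering centroid table
(one mean-centered unit vector per feature per sample), ready for

```sh
aliasclust stats --centroids demo/run/centroids.tsv --design demo/design.tsv \
    --out demo/stats.tsv
# INFO aliasclust: 0/12 features significant at FDR 0.05
```

(at these small-sample demo conditions the planted group effect does not
survive FDR — the point of the demonstration is the feature reduction).
A threshold sweep for plotting cluster counts against the CV threshold is
available via `aliasclust sweep`.

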
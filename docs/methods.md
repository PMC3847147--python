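# Methods

## Data model

The input is a peak-intensity table from a SELDI-TOF protein-profiling
study after vendor-side spectrum processing (baseline subtraction,
per-energy normalization, peak detection): rows are detected peaks,
annotated with chromatographic fraction, array surface, laser energy and
a vendor mass label (`C066628_` → 66,628 Da, or a bare number); columns
are per-sample duplicate intensities.  A separate design file pairs the
two replicate columns of each sample and may assign group labels.
Spectrum-level processing is out of scope: intensities are taken as
exported.

Missing cells (empty or `NA`) are imputed by k-nearest-neighbor over
peaks: for a missing cell the donor peaks observed in that column are
ranked by Euclidean distance over jointly observed columns, and the mean
of the k = 10 nearest donors' values in that column is used (k capped at
the available donors; ties broken by distance, then mass, then label —
fully deterministic).  Each peak is then collapsed to its per-sample
replicate means and represented as a mean-centered unit vector
v = (x − x̄) / ‖x − x̄‖, so that only the *pattern* of a peak across
samples matters, not its absolute intensity (scaling the input leaves v
unchanged).  The replicate noise of a peak is the pooled duplicate-pair
variance, mean over samples of (rep1 − rep2)²/2, mapped onto the
normalized scale by the squared normalization factor.  Constant-vector
peaks cannot be normalized and are excluded from clustering with a
warning.

## Candidate alias search

A peak at apparent m/z M may alias a peak near M/z (charge states
z = 2, 3), near z·M (aggregates), or near M under another acquisition
condition.  Charge states above 3 are too faint to identify reliably in
complex-mixture spectra and are not searched (`max_multiple`,
configurable).  Matches are accepted inside a window centered at the
*expected* mass whose total width is a percentage of that mass:

| mass range (Da)   | window (% of mass) |
|-------------------|--------------------|
| 2,000 – 10,000    | 0.1                |
| 10,000 – 30,000   | 0.15               |
| 30,000 – 100,000  | 0.5                |
| > 100,000         | 1.0                |

These defaults reflect the calibration behavior of the SELDI instrument
class this tool targets and are overridable via a window-table file.
The published bin table this follows leaves 70,000–100,000 Da
unassigned while listing a 75.1 kDa protein under the 0.5% row, so the
0.5% bin is extended to 100,000 Da; masses above 200,000 reuse the 1%
bin.  Peaks below 2,000 Da are excluded from the search.  Reported
window bounds are rounded half-to-even to whole Daltons (66,000 at
z = 2 → 32,918–33,082); membership tests use the unrounded floats.

Candidates are generated in four steps of widening scope — (1) within
one (fraction, surface, energy) condition, integer multiples only;
(2) across energies on one surface in one fraction; (3) across surfaces
within a fraction; (4) across fractions — with steps 2–4 testing both
same-mass (multiple 1) and integer-multiple relations.  The scopes
partition all peak pairs, so no pair is tested twice; steps without
applicable condition diversity are skipped (an unfractionated
single-surface study finishes after steps 1–2).

## Ratio CV test

For a candidate pair the per-sample ratio of replicate-mean intensities
is formed, oriented so the denominator is the vector with the larger
grand mean (tie: the lower-mass peak) to keep the denominator away from
zero.  Samples whose denominator is below 1e-9 of its maximum are
excluded; if more than 20% of samples are excluded, or fewer than 3
remain, or the mean ratio is non-positive, the pair is rejected
outright.  Otherwise the pair passes iff sd(ratios, n−1) / mean(ratios)
is strictly below the threshold.  The threshold is the single stringency
dial of the method: there is no "correct" value, and the cluster count
as a function of threshold (the `sweep` subcommand) is the recommended
way to choose one.

Clusters are the connected components (size ≥ 2) of the passing-pair
graph, i.e. single linkage.  The published description speaks of peaks
being "added to clusters" step by step without defining a peak-vs-cluster
test statistic; connected components over pairwise passes are the
order-independent, deterministic reading of that procedure, at the cost
of possible chaining.  Clusters are ordered by smallest member mass and
labelled `cluster_001`, `cluster_002`, …

## Centroids and member weights

A cluster's centroid starts from the inverse-noise-weighted average of
the member vectors, then applies exactly two refinement passes of

    w_i ∝ 1 / (noise_var_i + ‖v_i − c‖²),   c = Σ w_i v_i  (re-centered,
                                                 re-normalized)

so a member's weight reflects its *total* variance about the cluster:
replicate-measurement noise plus lack of fit to the consensus pattern.
For mutually proportional members the lack-of-fit term is exactly zero
and the weights reduce to classical inverse-variance weights (noise
(σ²₁, σ²₂) = (1, 3) → weights (0.75, 0.25)).  The lack-of-fit term is
what makes the weights sensitive to a member that merely rides along:
scrambling the sample identities of one member of a tight cluster leaves
its replicate noise unchanged (pairs travel together) but drives
‖v − c‖² toward 2, collapsing its weight by roughly two orders of
magnitude — pure inverse-replicate-noise weights are mathematically
invariant under such scrambling and cannot show this diagnostic
behavior.  Two passes are used, not a fixed-point iteration: the first
pass purges ill-fitting members from the provisional centroid, the
second measures misfit against the cleaned centroid; iterating further
progressively concentrates weight on the single best-fitting member
whenever replicate noise is small relative to member-to-member
deviations, which is not the intent.  Noise variances are floored at
1e-12 when inverted.  A zero-norm weighted sum (exactly anticorrelated
members) dissolves the cluster with a warning.

Outputs: (1) a cluster report — one row per member with its weight
(summing to 1 within each cluster), average replicate variance, and,
when the design has groups, the informational per-group ratio CV of each
member against the cluster's highest-weight member (groups with < 3
samples are marked unavailable; these values never influence
clustering); (2) a feature-by-sample centroid table (cluster centroids
plus the unit vectors of unclustered peaks); and (3) the pre-clustering
normalized table.  Feature conservation holds on every run:
features out = peaks in − peaks clustered + clusters.

## Downstream statistics

Features are tested per row with the two-sided Mann–Whitney U test
(exact enumeration when n₁+n₂ ≤ 12 and untied, otherwise the normal
approximation with tie and continuity corrections; constant data gives
p = 1) and corrected with Benjamini–Hochberg across the whole feature
family ("global" FDR).  A permutation utility reports the mean number of
FDR discoveries over random group-label permutations.  Bookkeeping maps
significant features back to original peaks: peaks inside significant
clusters plus significant unclustered peaks.

## Synthetic data

The generator emulates the table shape of a duplicate-measurement
discovery study.  Defaults: 45 samples in two groups, three laser
energies on one surface (unfractionated), protein masses log-uniform in
7–160 kDa, log-normal abundances across samples (σ = 1 on the log
scale — large biological spread is what keeps independent proteins from
passing the ratio test), a 1.5× multiplicative group effect on 20% of
proteins, 5% multiplicative alias noise and 5% replicate noise, no
missing cells.  A planting plan assigns each protein z = 2 / z = 3 /
cross-energy same-mass aliases (alias intensity = parent abundance ×
constant attenuation × log-normal noise; alias mass jittered within 30%
of the search half-window); the ground-truth pair list is returned with
the table.  Randomization utilities permute a peak's duplicate pairs
across samples (optionally within groups), with per-peak generators
derived from (master seed, peak index) so single-peak and all-peak
randomizations agree.

What the generator does **not** emulate: mass-calibration drift between
spectra, intensity-dependent detection (censoring) of missing values,
correlated biological covariation between distinct proteins, and
saturation effects.  Passing the planted-recovery suites therefore shows
the algorithm's correctness under multiplicative noise, not its field
performance on any particular instrument.

## Problem sizes and determinism

The test suites run at desk scale — hundreds of peaks, tens of samples,
50-seed stochastic aggregates — which is where the method's statistical
behaviors (threshold monotonicity, planted-pair recovery ≥ 95%, weight
collapse under identity scrambling, null FDR behavior under full
randomization) are already clearly expressed.  All randomness flows from
explicit integer seeds; identical config + seed produces byte-identical
output files.
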
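# Methods

This note documents the models and procedures implemented in `diffenh`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for reproducibility.

## Window grids

Windows are 1500 bp placed every 500 bp (`window_len`, `shift`), so each
locus is covered by up to three overlapping windows; the window length
follows the typical size of experimentally validated enhancers, and the
2/3 overlap gives merging enough resolution to delimit call boundaries.
Coordinates are 0-based half-open everywhere internally; GTF (1-based
closed) is converted on read and BED is written natively.

*Intergenic* windows exclude any window overlapping a gene body by ≥ 1 bp
and any window closer than `tss_excl = 500` bp to a TSS. Distance from a
TSS *t* to a window [s, e) is the edge gap: 0 if s ≤ t < e, else s − t to
the left and t − e to the right. (The asymmetry — `t − e` rather than
`t − (e−1)` — matches the convention used throughout for interval-to-point
distances.) *Intragenic* windows lie fully inside the host gene, start
`first_tss_offset = 500` bp downstream of the first TSS in gene
orientation, and exclude windows overlapping ±1 kb (`internal_tss_flank`)
around internal alternative TSSs. Both flank sizes are configuration
parameters because "a region around the TSS" admits several readings; the
defaults take ±1 kb (2 kb total).

Randomized-position controls conserve the number of regions and the exact
length multiset. Intergenic randoms stay ≥ 500 bp from any gene span and
avoid assembly gaps (runs of ≥ 50 N when a genome is supplied) and each
other; intragenic randoms stay inside the same host gene and avoid internal
TSS flanks. Placement is rejection sampling with a 1000-try budget per
region, deterministic per seed.

## Relative enrichment

Counting: a mapped primary read increments every window its interval
overlaps by ≥ 1 bp; overlapping windows deliberately share reads. GC is the
G+C fraction of the window with N in the denominator; windows over 50 % N
are flagged.

Normalization has two stages. (1) Within each sample, windows are split
into 10 equal-occupancy GC strata and each stratum is full-quantile mapped
onto the sample's overall count distribution, removing the count–GC trend.
(2) Across samples, classic full-quantile normalization: each sample's
values are replaced, by rank, with the across-sample mean of sorted
vectors. Ranks are ordinal (stable, first-occurrence tie-break), which
makes stage 2 *exactly* idempotent in distribution: after it, every
sample's sorted vector is bit-identical. With average-rank ties that
invariant would fail for the large zero-count blocks typical of window
counts, which is why ordinal ranks are used.

The differential statistic is an MA-scale z-score. For condition vectors a,
b (replicate means per condition; with equal replicate counts the log-ratio
M is identical to using sums, but the mean keeps the abundance A on the
same scale as the single-replicate calibration pairs):

* M = log2((a+c)/(b+c)), A = ½ log2((a+c)(b+c)), pseudocount c = 1;
* the null of M given A is estimated from replicate-vs-replicate
  comparisons pooled over conditions, in ≤ 100 equal-occupancy A bins of
  ≥ 50 points (sparse tail merged), per-bin mean μ and sd σ floored at 1e−6;
* z = (M − μ_bin(A))/σ_bin(A), with out-of-range A assigned to the nearest
  bin. Positive z = enrichment in condition A.

Datasets without replicates get pseudo-replicates by splitting the pooled
(normalized, rounded) counts binomially with p = 0.5 per window —
conservation rep1 + rep2 = pooled holds exactly. One-tailed normal
p-values convert z to significance calls; the `left` tail tests enrichment
in condition A (p = 1 − Φ(z)), `right` the opposite, and the two tails sum
to 1. The same enrichment operation applied to RNA-seq or DNase counts over
called enhancer intervals yields the eRNA / open-chromatin association
analyses.

## Feature selection

The wrapper is an all-relevant ("shadow feature") selector: at each
iteration every candidate attribute gets one permuted shadow copy, a forest
regressor is fitted to the correlation class (a proxy mark's z minus the
Input z; both columns withheld from the candidates), and an attribute
scores a hit when its impurity importance exceeds the best shadow.
Accept/reject decisions use a two-sided binomial test (p = 0.5) at
α = 0.01, attempted from iteration 5; rejected attributes leave the design.
The forest is `ExtraTreesRegressor(100 trees, max_depth 5,
max_features="sqrt")`: split-candidate subsampling is essential — with all
features available at every split the shadows are never used and
chance correlations of noise attributes systematically outrank the shadow
null; it also makes the 10-run × 2-class protocol affordable on one CPU.
Any sklearn regressor exposing `feature_importances_` can be substituted.

The protocol repeats each analysis 10 times on random 5000-window subsets.
The final predictor set requires, in every report in which an attribute is
a candidate: acceptance in ≥ 60 % of runs *and* mean importance above every
negative control (the non-specific-antibody Control and H4K20me1). A
correlation-class proxy is withheld from its own report and qualifies
through the other, mirroring the practice of adding the proxies back to the
final set. The 7-mark activation preset ships for pipelines that skip
selection.

## Mixture model

The chromatin-state classifier is a finite Gaussian mixture over the
selected attribute z-scores, fitted by EM to a seed of 15,000 intergenic
windows. Defaults: k-means++ initialization, 2 restarts, tolerance 1e−4,
≤ 300 iterations — chosen so a full K = 1..9 scan of a 15,000 × 7 seed
takes seconds without changing the selected model on well-separated data.
BIC is reported as 2 log L − p log n (larger is better).

Model selection defaults to **argmax BIC** (the standard finite-mixture
criterion). A "smallest K before the BIC plateau" elbow rule
(`k_selection="elbow"`, threshold 5 % of the BIC range) is also provided,
but it is fragile when the background is heavy-tailed: the K = 1→2
improvement (modeling kurtosis) can dominate the range so strongly that the
genuine gain from two small, well-separated enhancer classes falls under
the relative threshold, selecting a K = 2 model that splits the background
and misses both classes — argmax BIC selects K = 3 in exactly those cases.
`force_k` overrides selection entirely.

Covariances are unconstrained ("full") by default. The constrained family
with per-component volume and orientation but a shared eigenvalue shape
(`covariance="vev"`: Σ_k = λ_k D_k A D_kᵀ, det A = 1) is available behind a
flag; its M-step alternates the shared shape A and scales λ_k to a 1e−4
fixed point, initialized from the best full fit. The first constrained step
may reduce the likelihood relative to the unconstrained initializer (a
model-family switch); within the family EM is monotone.

Components are labeled by the mean of their centroid over the activation
marks: highest → active, lowest → silent, remainder → no-change (ties break
on the H3K27ac coordinate; a warning fires when all centroids are near
zero). Classification takes per-window component posteriors from the
fitted mixture; the class posterior sums the responsibilities of components
sharing the argmax component's label. Retained predictions are active or
silent windows with posterior strictly above 0.95.

## Calls, linking, splicing

Retained windows of the same class and context merge when consecutive
windows overlap by ≥ 1 bp (abutting windows never merge: two loci 500 bp
apart on the grid stay separate unless a shared window bridges them); calls
carry window provenance, counts and posterior statistics, and calls longer
than 5 kb are discarded (strictly; a 5000-bp call is kept).

Nearest-TSS linking measures the edge gap from call to TSS (0 inside),
takes the globally nearest TSS with ties toward the smaller gene id, and
keeps links with 2 kb ≤ d ≤ 100 kb. Interaction-based linking requires
≥ 3 ChIA-PET pairs with one anchor on the call and the other in TSS ± 1 kb
for any TSS of the gene; pairs with both anchors on the call do not count.
Alternative-transcription events are consecutive TSS pairs per gene
separated by > 20 kb; attached enhancers lie strictly between the pair and
≥ 1 kb from each TSS, and events of genes with an intergenic call within
100 kb upstream (strand-resolved) of the first TSS are vetoed. RNAPII
activity at each TSS is the enrichment z of a 1500-bp window centered on it,
computed through the identical enrichment path. The gene-level association
between enhancer presence and splicing regulation is a two-sided Fisher
exact test on the 2×2 gene table.

Cassette exons are triples E1–E2–E3 where one isoform supports the
inclusion junctions and another isoform of the same gene the skipping
junction with identical outer boundaries; events are deduplicated by
junction triple and events whose spans overlap are all discarded. Only
exon skipping is extracted — "does not overlap any other event" is
enforced over skipping events, a deliberately narrower catalog than a full
event taxonomy. PSI uses junction reads only (so enhancer-derived RNA
overlapping an event cannot leak into the estimate), is undefined below 20
junction reads, and condition comparisons pair replicates by index.

## Synthetic data

The generator emulates exactly the data model the pipeline consumes:

* genome: random sequence, GC varying sinusoidally between 0.35 and 0.65
  along each chromosome (10-kb blocks);
* annotation: non-overlapping genes of 60–100 kb with 1–3 TSSs (two-TSS
  genes separated by > 20 kb, third TSSs closer so the separation filter is
  exercised), ~40 % of genes carrying one inclusion/skipping isoform pair;
* counts: negative-binomial background (dispersion 0.1 — so the σ
  calibration is exercised beyond the Poisson case) with mean
  `depth · exp(gc_bias · standardized GC)`, depth 30 per replicate, two
  replicates per condition, for the 7 activation marks plus Input and
  Control;
* plants: 200 active and 200 silent enhancer intervals of 2500 bp on the
  window grid, ≥ 1.5 kb from genes and ≥ 1 kb apart. At active loci the
  condition-A mean of every activation mark is scaled by a fold chosen so
  the *pipeline's measured* mean z equals the requested effect (default
  +3; silent loci scale condition B). Because between-sample quantile
  normalization compresses extreme values, a closed-form fold overshoots by
  ~15 %; the generator therefore calibrates the fold by a two-step
  fixed-point iteration on a 6000-window dry run of the actual
  normalization + calibration + z pipeline. Input and Control carry no
  effect;
* interactions and junctions: each planted enhancer–gene link receives
  exactly `link_support = 4` anchor pairs (so thresholds 3 and 5 bracket
  it); junction counts are binomial around the planted per-condition PSI
  at `junction_depth = 50`.

What the generator does **not** emulate: read-level error and mappability,
fragment-size effects, copy-number and chromatin-domain structure,
correlated mark backgrounds (marks are conditionally independent given GC),
biological replicate variability beyond counting noise, and eRNA
transcription. Passing recovery tests therefore demonstrates the
correctness and internal consistency of the statistical machinery under
its stated assumptions — not performance on real ENCODE-scale data, where
effect sizes are heterogeneous and the background correlation structure is
richer.

## Experiment sizes and statistical power

The packaged experiments (`diffenh.experiments`, also run by
`scripts/acceptance.py`) use: a 2 × 10 Mb genome (~24,000 intergenic
windows) for end-to-end recovery; 20 repetitions of the 15,000 × 7 seed for
model selection; 10 repetitions × 2 correlation classes × 10 runs on a
2000-window fixture with a 20-iteration cap for feature-selection recovery
(informative/noise decisions resolve within ~15 iterations; the cap only
truncates marginal chance-correlated stragglers that remain tentative
under the shadow null); and 300 events for splicing recovery.

The splicing experiment uses junction depth 1500 rather than the
generator's default 50. This is a pre-hoc power choice: the unchanged label
requires |ΔPSI| < 0.05 in *all* replicate pairings, and the binomial
sampling noise of PSI at depth n gives sd(ΔPSI) ≈ √(2·PSI(1−PSI)/n) — at
depth 50 that is ≈ 0.10, so a true-null event satisfies the criterion with
probability ~0.15 regardless of implementation; at depth 1500 (sd ≈ 0.018)
label errors reflect the plant, not counting noise.

## Known limitations

* The enrichment statistic is a reconstruction of the
  replicate-calibrated MA z-score idea (pseudocount, bin counts and σ floor
  are configuration values), not a port of any specific tool.
* The intergenic definition is the strict reading (outside all gene spans
  *and* ≥ 500 bp from all TSSs).
* Merging is per class and, for intragenic windows, per host gene; nested
  genes therefore yield per-gene calls.
* ChIA-PET replicates are pooled before the ≥ 3-pair threshold.
* The linking step is O(pairs × calls) and intended for call-scale inputs,
  not raw genome-wide interaction catalogs.
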
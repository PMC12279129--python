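# Methods

This note documents the statistical model, the decisions taken where the
procedure left latitude, what the synthetic generator does and does not
emulate, and the known limitations.

## The detection problem

A GBS library samples a genome at tag sites — discrete loci adjacent to
restriction sites — at low coverage. A drive haplotype spans tens of
megabases (Ab10 ≈ tens of Mb at the end of chromosome 10; the B chromosome
≈ 150 Mb), so a carrier has reads at hundreds of tag sites that a
non-carrier lacks. The detector aggregates that signal per 1 Mb bin and asks
a clustering question — does this sample look like the positive or the
negative controls? — rather than a genotyping question at any single locus.

## Ingest filters

* **Replicate merge.** Technical replicates are summed per biological
  individual before any normalization.
* **Missingness** of a sample is the fraction of tag sites with zero raw
  reads. Zero-count is the only observable notion of "missing" at the
  count-table level.
* **Blank cutoff.** Blank (no-DNA) lanes measure sequencing background; the
  sample cutoff is min(blank missingness) − 0.001, and samples with *more*
  missing data than the cutoff (strict >) are removed. Without blanks the
  caller requires an explicit cutoff rather than guessing one.
* **MAPQ.** Tags with mapping quality < 20 are removed. Missingness is
  computed on the pre-filter tag set (sample filter first, then tag filter);
  the two orders give the same surviving samples whenever blanks and samples
  are affected proportionately, and the fixed order makes runs reproducible.
* **RPM.** Reads-per-million is computed per sample after filtering; a
  zero-read sample stays all-zero and is flagged rather than dropped
  silently.
* A per-group missingness report is logged so datasets from different
  sequencing providers can be compared; it never gates execution.

## Tag index

`index = sqrt(c) + d` per sample per 1 Mb bin, where `c` counts the bin's
tag sites observed in that sample (depth > 0) and `d` sums their RPM depth.
`c` must be sample-varying: a reference-fixed tag count would make `sqrt(c)`
a constant column offset carrying no presence information. `d` uses RPM, not
raw counts, so library size cancels. Tags are assigned to bins by start
coordinate (half-open bins make ties impossible); the last bin of a region
may be shorter than 1 Mb.

Min/max scaling is per bin (feature) across samples, recomputed inside each
clustering batch over exactly the batch's members, so every k-means run sees
features on [0, 1] regardless of batch composition. Constant bins scale to 0
rather than NaN.

## Iterative k-means calling

* **Diagnostic bins**: bins whose scaled-index class means differ by ≥ 0.5
  between positive and negative controls. Selection runs **per copy
  stratum**: scaling over a pooled control set that spans 1–8 copies
  compresses the low-copy mean toward the negatives and can hide bins that
  separate perfectly within a stratum. Each stratum's clustering runs on its
  own bin set; a user-supplied BED of diagnostic intervals overrides
  selection.
* **Batches.** Controls are class-balanced by downsampling the larger class
  to within 20% of the smaller. Experimental samples are randomly
  partitioned each round into batches of at most `spike_fraction` × the
  balanced control count (25% for Ab10/K10L2, 10% for B), so controls always
  dominate the clustering.
* **Naming and verification.** k = 2 clusters are named positive/negative
  when ≥ 80% of their *controls* (spikes never count) share a class; a batch
  is redrawn (fresh control subsample, fresh k-means seeding) until every
  control lands in the cluster matching its truth, with a retry ceiling of
  50 after which the batch is abandoned and its samples uncalled for that
  round.
* **Consensus.** 125 rounds; final call = majority class iff its fraction of
  completed rounds ≥ 95%, else ambiguous. Rounds lost to abandoned batches
  leave the denominator; a sample completing under half its rounds is
  ambiguous with a flag. Exactly 80% purity and exactly 95% agreement count
  as passing ("at least").
* **Strata.** High-copy (homozygous, or visually high-copy B) and low-copy
  controls run separately so clusters reflect presence, not dosage. For
  Ab10/K10L2 the stratum results combine by union: positive if either
  stratum is positive, negative if both are negative, else ambiguous.
* **Stepwise orders.** Ab10 runs first; only Ab10-*negative* samples enter
  the K10L2 stage (the K10L2 features cannot distinguish Ab10 from K10L2, so
  the order enforces exclusivity; ambiguous Ab10 samples are not forwarded).
  The B pipeline runs high-copy controls first and sends stage-1
  non-positives to the low-copy stage; positives are the union.
* **k-means details** (unspecified by the protocol): k-means++ seeding, 10
  restarts, Euclidean distance on scaled diagnostic bins, best inertia wins.
  The inner solver is a small vectorized Lloyd iteration — the pipelines run
  on the order of 10^5 clustering problems of a few dozen samples each, and
  the tests verify its partitions against scikit-learn's KMeans on random
  fixtures.
* **Control validation** repeats the naming step on controls alone: 3 random
  groups (redrawn when a group misses a class), 100 repetitions, per-control
  accuracy reported. When a class cannot supply at least two controls per
  group the controls are clustered as a single group instead — subsampling a
  handful of low-copy positives into thirds leaves single controls that can
  be absorbed by the wrong cluster, which is exactly why small control sets
  are validated whole.
* **RNG**: one master seed; all draws flow from one generator, so identical
  inputs and seed reproduce identical calls bit for bit.

## Copy number

The baseline is the mean tag index across 1 Mb bins of **concatenated
single-copy core-gene sequence** (gene space, not genomic coordinates):
genes are laid end to end and tags map by offset within their gene. The
relative index = mean diagnostic-bin index / baseline cancels library size
exactly (both terms are RPM of the same sample).

Calibration is two-point: increment Δ = median(2-copy controls) −
median(1-copy controls); offset = median(1-copy) − Δ; copies =
round((value − offset)/Δ), ties-to-even, clipped at 0, capped at 2 for
Ab10/K10L2 (reported as homozygous) and uncapped for B. Medians are used
because control strata are small. When no known-copy controls exist (the
realistic B situation), the increment falls back to the low-stratum median
with zero offset and a warning — estimates are then approximate one-copy
increments, which is how they should be read. The raw ratio is always
reported alongside the integerization.

## Ab10 typing

Random forest (500 trees, sqrt-features per split, seedable) on the scaled
tag index over the Ab10 region; stratified 70/30 train/test split (every
type needs ≥ 2 controls); held-out accuracy reported with the model. A
sample is typed only when ≥ 65% of trees agree, else ambiguous — raising the
threshold can only shrink the typed set. Mean-decrease-Gini ranks the bins;
the PCA of the top bins (default 20) uses those features only.

## Synthetic data generator

Counts are Poisson: `count[t,s] ~ Pois(lib_s · depth · w_t · rate(t,s))`
with per-tag efficiency `w_t ~ Gamma(4, 1/4)` (mean 1), log-normal library
factors (σ = 0.4), and `rate` = local dosage + background:

* normal-genome, core-gene and shared-homology tags: dosage 2 in every
  sample;
* haplotype-specific tags: dosage = copy number × `signal`, with Ab10
  cytological types encoded as per-bin dosage profiles (a common block
  carried by all types plus one block private to each type);
* Ab10 copies also dose the K10L2-specific tags one-for-one
  (`cross_homology = 1`), reproducing the confusion that motivates the
  stepwise order;
* every specific tag carries a small cross-mapping background
  (2 × 0.02 dosage equivalents) in all samples;
* blanks draw from a residual rate of 0.002;
* haplotype-specific tags yield 0.4× the reads of normal tags
  (`specific_weight`): the haplotypes are repetitive and poorly conserved,
  so far fewer reads align per Mb than in gene space. This is also why
  relative indices are fractional (≈ 0.2 per copy), and it keeps the
  library share of a many-copy B realistic — without it a 7-copy B soaks up
  enough of the library to depress the RPM depth of everything else and can
  flip co-occurring calls.

Default scale: two normal chromosomes (40 + 20 Mb, with 9 Mb of core-gene
space), Ab10 24 Mb (4 shared bins), K10L2 12 Mb (2 shared), B 16 Mb
(1 shared), 40 tags/Mb, mean 4 reads per tag per copy, 10% of tags with
MAPQ < 20. The default control panel mirrors a realistic design: 49 Ab10
(three types, 12 homozygous), 13 K10L2 (5 homozygous), 18 B (13 high-copy at
4–8 copies, 5 low-copy at 1–2 — deliberately too few to subsample, so
validation clusters them as one group), 18 negatives, 3 blanks. The `signal`
parameter is the effect-size dial: 1.0 ("strong") reproduces the stark
control contrast of real panels; the "hard" preset (0.05) sits near the
cross-mapping background.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence-level artifacts (restriction-site
polymorphism, GC bias, barcode bleed), population structure among samples,
recombinant or diverged haplotypes beyond the three fixed type profiles,
batch effects between sequencing providers, and reference errors. The
simulator validates the calling machinery under its stated count model, not
the biology of any particular panel.

## Numerical choices and degenerate inputs

Threshold comparisons use a 1e-12 tolerance so exact boundary fractions
(4/5, 19/20) pass "at least" rules under floating point. Empty clusters
during Lloyd iteration are re-seeded at the point farthest from the other
centroid. A batch of identical points gets a single cluster label. Zero-read
samples keep all-zero RPM columns; zero baselines make the relative index
NaN with a flag rather than infinite. Constant features scale to 0.
Problem sizes in the test suite and the acceptance script (500-sample
cohort, 125 rounds, 100 validation repetitions, 5 panels) match the study
design the defaults encode.

## Known limitations

* The K10L2 stage inherits Ab10's ambiguity: samples ambiguous for Ab10 are
  never forwarded and stay unresolved for K10L2 by construction.
* B copy estimates without known-copy controls are approximate increments,
  not counts.
* The recombinant-haplotype space is open-ended: the typing forest can only
  vote among the trained types, and genuinely intermediate profiles are
  (correctly) ambiguous rather than identified as recombinant.
* Diagnostic-bin selection assumes ≥ 2 positive and ≥ 2 negative controls
  per stratum and fails loudly otherwise.
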
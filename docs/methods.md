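# Methods

## Model and procedure

`epmotif` models an enhancer–promoter (EP) interaction landscape as a
binned, normalized, intra-chromosomal contact matrix plus interval
annotations, and motif biology as position weight matrices (PWMs) scanned
over the region sequences. The pipeline has five stages; each is a pure
function of its inputs and the run seed.

### EP-pair calling

Bin pairs are *interacting* when their normalized contact value is
**strictly greater than 30** (150 for libraries an order of magnitude
deeper, where the same quantile of the contact distribution sits higher),
and *non-interacting* when the value is **strictly less than 5**, with bin
pairs absent from the sparse dump counting as zero. Annotated EP pairs are
formed by ≥ 1 bp overlap of an active enhancer with one bin and an active
promoter with the other bin of a selected bin pair, with the distance
filter 2.5 kb ≤ d ≤ 2 Mb. Choices that were genuinely open:

- **Coordinates** are 0-based half-open throughout (BED convention).
- **Promoter window**: 1000 bp upstream to 100 bp downstream of the TSS.
  The window is mirrored on minus-strand genes so "upstream" is biological
  upstream; `promoter_ignore_strand` restores the unstranded reading.
- **Distance** is enhancer midpoint to TSS (configurable to edge-to-edge).
  The TSS is recovered from the promoter window shape and clamped inside
  the interval for clipped windows.
- **Contact value of an EP pair** supported by several bin pairs is the
  maximum (most confident evidence).
- Activity calling (e.g. H3K27ac overlap for enhancers, expression for
  promoters) is accepted as input annotation, not recomputed.

### Motif scanning

The scanner computes, for every window on both strands, the log-odds score
Σᵢ log₂(p_b(i)/q_b) against the background composition q (default uniform).
Score-to-p-value conversion enumerates the exact PWM score distribution by
dynamic programming over positions at a granularity of **1/1000 bit**; the
documented tolerance against exact word enumeration is 1e-3 on p-values.
Windows containing N never match (masked content is tolerated, not
rejected). The default hit threshold is p < 1e-4, the common FIMO default.
Note a discreteness floor: a width-w PWM cannot produce p below 4⁻ʷ, so
width-4 motifs (floor ≈ 3.9e-3) never pass the default threshold.

### Motif similarity and redundancy removal

Similarity of two PWMs is the best mean per-column Pearson correlation over
all ungapped offsets with ≥ 4 overlapping columns, in both orientations.
The null model permutes columns within each motif; because a raw exceedance
fraction over n permutations is floored at 1/(n+1) — far above the 1e-5
(redundancy/annotation) and 1e-8 (cross-condition sharing) working cutoffs
— the p-value is calibrated parametrically: the observed mean over the L
aligned columns is referred to a Gaussian with the null's per-column mean
and sd/√L. This E-value is a calibrated score, not a replication of any
external tool's statistic; the two cutoffs are configuration, and both are
exposed as parameters. Note the attainable depth grows with overlap width
(z ∝ √L): identical width-10 motifs sit near 1e-7–1e-8, so the strict
cross-condition sharing cutoff of 1e-8 only bites for wide,
information-rich motifs; identical motif names short-circuit as shared.
Redundancy removal single-links motifs under the cutoff and keeps the
lexicographically smallest name per cluster (deterministic).

### Module and pair discovery

Each EP pair contributes a presence profile (motifs with ≥ 1 hit in the
enhancer; likewise for the promoter). Modules of 2–5 motifs are enumerated
level-wise (Apriori) with anti-monotone pruning at support ≥ 30 — the
support floor also used when reporting pairs — and tested against
λ_module = N·Π(member marginal frequency) with a Poisson upper tail,
Bonferroni-corrected at 0.01. For each oriented pair within a module, with
a of N enhancers carrying the enhancer-side motif and b of N promoters the
promoter-side motif, the observed cross-region support k is referred to
P(X ≥ k), X ~ Poisson(**λ = a·b/N**): the expectation under independence
of the two region-wise presences. This rate parameterization is the
package's reconstruction of the Poisson-clumping approach for co-occurring
words; the approximation is conservative-to-accurate in the regime tested
(marginals well below N, support ≥ 30; the null-calibration test bounds
the raw false-positive rate at ≤ 2α). The two orientations of a pair are
separate hypotheses; both count toward the Bonferroni denominator, which
is the number of oriented pairs actually carried to the test.
Benjamini–Hochberg is available as an alternative correction.

**Power caveat**: λ = a·b/N uses the *observed* marginals. When a planted
or real signal dominates both marginals (joint presence approaching the
marginal presence, e.g. a pair present in 90% of pairs), the independence
expectation tracks the signal and the test deliberately loses power — it
detects *excess* co-occurrence, not abundance. The classification stage is
therefore evaluated with the feature pairs supplied explicitly in the
strong-signal regime.

### Homogeneous, preference, and enrichment statistics

- **Homogeneous pairs** (same motif both sides): n of N EP pairs carry the
  motif in both regions. Variant 1 (length-aware) uses
  p = x/(N·(l₁+l₂)) with x the total occurrence count and l₁, l₂ the mean
  promoter and enhancer lengths *computed from the input annotation*;
  variant 2 (presence-based) uses p = x·y/N². Both use the exact binomial
  upper tail (inclusive of i = n) and the threshold **0.01/K** for K motifs
  tested. A success probability ≥ 1 is a degenerate input and an error,
  never clipped.
- **Preference**: binomial test on the split of a motif's hits between
  enhancers and promoters, with null probability 0.5 (count-only) or
  l₂/(l₁+l₂) (length-aware, longer regions absorb more hits).
- **Enrichment**: predicted motifs map to TFs through motif-library
  similarity (mode `all`: every TF under the 1e-5 cutoff; mode `best`:
  the argmin-E-value TF, ties lexicographic). With N database TFs and M
  interacting pairs, n predicted TFs define n(n−1)/2 drawn pairs and m
  database hits; the p-value is the exact hypergeometric upper tail.
  Direct-only and direct+indirect database modes are supported; TF names
  match case-insensitively with no alias resolution.

The binomial, Poisson and hypergeometric tails are evaluated through
scipy's survival functions (log-space internally); the test suite verifies
them against exact rational arithmetic (`fractions.Fraction`) and 50-digit
summation (sympy) to 1e-12 on all instances with N ≤ 30 / k ≤ 50.

### Negative controls

- **Type 1** shuffles each positive pair's sequences independently
  (mononucleotide permutation, composition conserved exactly; a
  dinucleotide-preserving walk is optional but not the default).
- **Type 2** keeps the promoter and replaces the enhancer with a random
  region of *identical length*, at a TSS distance resampled with
  replacement from the empirical positive distance distribution, rejected
  while overlapping the excluded regions (default: all enhancers and
  promoters). Up to 100 placement attempts per pair; > 10% skips is an
  error.
- **Type 3** re-runs EP-pair construction on bins with contact < 5.
  The natural class imbalance is preserved by default.

### Classification

Each EP pair is a 4n+1 vector: per motif pair, the occurrence counts
(both strands) of the enhancer-side motif in the enhancer and promoter and
of the promoter-side motif in each region, plus the label. The classifier
is L1-penalized logistic regression ("lasso" as a classifier), liblinear
solver, inverse-regularization C chosen from {0.01, 0.1, 1, 10} by an
inner stratified 3-fold grid on each training split, under stratified
10-fold outer cross-validation with a fixed seed. Metrics are precision,
recall and F1 of the positive class; the selected pairs come from a final
refit on all data. Counts are not standardized by default (they share a
scale); an optional standardization flag exists and changes the selected
set. Class ratios are preserved (no balancing before CV).

## Synthetic data generator

`synth.simulate` tiles a random i.i.d.-base genome into blocks of three
contact bins (default resolution 5 kb); each block hosts one enhancer
(bin 0) and one promoter window (bin 1), so every annotated candidate maps
to exactly one bin pair. Interacting blocks draw contact values from
U(40, 100) and non-interacting from U(0.5, 4.5): the 30/5 cutoffs separate
the classes by construction, which is what fixed-threshold calling
assumes. Default conditions: **500 EP pairs**, **300-bp enhancers** (so
the 1100-bp promoters are roughly three times longer, making the
length-aware tests behave realistically), background motif presence
**0.05 per region**, one planted oriented pair at joint probability
**0.4**, and a motif library of 8 information-rich width-8 PWMs (dominant
base 0.91). Planted sites are exact consensus (scan p ≪ 1e-4), decoupling
scanner sensitivity from discovery tests. The manifest records carriers,
interacting bins, and consensus strings as ground truth.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: distance-dependent contact decay, normalization
artifacts, nucleotide-composition heterogeneity (isochores, CpG islands),
repeat content, overlapping or nested regulatory elements, motif
self-overlap and clustering, and many-to-many EP topologies. Recovery
rates on bundles are statements about the statistics under the stated
generative model only.

## Problem sizes and determinism

The shipped tests run the discovery sweep at 500 EP pairs over 20 seeds
(planted and pure-null), the null calibration at N = 200 with 1000
replicates, and the classification regime at 400/400; the acceptance
script uses 10 seeds per sweep arm. These sizes give stable pass/fail
behavior for the stated thresholds on a single CPU. All randomness flows
from explicit seeds through `numpy.random.default_rng`; the full pipeline
writes byte-identical outputs on reruns with the same inputs and seed
(sorted outputs, fixed float formats, seeded folds).

## Known limitations

- The Poisson rate reconstruction (λ = a·b/N) and the correction family
  are design choices; other parameterizations of "expected co-occurrence"
  exist and are not implemented.
- The similarity E-value is a calibrated internal score; absolute values
  are not comparable with other tools' E-values, only the relative
  ordering and the configured cutoffs are meaningful.
- Only intra-chromosomal EP pairs are considered (implied by the distance
  bound).
- TF mapping has no alias/orthology resolution; unmapped motifs silently
  drop out of enrichment (with a logged count).
- Module support counts presence anywhere in the EP pair (either region);
  per-region support enters only at pair extraction.
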
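# Methods

This note documents the models implemented in `sucrophylo`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Alignment-free distances

**k-mer spectra.** A spectrum counts every width-k window over each contig;
windows containing any non-ACGT symbol are skipped entirely (masked repeats
in real assemblies appear as runs of N and must not contribute words).
Optionally each word is replaced by the lexicographic minimum of itself and
its reverse complement before counting (`canonical=True`). The default is
non-canonical counting, appropriate for genome collections scaffolded into a
single reference orientation; the canonical mode exists for unoriented
assemblies, and the background model is strand-symmetrised accordingly
(p(w) + p(rc(w)) unless w is its own reverse complement).

**Choice of k.** The unique-k-mer fraction — distinct words seen exactly
once divided by all distinct words — rises with k and plateaus once most
words are unique. `select_optimal_k` returns the smallest k whose increase
to k+1 is below `epsilon` (default 0.005, absolute) for *every* genome, a
scale-free formalisation of the saturation criterion. The fraction is
defined over distinct words (not windows) so it is invariant to genome
length. If no plateau occurs before `k_max` the largest k is returned with
a warning flag rather than an error, since the curve is monotone enough in
practice that the caller can widen the range.

**D2S.** For genomes X, Y with counts X_w over n_X windows, the expected
count of w is n_X·p_X(w) with p_X(w) the product of single-nucleotide
frequencies (order-0 background). The similarity is

    Σ_w X̃_w Ỹ_w / √(X̃_w² + Ỹ_w²),    X̃_w = X_w − n_X p_X(w),

summed over the union of words observed in either genome; terms with zero
denominator contribute 0. Summing over the union — not all 4^k words — is
a deliberate definition, matching counter-based implementations and keeping
k = 21 tractable: the excluded words would contribute products of two
negative expectations. The test suite pins the union-rule value against a
word-by-word enumeration oracle and documents that the all-words variant
genuinely differs when not all words are observed.

**Distance.** d(X,Y) = −ln r with r = S(X,Y)/√(S(X,X)·S(Y,Y)); r ≥ 1 maps
to distance 0 and r ≤ 1e-12 is floored (keeping distances finite for
neighbor joining; the floor corresponds to distance ≈ 27.6, far beyond any
within-species signal). Non-positive self-similarity raises an error — it
signals a degenerate input such as a genome shorter than k. This transform
satisfies d(X,X) = 0, symmetry and monotone decrease in similarity, which
the tests assert directly; it is a documented choice of normalisation, not
a claim about any particular antecedent implementation.

## Trees and support

**Neighbor joining** is the classic O(n³) agglomeration with the
rate-corrected criterion Q_ij = (n−2)d_ij − r_i − r_j, standard two-point
branch lengths, and two explicit conventions: ties break toward the
smallest (row, column) index pair in the current label order (determinism
under rerun and label permutation is tested), and negative branch-length
estimates are clamped to zero (keeps Newick valid; arises only on
non-additive inputs). On additive matrices NJ is exact; the suite verifies
topology and branch lengths to 1e-9 on 50 random binary trees of up to 12
taxa, and cross-checks topology against scikit-bio's implementation.

**Rooting and monophyly.** Outgroup rooting bisects the edge subtending the
outgroup clade (a single tip always qualifies); an outgroup that is not a
clade in the unrooted tree is an error naming the offending set. A taxon
set is monophyletic iff it is exactly the leaf set of some node in the
rooted tree; singleton sets are trivially monophyletic.

**Jackknife support.** Each pseudo-replicate deletes
⌊fraction·contig_length/fragment⌋ non-overlapping fragments (default 40%,
100 bp) per contig at uniformly sampled positions (rejection sampling with
1000 retries per fragment), splices the remainder, and recomputes spectra,
distances and the NJ tree. Deletion is per contig so the deleted fraction
is exact to within one fragment per contig and no splice joins material
across contigs. Support of a reference-tree node is the percentage of
replicates whose tree contains its bipartition, rounded half-up to an
integer. Each (seed, replicate, contig) triple seeds an independent stream,
so replicates are reproducible individually. Display can suppress supports
below a floor (conventionally 70) without touching the stored values.

## Copy number from read depth

The estimator is deliberately simple: copy(f) = mean depth over the feature
interval (flanks excluded) / genome-wide mean depth. Flanks of at least
250 bp are required when building probe references because their role is to
let reads align completely at feature edges; they are never quantified.
Background is the mean (not median) over all positions, matching the
"average genome coverage" convention; a median option exists for
robustness to focal amplifications. The estimator assumes probed features
are a negligible fraction of the genome — that is what makes the
genome-wide mean a valid single-copy baseline — and the synthetic recovery
study respects this (10 kb of features in a 4 Mb genome).

Differential copy number subtracts reference-annotation copies; heatmap
export clips the display at +4 extra copies (entries beyond the clip are
flagged as an extreme class) while the underlying matrix keeps raw values.

Group differences use a two-sided Mann-Whitney U per feature: exact
enumeration when the combined tie-free sample is ≤ 12 (C(12,6) = 924 tables
is cheap), otherwise the normal approximation with tie and continuity
corrections. Strains with missing estimates are excluded pairwise, never
imputed. Pearson r (for validating depth-based against assembly-based
counts) reports a 95% CI via the Fisher z transform with quantile 1.959964.

## Presence/absence and enrichment

A feature is present in a strain iff at least one hit passes the identity
threshold — strictly greater than 70% by default, so 70.0 exactly fails —
and a query-coverage threshold (default 0.5, configurable; per-feature
search criteria are runtime parameters, not constants). Hits to either of
a feature's alternative alleles count (diploid heterozygosity); strains
with no hits are absent. Fisher's exact test uses the minimum-likelihood
two-sided convention: the p-value sums all tables with the observed margins
whose point probability does not exceed the observed one. The suite checks
this exhaustively against integer hypergeometric enumeration for all tables
with N ≤ 30 and on a seeded sample up to N ≤ 60. Reported percentages
round half away from zero at a configurable number of decimals (published
tables mix precisions value by value). No multiple-testing correction is
applied by default, matching the per-feature reporting convention; callers
can correct downstream.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical* structure the analyses assume:

- **Divergence**: Jukes–Cantor substitutions applied site-independently
  along each branch, with per-site substitution probability
  p_sub = (3/4)(1 − e^(−4d/3)) for branch length d (expected
  substitutions/site). JC is the minimal model under which NJ on exact
  distances is consistent, which is the property the pipeline tests need.
  No indels, rearrangements, repeats or introgression are simulated by
  default — so passing tests demonstrate signal recovery under clean
  divergence, not robustness to structural variation.
- **Coverage**: per-base depth ~ Poisson(λ·c), with c the regional true
  copy number (1 outside features). Real Illumina depth is over-dispersed
  and GC-biased; Poisson is the idealisation the normalised-mean estimator
  targets. Defaults: λ = 50 (typical short-read coverage in resequencing
  panels), 2 kb features.
- **Presence**: independent Bernoulli entries with group-specific
  probabilities (defaults 0.95 focal / 0.10 background, the order of
  magnitude of the published marker differentials; equal probabilities
  give the type-I calibration setting).

Truth (generating tree, per-feature copies, per-cell presence) is emitted
beside every dataset, enabling the parameter-recovery tests.

The standing two-clade study used by the end-to-end tests is 8+8 tips from
a 50 kb root (GC 0.38, the genome-wide composition of *S. cerevisiae*),
within-clade divergence 0.01 and between-clade 0.2 at k = 11, with 25
jackknife replicates. These sizes were chosen as the smallest at which the
clade signal is unambiguous per the expectation ordering of pairwise
differences; the real study's scale (197 genomes of ~12 Mb at k = 21, 100
replicates) is the same algorithm at larger n.

## Numerical conventions and degenerate inputs

- Words pack 2 bits/base into uint64 (k ≤ 31); spectra store sorted word
  arrays, and all pairwise algebra is vectorised set arithmetic.
- Distance matrices must be symmetric within 1e-9 with zero diagonal; they
  are symmetrised on construction. PHYLIP square output pads labels to 10
  characters (classic) or writes full labels (relaxed mode).
- Empty spectra, genomes with no ACGT bases, k exceeding every contig,
  zero-length features, zero-variance correlation inputs and empty test
  groups all raise informative errors rather than propagating NaN.
- Determinism: every stochastic routine takes an explicit integer seed and
  derives independent numpy Generator streams; identical configuration
  yields byte-identical output.

## Known limitations

- The order-0 background is the only expectation model; higher-order
  Markov backgrounds are out of scope.
- The copy-number estimator has no mappability or GC correction and no
  segmentation; it quantifies predefined probe features only.
- The built-in presence caller consumes externally produced hit tables;
  running the similarity search itself is out of scope.
- Jackknife supports assume the reference tree and replicates share the
  same taxon set; partial-taxon replicates are not supported.
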
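# Methods

## Coordinates and formats

All internal coordinates are 0-based, half-open, on the forward strand of
each species; conversions (1-based closed GFF3, MAF reverse-strand starts,
1-based VCF POS) happen only at format boundaries. Minus-strand MAF rows
are stored as forward-strand intervals plus a strand flag so interval
arithmetic is uniform everywhere. Alignment blocks missing one or more
non-reference species are kept for conservation scoring (missing data is
informative about nothing, but the present rows still are) and flagged;
only complete-profile blocks qualify as collinearity anchors.

## Phylogenetic models

Substitution models are reversible nucleotide rate matrices (JC, HKY,
GTR) normalized so −Σᵢ πᵢ Qᵢᵢ = 1; branch lengths are expected
substitutions per site. Column likelihoods use Felsenstein pruning with
per-node renormalization against underflow; gaps and ambiguity codes are
marginalized (partial vector of ones), never treated as a fifth state.

`fit_model` maximizes the summed column log-likelihood over log branch
lengths (bounds 10⁻⁶–20 substitutions/site) and family parameters (HKY κ;
five free GTR exchangeabilities, GT fixed at 1; π empirical) with
L-BFGS-B, `ftol` 10⁻⁸. A single fixed start can be trapped on the
saturation plateau — all branches at the stationary limit is a genuine
local optimum for highly diverged data — so the optimizer runs a
deterministic ladder of starts (0.1, 0.5, 1.5 per branch) and keeps the
best optimum. Fitting is exactly reproducible.

Neutral-model site classes come from the reference annotation only: a
third codon position is four-fold degenerate iff the reference codon's
amino acid is invariant to that position under the standard code; genes
whose summed CDS length is not a multiple of 3 are skipped with a
warning. For a rooted reversible model the two root-adjacent branch
lengths are identifiable only through their sum; symmetric truth and a
symmetric start keep the split symmetric in practice.

## Conservation HMM

The two-state phylo-HMM emits alignment columns under the neutral model
(scale 1) and a conserved model (all branches × ρ). Tuning follows the
standard coverage/length parameterization: μ = 1/ω, ν = γμ/(1−γ), initial
distribution (γ, 1−γ). Defaults γ = 0.2, ω = 80 bp are the values used for
plant clade scans; ρ defaults to 0.3 and can be re-estimated (below).

Chains run along the reference; a gap of even 1 bp between consecutive
blocks breaks the chain, because unaligned reference sequence carries no
evidence for either state, and each chain restarts at the stationary
distribution. Columns in which the reference row is gapped occupy no
reference position and are dropped. Columns with fewer than two
non-missing species get likelihood ratio 1 (posterior driven purely by
the transitions). Forward–backward runs in scaled linear space on the
emission *ratio* (the common neutral term cancels from posteriors);
segmentation uses Viterbi with ties broken toward the neutral state, so
"most-Cons" elements are discrete maximal conserved runs, not posterior
thresholdings. Element score is the summed per-column log-odds.

ρ estimation maximizes the HMM likelihood on a log-spaced grid followed
by golden-section refinement. The mixing weight γ is profiled out on a
grid alongside ρ by default: with γ fixed at a value far from the true
conserved coverage the ρ estimate is biased toward 1 (the conserved state
is forced to also explain neutral sites); joint profiling removes that
bias. ω stays fixed. Everything is deterministic.

Per-site scores: the branch scale s is profiled per column over a fixed
log grid (10⁻³–10, 81 points, 1 included exactly); the statistic
2(ℓ(ŝ) − ℓ(1)) is referred to the one-sided boundary null (½χ²₁ mixture);
score = −log₁₀p signed + for ŝ < 1, − for ŝ > 1, exactly 0 at the
boundary. This is a likelihood-ratio stand-in with the same ranking
behaviour as exact substitution-count tests, which is all the downstream
class table consumes; it is not a reimplementation of any published exact
method.

The region-class score table uses 14 default classes: CDS, intron, 5′UTR,
3′UTR, five upstream distance bins from the start codon
((−5000,−2000], (−2000,−1000], (−1000,−500], (−500,−100], (−100,0]) and
five mirrored downstream bins from the stop codon. Flanking-bin positions
overlapping any gene body are excluded; thresholds are global score
quantiles; empty classes report NaN, never 0. The bins are configurable.

## CNS filters

Elements are split by the merged CDS union; pieces pass with length
≥ 20 bp and aligned identity ≥ 80% (inclusive bounds — "minimal" reads as
inclusive). Identity is the column-weighted mean over non-reference
species of exact base matches; a species missing or gapped in a column
drops out of that column's denominator, since missing data is not
divergence. Element-mean identity was chosen over per-row minimums; the
aggregation is localized in one function if a different convention is
wanted. Context (intergenic / intron / UTR / upstream / downstream) is
assigned against the nearest gene within 5 kb.

## Collinearity

Complete-profile blocks become anchors, ranked by interval start per
species chromosome; tandem duplicates (identical reference interval) are
collapsed. Segments are maximal runs of anchors, scanned in reference
order, in which every species' ranks move strictly monotonically in one
per-species direction, per-step rank gaps are ≤ `max_rank_gap` (default
25), and the anchor's relative strand per species is constant — the
strand rule is what terminates segments exactly at inversion boundaries.
Runs need ≥ `q_min` = 3 anchors and must beat a closed-form randomness
bound: under uniform random rank placement each step lands within the gap
bound with chance ≤ g/(Mₛ−1) and matches the fixed direction with chance
½, multiplied over steps and non-reference species; the product must fall
below `p_cut` = 0.01. Anchors join at most one segment
(longest-run-first, ties to the leftmost reference start). This replaces
cloud-based clustering with a rule simple enough to verify against an
exhaustive brute-force oracle; the three parameters are config-exposed
because no canonical values exist for anchor-based (rather than
gene-based) markers. A short translocated run reinserts within the rank
gap tolerance at its destination, so only its source boundaries break
collinearity — the simulator's truth breakpoints record exactly those.

## cis-RCNEs and regulatory pairs

Containment ("covered by"), not mere overlap, promotes a CNS to a
cis-RCNE; serials are assigned per chromosome in coordinate order so ids
are stable. Candidate targets: gene body within 5 kb of the element edge
(or overlapping) *and* overlapping the host segment's reference span.
Distance is edge-to-edge and signed by the element's position relative to
the gene (negative = element on the gene's 5′ side). Validation is binary
differential marking — a peak overlapping the element in exactly one
condition of an ordered pair — combined with gene FDR ≤ 0.05 and no
fold-change floor; all thresholds are config fields. Many-to-many
element–gene pairs are allowed.

Metaprofiles average a coverage track in 50-bp bins over ±2 kb around
element centers, with coding positions masked to missing and elements
stratified by target-gene expression quartiles; RPKM is
count/(length/10³)/(library/10⁶).

## Sequence features

The A+T profile slides a 10-bp window, 1-bp step, across
[center − 15 − 1000, center + 15 + 1000) of each element (center = 30 bp
around the element midpoint); elements whose profiled region touches CDS
or a chromosome end are excluded, and the center-vs-flank contrast is a
Welch t-test on per-element fractions.

Nucleosome occupancy uses the exact hard-core placement partition
function for a 147-bp footprint: Z_f(i) = Z_f(i−1) + W_{i−w}Z_f(i−w) and
its backward mirror, in log space; P(start i) = Z_f(i)W_iZ_b(i+w)/Z;
O(j) is the footprint-window sum of start probabilities. The energy model
is deliberately simple and pluggable: ln W_i = ln(scale) + α(AT_ref − AT_i)
with α = 6 (AT-rich footprints disfavored, the experimentally reported
direction), reference composition 0.65, and scale 1.223 calibrated so
background occupancy ≈ 0.8 on sequence at the reference composition — a
typical genome-wide level. No trained k-mer weights are reproduced; the
DP is the testable substance and is verified against explicit placement
enumeration. Free sequence ends create statistical-positioning
oscillations that decay over a few footprints, so occupancy is reported
over the central 2·flank+1 positions of sequences padded by ten
footprints (1470 bp) per side.

Matched controls are CDS-free random draws, optionally accepted only when
their A+T is within ±2% of the paired element (the tolerance is this
package's choice; exact matching is a measure-zero event), deterministic
under a seed.

SNP density: per class, SNPs inside the merged interval union, per-kb
rate, and 2×2 χ² with Yates continuity correction (SNP/non-SNP ×
class/comparator) against the whole genome and the coding region.
Comparators are used as printed — nested classes are scored
independently, not against their complements. The continuity correction
is what reproduces the published p-values from the published counts
(e.g. 0.5052 for elements vs coding).

## Simulator

The synthetic clade is the package's study condition, not a tuning knob:
5 species on a caterpillar topology, reference-to-leaf divergences
0.10–0.44 substitutions/site (the spread of a compact, recently radiated
plant family), 200-kb genome at 65% A+T, HKY with κ = 2, 25 single-block
genes, 20 planted non-coding elements of 60–200 bp with GC-enriched 30-bp
cores (the A+T dip real plant CNS centers show), conserved branch scale
ρ_true = 0.3, one inversion (6 blocks) and one translocation (5 blocks)
in different lineages, 12% of non-element blocks missing one random
species from the alignment, and SNP rates of 16/kb neutral vs 7.6/kb
constrained — echoing observed genome-wide vs element-level densities.

Selection in coding sequence is applied to codon positions 1 and 2 only;
third positions evolve neutrally. Scaling whole CDSs would place
four-fold degenerate sites under conservation and corrupt the neutral
model the pipeline fits from them — the simulator must not violate the
premise the method rests on.

There is no indel evolution (columns map one-to-one to homologous
positions, so the MAF is exact truth) and rearrangements act at 2-kb
block granularity with every gene and element inside a single block.
Consequently the tests demonstrate correctness of the inference given a
correct alignment; they say nothing about alignment error, repeat
content, lineage-specific duplications, or indel-induced column
ambiguity in real data. The epigenome generator marks a configured
fraction of elements with a single-condition peak, gives all their
candidate genes significant DE records, adds both-condition peaks and
off-element background peaks as negative controls, and records exactly
the pairs the validator must return.

## Problem sizes

Default test and acceptance runs use 30–200-kb genomes with 5 species;
the exhaustive oracles run on ≤ 5-leaf trees, 8-column chains,
≤ 12-anchor tables and ≤ 441-bp sequences, where enumeration is exact.
These sizes were chosen as the smallest at which every contrast of
interest (recovery, breakpoints, validation) is comfortably powered.

## Known limitations

- The per-site score is an LRT, not an exact substitution-count test;
  absolute −log₁₀p values are not comparable to exact-method output,
  though rankings are.
- The HMM transition probabilities are tuned, never EM-trained; only ρ
  (and optionally γ) are estimated from data.
- Collinearity is detected on the reference scan order only; paralogous
  (intra-genome) collinearity and whole-genome-duplication multiplicons
  are out of scope.
- The identifiability of root-adjacent branch pairs is inherent to
  reversible models; report path distances, not individual root edges.
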
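# Methods

`mprakit` analyzes massively parallel reporter assays (MPRA) in which
~150 bp DNA elements — the two alleles of candidate regulatory variants,
constitutively active positive controls and scrambled negative controls
— are cloned upstream of a minimal promoter and a random 20 bp barcode,
transfected in replicate, and read out as DNA and RNA barcode counts
under two conditions (a stimulated state and a vehicle baseline). This
note records the models, defaults and numerical choices, what the
synthetic generator does and does not emulate, and known limitations.

## Barcode mapping and counting

Mapping reads carry the element sequence followed by its barcode at
configurable offsets; the element segment must match a library sequence
exactly (a mismatch tolerance is configurable but defaults to 0, the
conservative choice), and extracted barcodes must be exactly 20 bp.
Barcodes observed with more than one element are removed entirely rather
than resolved by majority vote: the final dictionary keeps only unique
barcode–element pairs, and no vote rule is assumed. Count reads are
matched to the dictionary as exact 20-mers only. An orientation flag
reverse-complements reads for protocols that sequence the reverse
strand.

## Quality control

Filters run in a fixed, documented order:

1. **Count floor.** A (barcode, replicate) observation is dropped when
   its DNA *or* RNA count is below 5. The rule is strict ("less than"),
   so a count of exactly 5 survives. The disjunctive reading (either
   assay failing drops the barcode) is the package's documented choice.
2. **Outlier barcodes.** Within each (element, replicate, condition),
   barcode-level log2(RNA/DNA) values outside the Tukey fences
   [H1 − 1.5·IQR, H3 + 1.5·IQR] are excluded, where H1/H3 are Tukey
   hinges (the fivenum convention, matching R's `boxplot.stats`), not
   type-7 quantiles. Barcodes are dropped only in the replicates where
   they are flagged.
3. **Aggregation.** Retained barcode counts are summed per (element,
   replicate, condition). Library-size factors default to total retained
   counts scaled to mean 1, per assay; the replicate-level log2 ratio is
   log2((rna_sum/s_RNA + c)/(dna_sum/s_DNA + c)) with pseudocount
   c = 0.5 (configurable), which keeps ratios finite for sparse
   elements. Replicates with a DNA size factor below 0.10 can be
   excluded.
4. **Replicate QC.** Pairwise Pearson correlations of per-element log2
   ratios are computed within condition; a replicate is dropped when its
   median correlation to the others falls below 0.7 (configurable). This
   monotone rule operationalizes the qualitative "poorly correlated
   replicates are removed" practice.
5. **Availability filters.** (element, replicate) rows need ≥ 5 retained
   barcodes; elements must remain in ≥ 10 retained replicates per
   condition.

## Activity calling

The transcription-rate estimate of an element in a condition is the
ratio of depth-normalized summed RNA to summed DNA across retained
replicates, α = (Σ_r rna_r/s^RNA_r)/(Σ_r dna_r/s^DNA_r). Activity is
tested with a robust z (MAD score) of log2 α against the scrambled
negative controls:

    z = (log2 α − median_neg) / (1.4826 · MAD_neg)

with a one-sided upper-tail normal p (activity *above* the null is the
alternative), Benjamini–Hochberg adjustment across all tested elements
per condition, and an active call at FDR < 0.1 with z > 0. The 1.4826
factor makes the MAD a consistent scale estimate under normality. A
variant counts as active when either allele's element is active.
Condition-differential activity is a Welch two-sample t test on
replicate-level log2 ratios, computed only for elements measured in both
conditions and active in at least one; Welch is used because there is no
reason to assume equal variances across conditions.

### Calibration of the MAD test (limitation)

The negative-control set calibrates both the center and the scale of the
null. With a small reference set (50 scrambled negatives in the default
synthetic study) the MAD has a relative standard error near 16%, and
because the one-sided normal tail is steep at the BH cutoff, realized
false-discovery proportions fluctuate strongly around — and average
above — the nominal level: across repeated synthetic studies at the
default conditions the mean FDP at nominal FDR 0.1 is about 0.15
(0.146 ± 0.014 over 100 studies, median 0.11), with single-study FDP
anywhere between 0 and ~0.4, while sensitivity for 4-fold planted
effects stays at 1.0. A finite-reference
correction (e.g. a t-type reference distribution) would temper this but
would change the plug-in normal-tail definition of the score this
package implements; users with few negative controls should treat
borderline calls with caution and prefer larger negative sets. The
acceptance harness reports expectation estimates averaged over repeated
studies for exactly this reason.

## Allelic effects and condition interactions

Allelic effects are tested per variant and condition on replicate-paired
differences d_r = log2_ratio(alt) − log2_ratio(ref) over the replicates
retained for both alleles; pairing removes replicate effects. logFC is
the mean of d, and the t statistic uses either the sample variance or,
by default when at least 10 variants are testable, an empirical-Bayes
moderated variance: a scaled-F hyperprior is fitted to the per-variant
sample variances by a moment fit on log variances (prior degrees of
freedom d0 from the excess spread of log s² over its sampling trigamma,
prior scale s0² from the centered mean), and each variance is shrunk to
s²_post = (d0·s0² + d·s²)/(d0 + d) with the t gaining d0 degrees of
freedom. Where retained replicate counts differ between variants the
hyperprior is fitted at the median residual df and shrinkage applied
with each variant's own df. Tests are two-sided (no prespecified
direction of allelic effects); emVars are variants at FDR < 0.1,
tested only when at least one allele showed activity.

Genotype-by-condition interactions are ordinary least squares on
replicate-level log2 ratios with allele (alt = 1), condition
(stimulated = 1) and their product; the t test is on the product
coefficient, BH-adjusted over tested variants. Only variants that are
emVars in at least one condition enter, and designs with an empty cell
are skipped with a reason code. The model is fitted at element level
(not barcode level), consistent with aggregating before testing.

## Transposable-element context

Repeat annotations come from RepeatMasker `.out` files or a BED6+
dialect. Overlaps use 0-based half-open intervals (adjacency is not
overlap), with chromosome-name normalization ("chr1" vs "1"). For
forward-oriented Alu elements of length ≥ 250 bp, the element's relative
position is the distance from the Alu start to the midpoint of the
overlap (floor of the mean); for minus-strand Alus the mirrored distance
from the Alu end is provided as a documented extension. The Pol III
promoter boxes are matched in the element sequence: A-box TGGCTCACGCC
and B-box GTTCGAGAC exactly, plus "box-like" hits within edit distance 1
(enumerated per offset over windows of width w−1, w, w+1, so a distant
exact hit never masks a local near-hit). The T4 terminator rule fires
when TTTT occurs 3′ of a box hit within the element. Alu age bins by
milliDiv (mismatches per thousand bases to consensus) are <100, 100–150
(closed on both ends, a documented convention) and >150. Consensus
landmark offsets used for approximate arm classification (A-box ≈ 6,
B-box ≈ 72, linker ≈ 130) are literature-informed configuration, and all
landmark-dependent outputs are approximate.

## Motif scanning and disruption

PWMs (JASPAR text or minimal MEME) are converted to probabilities with a
0.001 pseudocount and scored as base-2 log-odds against an i.i.d.
background (uniform by default). P-values are exact tail masses of the
null score distribution: for widths ≤ 8 the distribution of the exact
float score is built by convolution over columns with merging of equal
sums, so p-values equal exhaustive enumeration over all 4^w words to
floating-point precision; wider motifs use a dynamic program on scores
discretized to 0.01-bit steps, for which halving the step does not
change p-values at three significant figures. BH across a scan run uses
the total number of scored positions (all offsets, strands, motifs,
sequences) as the test count, so sub-threshold p-values need not be
materialized. Motif clusters can be restricted to those with at least
one member TF expressed in the assayed cells.

Disruption scores compare the best hit of each allele, over both
strands, among the placements covering the variant (a window of width
2w−1 centered on it): delta = best_alt − best_ref, antisymmetric under
allele swap by construction. "Strong" disruption means |delta|
normalized by the PWM's score range exceeds 0.4 (configurable; the
threshold is this package's convention). The disruption–effect
relationship is summarized by Pearson correlation and a least-squares
fit of allelic logFC on delta, pooled or per motif.

## Enrichment statistics

Fisher's exact test is two-sided with the probability-ordering rule
(all tables with fixed margins whose probability does not exceed the
observed one); the primary odds ratio is the conditional MLE under the
noncentral hypergeometric model, with the sample cross-product ratio
reported alongside (conventions differ between tools, so both are
emitted). BH adjustment is the standard step-up. The sign test is the
exact one-sided binomial tail. For element-level enrichment the unit is
the variant: the allele element with the smaller activity p is kept
(ties keep the reference allele), the active group is variants with an
active element, and the inactive background requires both alleles tested
and inactive, so each variant is counted exactly once.

## Gene linking and regional regression

Promoter linking uses a 2 kb window upstream of the TSS, closed at the
far edge and open at the TSS (the boundary convention is documented
since only "2 kb upstream" is specified). Loop linking connects an
element overlapping one anchor of a chromatin loop to every gene whose
TSS overlaps the mate anchor, symmetric in anchor order, de-duplicated
for self-loops. Concordance between condition-differential element
activity and differential gene expression (FDR < 0.1) is the fraction of
linked pairs with matching effect signs, tested one-sided against 0.5
with the exact binomial test.

Regional analysis regresses per-region association z-scores — effect
size over standard error, signed toward the motif-matching allele — on
mean regional TF expression (expression first averaged over
developmental ages, fine-parcellation values averaged many-to-one into
macroscale regions). Each (variant, TF) pair is a separate regression
with BH across pairs; pairs with fewer than 3 regions or constant
expression are skipped with reason codes.

## Synthetic data generator

The generator emulates the emulated study's design quantities: 150 bp
elements in ref/alt pairs differing at exactly one base (the variant at
offset 75), scrambled negatives that are exact Fisher–Yates permutations
of designed sequences (preserving base composition and GC), ~113
barcodes per variant before transfection (Poisson, split across the two
allele elements), and 16 replicates per condition (14 in the recovery
benchmark). Counts are hierarchical negative binomial: DNA ~ NB(mean,
dispersion α) with variance mean + α·mean², drawn once per replicate and
shared across conditions (the plasmid pool does not depend on
stimulation); RNA is NB around the realized DNA count times
2^(activity + allele·allelic-lfc + stim·allele·interaction) and the
replicate/condition depth. Defaults not fixed by the emulated design are
the generator's own documented choices: DNA mean 60 per barcode,
dispersion 0.1, log2 depth spread 0.25, and 1% jackpot barcodes with RNA
inflated 8-fold. A configurable subset of elements embeds Alu A/B boxes
(the planted B-box sits at offset 90 by default so the variant base at
offset 75 cannot destroy it; the Alu-consensus landmark 72 remains the
annotation-side convention), and side-annotations (repeat track, TSSs,
loops, PWMs, regional expression/z tables, a DE table coupled in sign to
planted interactions) are generated consistently with recorded truth.

What the generator does **not** emulate: sequencing error beyond
exact-match counting, PCR duplicates, batch structure beyond depth,
linked variants or haplotypes, heteroscedasticity between element
categories, and chromatinization — so passing recovery tests demonstrate
correctness of the statistical machinery under the stated noise model,
not performance on real libraries.

## Problem sizes and reproducibility

The recovery benchmark uses 200 variants (400 allele elements) plus 50
scrambled negatives and 4 positive controls, 14 replicates per
condition, dispersion 0.1, with activity log2 α = 2 planted for 10% of
variants, allelic lfc = 1 for 10% and interaction β = 1 for 5% — a
desk-scale study that keeps a full generate–QC–test cycle near three
seconds, so expectations can be estimated by averaging seeded runs. All
randomness flows from a single integer seed through named substreams
(library, counts, annotations), and two pipeline runs with the same seed
produce byte-identical outputs, verified by manifest SHA-256 hashes.
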
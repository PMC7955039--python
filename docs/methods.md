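# Methods

This note documents the statistical models, parameter defaults, numerical
choices, and the design decisions taken where the analysis was genuinely
open.  Notation: an *oligo* is one allele-specific test sequence; a variant
has one oligo per allele (forward and reverse-complement synthesis
orientations are merged before analysis).

## Oligo design

For a SNP, the genomic core is 170 bases: 84 bases of upstream flank, the
allele base, 85 bases of downstream flank, so the variant sits at 0-based
core position 84.  For indels the flanks are chosen so the *longest* allele
reaches exactly 170 bases, with the first base of the longest allele
anchored at core position 84 and the 3' flank truncated accordingly; all
alleles of a variant share byte-identical flanks.  The anchor choice for
indels is a package decision (only the SNP 84/85 split is forced by the
design constants); it keeps the variant maximally centered while preserving
shared flanks.  The fixed adapters are `ACTGGCCGCTTGACG` (5') and
`CACTGCGGCTCCTGC` (3'), giving a 200-base oligo for a SNP.  Coordinates are
1-based VCF-like on input and 0-based half-open internally and in all BED
I/O.  Soft-masked genome bases are uppercased; non-ACGT bases in any flank
or allele are rejected.

## Barcode processing

A read is accepted when the two bases immediately 3' of the 20-base barcode
match the reference constant region exactly and the whole constant segment
is within Levenshtein distance 4 of the reference (edit distance via edlib).
Barcodes observed with two or more distinct oligos are discarded entirely;
the rest map to exactly one oligo.  Counts are summed to the oligo level
with forward/reverse-complement records merged by summation (how the two
synthesis orientations were combined is not dictated by the assay; summation
treats them as technical replicates of one allele).  Oligos with fewer than
30 distinct barcodes in the plasmid control are excluded.  Counting is
deterministic: per-sample totals always decompose into matrix column sums
plus an unmapped tally.

## Enhancer-activity model

Let `K_ij` be the barcode-summed count of oligo `i` in sample `j`, with
`n_D` plasmid and `n_R` mRNA replicates (default 3 + 3).

1. **Normalization.** Median-of-ratios size factors
   `s_j = median_i K_ij / (prod_j K_ij)^(1/m)` over zero-free rows; an error
   asking for a pseudocount is raised when no zero-free row exists.
2. **Fold change.** `log2FC_i = log2(mean_R / mean_D)` on normalized
   counts.  Oligos with zero mRNA everywhere are reported at the sentinel
   −10 and can never be enhancer alleles; zero-plasmid means are guarded
   with a 0.5 floor inside the standard-error formula only.
3. **Dispersion.** A per-oligo method-of-moments NB dispersion
   `alpha_i = max((s2_i − mu_i) / mu_i^2, 0.01)` where `s2_i` is the
   *within-group residual* variance of normalized counts (group means
   subtracted, pooled over both groups, `n_D + n_R − 2` df) and `mu_i` the
   overall normalized mean.  The 0.01 floor guards against degenerate
   variance estimates at this replicate number.
4. **Test.** Wald-type statistic `log2FC / SE` with the delta-method SE
   `SE^2 = [ (mu_R + a mu_R^2)/(n_R mu_R^2) + (mu_D + a mu_D^2)/(n_D mu_D^2) ] / ln(2)^2`,
   referred to a Student-t distribution with `n_D + n_R − 2` degrees of
   freedom, two-sided.  With 3 + 3 replicates the variance estimate carries
   ~4 df; a normal reference would roughly double the nominal type-I error
   (the statistic is essentially a pooled t in the large-count limit), so
   the t reference is used.  Under the null synthetic generator the raw
   p < 0.05 fraction is within [0.03, 0.07] (checked by the test suite).
5. **Decisions.** BH correction across all tested oligos in the run
   (controls pooled with the main library).  enAllele: `p_adj < 0.05` and
   linear fold ≥ 1.5.  enVar: any allele is an enAllele.  The resampling
   negative set (*non-enVars*) contains variants with *no* allele reaching
   `p_adj < 0.05` together with fold > 1.10; variants significant at
   intermediate folds belong to neither set.

## Allelic-skew model

Only enVars are tested.  Each barcode `b` of an allele contributes one
plasmid-normalized ratio

    r_b = log2( (rna_b / s_rna + 1) / (dna_b / s_dna + 1) ),

with the pseudocount 1 applied after size-factor scaling (avoids log of
zero; configurable).  mRNA counts are matched to plasmid counts by barcode
identity, replicate `r` mRNA against replicate `r` plasmid (or the single
plasmid control when only one exists), and ratios are pooled across
replicates.  Each unordered allele pair of each enVar is compared by a
two-sample Student t-test with pooled variance — pooled rather than Welch
because barcode numbers and ratio variances are comparable between alleles
of one variant — and BH correction is applied across all pairs of all
enVars in the run.  A pair is allelic when `p_adj < 0.05` and the
between-allele activity ratio `2^(mean difference)` is ≥ 1.25 or ≤ 0.8; a
variant is an allelic enVar when any pair is allelic.  Variant-level
summaries (genotype dependence vs maximum activity, the per-locus
candidate-reduction table) use the pair with the smallest adjusted p-value;
alleles with fewer than two barcodes skip their pairs with a flag.

## Peak-set enrichment

Variants are 1-base loci (indels: their reference span).  For each peak
dataset the observed number of input loci inside ≥ 1 peak (by ≥ 1 base;
intervals merged, half-open) is compared with a null built by sampling
`|input|` loci *without replacement* from the negative set, 2000 iterations
by default.  `z = (obs − mean)/sd` with a one-sided upper-tail normal
p-value; a batch run applies Bonferroni with the number of datasets actually
tested.  Degenerate nulls (sd = 0) report p = 1 when the observation does
not exceed the null mean, otherwise p = 1/n_iter with a flag.  Each dataset
draws from an RNG stream keyed by (seed, CRC32 of the dataset name), so
batch results are independent of dataset order and reproducible per dataset.

## Allelic ChIP-seq binding

Only sites heterozygous in the assayed cell line *and* inside a peak are
considered.  Imbalance strength is `1 − weak/strong` read counts (0 =
balanced, 0.5 = the strong allele has twice the reads; exactly 1 only when
the weak allele has no reads).  The per-dataset reproducibility score is the
minimum replicate strength when all replicates prefer the same allele and 0
otherwise; this score is a package-defined stand-in for a published
replicate-reproducibility score whose formula is external to this work, and
the scoring function is pluggable so an alternative can be swapped in.  A
dataset call is allelic when score > 0.4, a two-sided binomial test of the
summed reads against 0.5 gives p < 0.05, and at least 6 reads are available
(below that the binomial test is powerless); ties have no preferred allele
and are never allelic; zero-read replicates are dropped with a flag.  The
three consistency filters then retain a (variant, protein) event only when
(1) at least 50% of the heterozygous-in-peak datasets for that protein are
allelic, (2) at least 75% of the allelic datasets prefer the same allele,
and (3) replicates agree on direction (already enforced by the score).
Profiles report the median strength across cell lines (each cell line
contributing its median) and the "(k of n)" dataset counts.  Filters only
remove events.

## Motif analysis

PWMs are per-position base probabilities regularized with pseudocount 1e-3
and renormalized; background defaults to uniform 0.25.  A window scores
`sum_i log2(p_i(base)/bg(base))`; the reverse strand scores the reverse
complement.  The *relative score* is 100 × score / (maximum achievable
score); motifs whose maximum score is not positive are rejected as
uninformative.  Negative relative scores are kept negative rather than
clamped or min-max scaled — only the ≥ 70 / < 40 comparisons matter
downstream, and clamping would discard the distinction between poor and
catastrophic matches.

A *binding-site altering event* for a motif at a variant requires one
allele's best relative score ≥ 70 and the other's < 40, with each allele
padded by 25 bases of flank and **scored only over windows overlapping the
variant base(s)** — otherwise a strong site in the (identical) flanks would
mask the variant's effect.  An allelically bound TF with an altering event
for any of its motifs is *variant overlapping*; with allelic reads but no
event it is *variant adjacent* (TFs lacking any motif in the collection are
flagged and classified adjacent); TFs without allelic reads are not
classified.

Family-level tests use a two-sided two-proportion z-test (pooled variance).
The variant-overlapping analysis compares the fraction of allelic enVars
with an altering event per family against non-allelic enVars; the
variant-adjacent analysis compares the fraction of 170-base input sequences
containing a "hit" (any window, either strand, relative score ≥ 70 — the
same cutoff as the strong-site criterion, one consistent definition)
against dinucleotide-shuffled versions of the same sequences
(Altschul–Erickson Eulerian-walk shuffle, exact dinucleotide counts,
seeded).  BH correction runs across families; reported rows additionally
need ≥ 3 altering events (overlapping) or ≥ 5 predicted sites (adjacent)
and `p_adj < 1e-4`, with the full table always retained.  A hypergeometric
test is available as an option for sequence-set enrichment but the
proportions test is the primary statistic.

## Gene annotation

Targets are the union of chromatin-looping (promoter-interacting) genes and
eQTL genes; when empty, the nearest gene by distance to the *transcript
span* (not the TSS — the anchor is otherwise ambiguous) with lexicographic
tie-breaking.  Tiers: (1) some gene has both eQTL and looping support, (2)
any eQTL, (3) looping only, (4) neither.  Adding evidence can only improve
(lower) the tier.

## Synthetic data

The generators reproduce the study conditions the pipeline is designed for:

- Barcode multiplicity per oligo: rounded lognormal with median 729 and
  sigma 0.4 (approximating the roughly normal observed histogram on the
  count scale); the ≥ 30-barcode filter is applied downstream, not at
  generation.
- Counts: independent NB draws per (barcode, sample) with dispersion 0.05
  (typical of plasmid reporter libraries) and ~20 reads per barcode; mRNA
  means are scaled by the planted enhancer fold (all alleles of a variant)
  and by `2^delta` for non-reference alleles of planted allelic variants.
  Summing ~729 barcodes makes oligo-level totals nearly Poisson, matching
  the very high replicate correlations of real screens.  A separate
  oligo-level generator draws NB totals at a *specified oligo-level
  dispersion* for calibration studies of the activity test.
- Peaks: per dataset, each variant is covered by a 200–1000-base peak with
  probability 0.5 (planted targets) vs 0.1 (background).
- Allele-specific reads: binomial with 40 reads per replicate, 2
  replicates, allele-1 probability 0.5 (null) or a planted ratio (0.8 in
  the pipeline defaults); heterozygosity drawn per (variant, cell line).
- Motif planting: variants sit on an 80-base grid so planted sites never
  collide.  "Overlapping" plants write a motif consensus across the variant
  with a highly informative central column (0.997 concentration), set the
  reference allele to the weakest base of that column and the alternative
  to the consensus base — the alternative allele then scores 100% relative
  and the reference falls below 40%.  "Adjacent" plants write the consensus
  30 bases downstream into the shared flank of both alleles.

What the generators do **not** emulate: sequencing error profiles and read
alignment, barcode synthesis biases, GC/sequence-composition effects on
counts, linkage between variants, correlated (batch) noise across oligos
within a replicate, and real PWM shapes.  Passing tests therefore
demonstrate correctness and calibration of the statistical machinery under
the stated noise model, not performance on real screens — in particular,
real data carry between-replicate overdispersion that the barcode-summed
synthetic counts do not.

## Problem sizes and determinism

The test suite runs the calibration checks at 1000 null oligos and 500 null
variants, power checks at 100 variants with 20 planted effects, enrichment
recovery at 40 input vs 1000 negative loci with 2000 resampling iterations,
and the end-to-end determinism check at 20 variants; the default pipeline
configuration uses 40 variants at 8 loci with full 729-barcode depth.  These
sizes keep the whole suite under a minute while leaving every statistical
property measurable.  All randomness flows from a single seed through named
or spawned child streams; re-running any generator, stage, or the whole
pipeline with the same configuration is byte-identical.

## Known limitations

- The NB dispersion is estimated per oligo from few replicates with a
  simple floor; no information sharing across oligos (trend/shrinkage) is
  performed.  With barcode-summed counts this costs little, but with few
  barcodes per oligo the test becomes conservative.
- The minimal promoter design measures activation only; reduced activity
  relative to plasmid is reported but not interpreted as repression.
- The replicate-consistency binding score preserves the > 0.4 threshold
  semantics of published allelic-reproducibility scores but is not
  numerically identical to them; thresholds may not transfer across score
  definitions.
- Allelic ratios pool barcodes across replicates rather than aggregating
  per replicate first; with strong batch effects a replicate-level
  aggregation would be more robust.
- The two-proportion z-test is a large-sample approximation; family rows
  with very small denominators are filtered from reports rather than
  switched to exact tests.
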
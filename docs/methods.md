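# Methods

This note documents the models, parameter choices and numerical decisions
behind `dmrpipe`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and data model

Call files on disk are 1-based (the common extractor convention); the
in-memory model and all interval outputs are 0-based half-open, and BED
emission follows BED conventions. Sites are kept strand-specific; symmetric
CG positions therefore contribute two records. Binning pools both strands,
which maximizes per-bin counts and is what makes the "10 informative
cytosines per 100-bp bin" filter attainable in a rice-like genome (about
9 CG, 7 CHG and 34 CHH cytosines per 100 bp at GC 0.43); at bin scale the
results are insensitive to whether symmetric CG sites are collapsed.
Cytosines within 2 bp of a chromosome end lack a full trinucleotide and
fall back to CHH (negligible count, avoids dropping sites); any N in the
trinucleotide makes the site `not_cytosine` and it is excluded everywhere.

## DMR calling

A bin's test statistic is a two-sided Fisher's exact test on the pooled
`[[#C_sample, #T_sample], [#C_control, #T_control]]` table. Pooling reads
across cytosines treats reads as independent observations — the only
reading under which a per-bin count test is well defined. The two-sided
tail uses the point-probability rule: all tables with the observed margins
whose probability does not exceed the observed one, with a relative tie
tolerance of 1e-7 to absorb floating-point noise in the log-gamma
evaluation (the enumeration itself is exact; tests verify agreement with
exact integer-arithmetic enumeration to 1e-9 relative for all tables with
N <= 30). An all-zero table yields p = 1 by convention.

Benjamini–Hochberg runs genome-wide per (sample, context) over eligible
bins only. Bins failing the informative filter are excluded *before*
testing (statistically cleaner: they contribute no test); a
`filter_stage="post"` flag preserves the literal order of applying the
filter last. Ties at exactly the absolute-difference threshold pass (>=).
Significant bins are split by sign into hypo/hyper before merging; a gap of
up to `merge_gap` (default 100 bp, i.e. one empty bin) merges
same-direction bins, and hypo and hyper bins never merge together. Pooled
methylation of a merged region is recomputed over the full span. Output is
sorted by (chromosome, start) and disjoint within (sample, context,
direction).

Degenerate inputs: a sample compared against itself warns and returns no
DMRs; unknown chromosomes in the calls raise; bins with zero reads on
either side are never tested.

## Error-rate estimation

The chloroplast is unmethylated, so every methylated call there is a
non-conversion/sequencing artifact. The estimate is the pooled fractional
methylation over organelle cytosines of a context. Symmetrically, the
simulator's error model inflates apparent methylation only
(`p_observed = p_true + (1 - p_true) * error_rate`): a failure to call a
truly methylated cytosine is set to zero, because that is the quantity a
chloroplast-based estimate can measure.

## Synthetic methylomes

The generator emulates the data structure the analysis assumes, not
sequence-level reality. Key choices, with defaults:

- **Genome**: i.i.d. bases at GC 0.43 (rice-like), 2 chromosomes of 1 Mb by
  default, plus a 20-kb "chloroplast". Real genomes have CpG depletion,
  repeats and mappability structure; none of that is modelled.
- **Locus classes**: intergenic/TE background methylated at CG 0.85,
  CHG 0.55, CHH 0.07; gene bodies carry a CG-only 5'→3' gradient
  (0.3–0.7 x the CG baseline) with non-CG near zero; 30% of promoters are
  methylated, and those carry CHH at an RdDM-island level of 0.25. The
  island level exists because genome-background CHH (0.07) sits below the
  caller's 0.1 CHH difference threshold: plantable CHH losses require
  RdDM-like loci, which is also where they occur in real plants.
- **Susceptible regions**: hypomethylated regions of 400/500/500 bp
  (CG/CHG/CHH) are planted half in methylated promoters, half in methylated
  background (CHH: TE genes). Each region must contain at least one whole
  100-bp bin holding >= 10 cytosines of its context, so that the planted
  truth is recoverable by the caller's informative filter at 15x — a
  placement constraint, not a change to the loss model. Loss is
  multiplicative, `p -> p * (1 - delta/level)` floored at 0, with deltas
  0.8/0.6/0.15. The CHG delta (0.6) exceeds the CHG level (0.55), so the
  floor makes the realized drop equal the level itself (0.55), still above
  the caller's 0.5 threshold.
- **Sharing and inheritance**: each regenerant loses each susceptible
  region independently with probability 0.5 (partial sharing across
  plants). The first regenerant's T4/T6 descendants inherit its losses
  except a per-region recovering fraction: 10% recover at T4, 4.4% only at
  T6, 2% recover transiently at T4; the remainder are stable.
- **Callus**: gains +0.2 CHH (capped at 1) at a distinct unmethylated
  promoter subset; regenerants do not inherit these gains.
- **Counts**: coverage ~ Poisson(15) per site, methylated calls binomial
  with non-conversion 0.012. Read depth is independent across sites; real
  coverage is autocorrelated.
- **Small RNA**: 24-nt counts are Poisson with rate proportional to the
  sample's local true CHH methylation in 50-bp windows; 21-nt reads are a
  methylation-independent background. Only these two lengths are emitted.
- **mRNA**: negative binomial (mean 200, dispersion 0.05). A gene is
  responsive with probability 0.3; in samples where a responsive gene's
  promoter overlaps a lost region its mean is multiplied by 4. Library
  sizes default to column sums and can be fixed (e.g. 1e6) for controlled
  tests.

Everything is a pure function of (config, seed) via per-stage child
streams, so reruns are byte-identical and any sample's counts can be
re-drawn as an independent technical replicate of the same truth.

What passing tests show: the pipeline recovers exactly the structure the
generator plants, at realistic depth and error rates, with calibrated
nulls. What they do not show: robustness to alignment artifacts,
mappability holes, coverage autocorrelation, partial (heterozygous)
methylation losses, or annotation errors — none of which the generator
emulates.

## Comparative analyses

Overlap matrices are asymmetric by design (percent of row-sample DMRs
hitting any column-sample DMR; 1 bp counts). Common DMRs are anchored on
the first (reference) set because DMRs are sample-defined entities; the
result is bounded by the smallest set. Heat-map matrices hold pooled
methylation per region; rows with any zero-coverage (undefined) entry are
flagged and dropped before clustering, which uses complete linkage on
Euclidean distance with scipy's deterministic tie-breaking; dendrograms
export as Newick. Stability classification uses pooled fractions (not
per-site means), consistent with the caller; a level exactly half of wild
type counts as "gain", since loss is defined strictly and the tie has
measure zero on real data. Regions with zero coverage in any generation
are reported separately as unclassifiable.

## Enrichment

Randomized sets preserve the observed interval count and length multiset;
placement is uniform over valid starts, on a chromosome drawn
genome-proportionally (a `match_chrom` flag keeps the source chromosome
instead). Randomized intervals may overlap each other and the observed
set — the simplest null preserving number and size. The empirical p uses
the add-one estimator, so it is never zero and p < 1/101 is unattainable:
the p < 0.01 flag with 100 sets means "beyond every randomization". The
overlap unit is the DMR (hit/not-hit), not overlapping bp. TSS distances
are signed strand-aware (negative upstream), zero when the region spans
the TSS, with ties broken toward the smaller gene id.

## Expression and small RNA

The differential-expression statistic is a two-sided Fisher's exact test
of each gene's count against the remainder of its library — a standard
two-library count test of the era — BH-corrected over tested genes, gated
at fourfold on RPKM-normalized counts. The statistic is pluggable
(`call_de(..., test=...)`) for anyone preferring a dispersion-aware model.
Fold changes use +0.5 pseudocounts; genes with zero counts in both
libraries are excluded from testing and from every downstream denominator.
Library sizes are supplied (uniquely-mapped totals), not recomputed.

One measured limitation worth stating plainly: when the true expression
effect equals the fold cutoff exactly (a fourfold effect tested at a
fourfold gate), the estimated fold is centred on the cutoff, so such genes
are called at only ~50% rate no matter the sequencing depth; recovery of
genes at the cutoff boundary is intrinsically limited, while the
false-positive rate among unchanged genes stays below 1%.

## Metaprofiles

Regions are scaled to 20 body windows with equal-length flanks (20 windows
each); window counts are configurable, and any reasonable resolution gives
the same shapes. Window methylation is the pooled fraction, consistent
with the caller; small-RNA signal is reads per bp. Positions are points
and are assigned to the fractional window containing them, which is the
degenerate case of fractional-overlap weighting; windows with no data are
excluded from that region's contribution rather than imputed. Flanks
truncated at chromosome edges contribute their available span and are
counted.

## Problem sizes

The bundled acceptance checks run the full method on a 10 Mb, 2-chromosome
genome at 15x with 50 planted regions per context (plus 100-seed null and
enrichment calibrations and a 1000-region stability recovery), sizes at
which every statistical property of interest is already stable; the
simulator scales to larger genomes with the same configuration surface.
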
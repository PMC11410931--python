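# Methods

This note documents the models and procedures `peaksyn` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the procedure was genuinely open.

## Coordinate and overlap conventions

All coordinates are 0-based half-open (BED convention) internally; GFF3 is
converted on read. "Overlap" always means ≥ 1 shared base on the same
chromosome, ignoring strand (peaks are unstranded). Merging rules use
strict inequalities: fragments separated by a gap of *less than* 100 bp are
merged (a gap of exactly 100 bp survives) and fragments of *less than*
20 bp are discarded (a 20 bp fragment survives). Peak summits are stored as
offsets from the peak start (narrowPeak column-10 semantics); BED6 input
without a summit column defaults the summit to the interval midpoint.

## Replicate consensus

The operative criterion is support by at least `min_entries = 3` distinct
biological replicates. Pooled replicate peaks are clustered by
single-linkage overlap within a chromosome; each sufficiently supported
cluster yields one consensus peak spanning min(start)–max(end) of its
members, with the summit at the floored mean of the member summit
positions. Span (rather than intersection) semantics were chosen because
summit averaging presumes a region containing all member summits. When more
than `min_entries` replicates support a cluster, all supporting summits
enter the average; the original description covers only the three-replicate
case, so this is flagged as a package choice. Rank-combination statistics
of consensus-calling tools are intentionally not reproduced — the support
rule is the criterion. The species-level set adds condition-specific peaks
(zero overlap with any wild-type peak) to the wild-type set; wild-type
coordinates win on conflict.

## Regulatory classification and overlap testing

Classification is a pure intersection rule on the consensus ATAC set:
K4 ∧ K27 → putative promoter, ¬K4 ∧ K27 → putative enhancer, K4 ∧ ¬K27 →
K4-only, neither → uncharacterized. The four labels partition the input by
construction. The minimum overlap is configurable (`min_overlap`, default
1 bp).

The permutation overlap test re-places each query peak uniformly at random
on its own chromosome, preserving its length and allowing collisions among
placed peaks — the simplest null consistent with random re-placement; it
does not preserve inter-peak spacing. The statistic is the number of query
peaks hitting ≥ 1 reference peak; p = (1 + #{perm ≥ obs})/(n_perm + 1),
one-tailed for enrichment by default, and z = (observed − mean)/sd of the
permuted counts (reported missing when sd = 0). Published per-test
"Z-score" figures that merely repeat the observed count are not a defined
statistic and are not reproduced.

Feature annotation uses the summit base only, with fixed priority
promoter (0–3000 bp upstream of a TSS, inclusive of the TSS base) > exon >
intron > downstream (≤ 3 kb past the gene end in transcription direction) >
distal intergenic. `distance_to_TSS` is signed, negative upstream. The
nearest gene is the arg-min of |distance| over all genes on the chromosome.

## Conservation protocol

Two projections per peak: the full region (RGN) and the summit ± 25 bp
window (SUM, 51 bp, summit-centered; clipped at chromosome ends, so it may
shrink). Cleaning applies to RGN only — length filter *before* merging,
because reversing the order changes results (a short fragment could bridge
two distant fragments) — and never merges across recipient chromosomes. A
peak whose cleaned RGN fragments overlap any SUM fragment is a conserved
region; any SUM-supported fragment overlapping a recipient ATAC peak
upgrades it to conserved peak (liberal scoring: any overlap is a hit; the
test runs against merged cleaned fragments, not raw projections). A peak
projecting to multiple chromosomes is conserved if any chromosome's
fragments pass.

Aggregation over the three recipient species: high requires conserved peak
in all three; not conserved requires no conservation in any; partial is
everything else. The three categories partition the peak set, which the
category fractions must therefore sum to 1 — a property the tests assert on
every fixture.

The class × conservation association is Pearson χ² without continuity
correction. The small K4-only class is folded into uncharacterized by
default so the table is the 3 × 3 (df = 4) three-category comparison;
`collapse_k4=False` keeps it separate. Post-hoc tests are all pairwise
class comparisons (2 × 3 tables) with Bonferroni correction — the post-hoc
procedure was not specified upstream and is documented here as a package
choice. Zero-margin levels are dropped with a warning. An optional
permutation p shuffles class labels.

## Synteny statistics

The ortholog contingency table counts pairwise single-copy orthologs per
(chromosome A, chromosome B); genes on unplaced scaffolds are excluded
(chromosome-scale comparison). Significance: analytic χ² plus a
permutation null built by shuffling the chromosome-B column of the
ortholog list — this preserves both margins exactly and realizes the
"orthologs randomly distributed across chromosomes" null; shuffling
genes-within-chromosomes was the rejected alternative. Effect size is the
classic (uncorrected) Cramér's V, 0 at independence and 1 at perfect
association; the bias-corrected variant was rejected because the 0/1 limits
of the classic statistic are the documented interpretation. Permutation p
uses add-one smoothing with a 1e-9 tolerance on the χ² comparison to
absorb float jitter in tied statistics.

Linkage-group enrichment: per (group, chromosome), a one-tailed Fisher
exact test on [[in-group on-chrom, in-group off-chrom], [out-group
on-chrom, out-group off-chrom]], Bonferroni-adjusted over all pairs (the
upstream tool's internal correction is unknown; Bonferroni is the
conservative default). A group is retained when enriched on ≥ 1 chromosome
at adjusted α = 0.05.

## Breakpoint repeat enrichment

Every synteny-block edge contributes one 10 kb window immediately outside
the block, clipped at chromosome ends (a block touching position 0 or the
chromosome end loses that flank) and deduplicated when abutting blocks
share a breakpoint. The observed statistic per repeat family is the number
of elements overlapping the window set (element counts, not base pairs; an
element counts once against the set). Each of `n_iter = 1000` iterations
re-places the same number of windows with the same lengths, each on a
chromosome drawn with probability proportional to length (among chromosomes
long enough) and uniform within it, overlaps allowed. The two-tailed p is
2·min(upper, lower tail) with add-one smoothing, capped at 1. Families
whose permuted mean count is below `min_mean = 10` are reported untested —
"on average" is read as the permuted expectation — and excluded from the
Benjamini–Hochberg adjustment.

## High-confidence transcript filter

Kept iff repeat overlap ≤ 0.75 (strictly more than 75% rejects) AND either
ORF ≥ 100 aa with TPM ≥ 0.001, or 50 ≤ ORF < 100 aa with (BLAST support
and TPM ≥ 1) or (no support and TPM ≥ 10). BLAST support means identity ≥
75% and coverage ≥ 75%, both inclusive. ORFs under 50 aa are excluded
outright: no rule admits them. Each rejection carries exactly one reason
code with precedence repeat > orf_too_short > low_expression. The filter is
monotone in TPM and anti-monotone in repeat fraction. Repeat overlap is
accepted as a precomputed per-transcript fraction; how it was measured is
upstream of this package.

## Synthetic data

The generator produces a desk-scale universe: four chromosomes of 1–2 Mb,
2000 peaks by default, lognormal peak lengths (median ≈ 0.6 kb, matching
the ~0.67 kb mean of real accessible-chromatin peaks), laid out in disjoint
slots with ≥ 300 bp separation so that mark peaks (placed ± ≤ 100 bp around
their peak) can never contaminate a neighbor. Default class fractions are
the genome-wide proportions of the four classes in the reference peak
universe (≈ 0.248/0.192/0.013/0.548). Each truth peak enters each of four
replicates with probability 0.85, jittered ± 20 bp. Conservation: with
probability q = 0.7 per recipient species a peak receives a genuine
aligned core (normal length, mean 555 bp, sd 100, min 200, covering the
summit; 20% of cores on the minus strand to exercise the coordinate flip),
overlaid by a recipient ATAC peak with probability 1.0 by default;
otherwise only 0–3 spurious sub-20 bp fragments. The expected high
fraction is therefore (q · p_atac)³. Orthologs keep their ancestral 1:1
chromosome mapping with probability s (default 0.9), else re-assign
uniformly; linkage groups are contiguous ancestral sets. Repeats follow a
per-family Poisson background (elements/Mb) with an optional planted
density factor e inside true breakpoint windows.

What the generator does **not** emulate: sequence content (no FASTA, no
motifs), signal strength and peak-calling noise beyond positional jitter
and dropout, alignment paralogy/duplication (each peak maps to at most one
locus per species), correlated conservation between classes (conservation
is independent of class unless configured otherwise), and realistic repeat
nesting. Passing recovery tests therefore demonstrates correctness of the
decision logic and statistics under the stated generative assumptions, not
robustness to every artifact of real alignments.

All generators draw from per-generator RNG streams derived
deterministically from the config seed, so outputs are bit-reproducible
given (seed, config) and stable under partial regeneration.

## Numerical and scale choices

Simulation sizes in the test-suite and acceptance script (2000 peaks, 2000
orthologs, 100–200 null replicates, 99–10,000 permutations depending on
stage) are the package's desk-scale study conditions: large enough that
binomial error on recovered fractions is ~1 percentage point and
permutation p granularity is at or below the thresholds being tested,
small enough to iterate quickly. CLI defaults keep the full-scale
parameters (10,000 overlap permutations, 100,000 synteny permutations,
1000 breakpoint iterations). Degenerate contingency tables (one row or
column) return χ² = 0, V = 0 rather than erroring. Empirical p-values use
add-one smoothing everywhere, so p ∈ [1/(n+1), 1] one-tailed and
[2/(n+1), 1] two-tailed, and no test can ever report p = 0.

## Known limitations

- Single-linkage clustering can chain distinct sub-peaks into one
  consensus interval when replicates tile densely; the span-based interval
  is then wider than any individual call.
- The permutation null for overlap testing ignores chromatin accessibility
  structure (GC, mappability); on real data a matched null would be more
  conservative.
- The breakpoint test's two-tailed doubling convention is slightly
  conservative for discrete counts; calibration tests assert the type-I
  rate within the 99% binomial band rather than exact nominal level.
- Fisher linkage-group tests treat genes as exchangeable units; clustered
  tandem duplicates would inflate enrichment on real annotations.
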
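# Methods

`pchic` post-processes significant promoter-capture Hi-C (PCHi-C)
interaction calls into consensus promoter-interaction maps and layers the
standard regulatory-genomics analyses on top. This note describes the
models and procedures, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Coordinate model

All coordinates are 0-based, half-open internally. BED and bedGraph inputs
keep their native 0-based convention; interaction tables and the TSV
catalogs (TSS, SNPs, eQTLs) are 1-based inclusive on disk and converted at
the I/O boundary. The restriction-fragment map is the universal scaffold:
fragments tile each chromosome exactly (first start 0, abutting intervals,
last end = chromosome length), carry stable indices increasing with
coordinate, and every analysis that needs a genomic unit — interaction
ends, peak overlaps, background draws — works in fragment indices. With a
4 bp cutter (MboI, GATC) the mean fragment is ≈422 bp, which is what gives
PCHi-C enhancer-level resolution.

## Capture design model

Bait selection reproduces the capture-design rules at the fragment/end
level only (probe sequences, adapters and vendor post-processing are not
modeled): candidate fragments must be longer than 200 bp and overlap a
±10 kb window around a transcription start site; TSSs closer than 1 kb are
deduplicated (the smallest coordinate is kept — the rule's tie-break is
otherwise unspecified); the four fragment ends closest to the TSS are
selected, each fragment contributing at most one end before any second end
is considered, ties broken by fragment index then left end. A gene's
*merged-TSS promoter region* is the envelope (min start, max end) of its
bait fragments; genes annotated to coordinate-identical regions are
reported individually.

## Consensus interaction calling

Per replicate, cis records spanning less than 10 kb
(promoter-region midpoint to distal-interval midpoint; the reference points
are a package choice, the threshold inclusive per "at least 10 kb") are
removed first. Records are then matched within genes: each distal interval
is extended by 1 kb on both sides and records whose extended intervals
intersect by ≥1 bp (extended-vs-extended, pairToPair-style) are clustered
by transitive closure. Only the distal end is extended; bait ends are
matched by gene identity. Because distal ends live on a line, the closure
equals a left-to-right sweep with a running maximum end, which is the
production path; the test suite checks it against a quadratic union-find
oracle. Clusters supported by at least two distinct replicates are emitted
with the un-extended envelope of member fragments as the distal interval
and the per-replicate maximum score.

A consensus interaction of cell type A is *A-specific* when no record for
the same gene in any single replicate of cell type B — including
sub-threshold ones — overlaps it under the same extension rule; otherwise
it is shared.

Categories of the non-promoter end: `P-promoter` when the distal interval
contains a TSS of a captured gene, `P-proximal` when it overlaps a bait
fragment without containing a TSS, `P-distal` otherwise.

One caveat discovered during testing: the *number* of consensus
interactions is not monotone in the extension parameter — a larger
extension can merge two independently supported clusters into one row. The
genomic span covered by the output is monotone, and that is the property
the suite asserts.

## TAD and compartment integration

TAD calls are consumed (TopDom-style BED with domain/boundary/gap labels;
the caller's window/resolution is provenance only). An interaction is
*intra-TAD* when its full span (leftmost start to rightmost end of either
end) lies inside one domain, *inter-TAD* when each end overlaps exactly one
domain and they differ; an end in a boundary or gap, or straddling a domain
edge, leaves the interaction unassigned, and unassigned interactions are
reported separately rather than folded into either class.

Compartments arrive as a signed-eigenvalue bedGraph (positive = A under the
caller's sign convention, which is never inferred here) or labeled BED.
Genes are anchored by their TSS. Switch classes between two cell types are
the cross-tabulation {stable_A, stable_B, A_to_B, B_to_A}; expression
contrasts use two-sided Wilcoxon rank-sum tests with the normal
approximation and tie correction, on DE-table log2 fold changes when
available or on a pseudo-count fallback log2((TPM₂+1)/(TPM₁+1)).

## Randomized-background enrichment

The observed statistic is the proportion of distinct promoter-interacting
fragments (fragment-level, un-extended intervals) overlapping at least one
feature peak by ≥1 bp. Peaks overlapping captured promoter regions are
removed first so the strong promoter peak signal cannot drive the result.
The null draws, per iteration, the same number of fragments uniformly
without replacement from a pool that excludes captured regions and
unmappable gaps; 100 iterations by default. Fold enrichment is
observed / null mean; the Z statistic uses the null mean and sd, and the
p-value is one-sided in the direction of the observed deviation (the
sidedness is a package choice). A zero-spread null yields p = NaN with a
warning. Every randomized result records its seed and iteration count.

Expression-binned enrichment groups genes by mean TPM into
{0}, (0,3], (3,25], (25,150], (150,∞) — boundary closure is a package
choice, right-closed. The 3×3 specificity grid crosses
{A-specific, B-specific, shared} interactions with
{A-only, B-only, shared} peak classes, where a peak is "shared" when it
overlaps any peak of the other cell type by ≥1 bp; each cell runs its own
matched background. The expression/peak-density analysis counts peaks
within ±300 kb of each TSS, restricted to genes with at least one
interaction, and reports Spearman's ρ with average ranks and a two-sided p.

## GWAS linking

LD r² is D²/(p_A p_a p_B p_b) on phased 0/1 haplotype vectors, identical to
the squared Pearson correlation of the indicators; monomorphic variants are
NaN, and unphased genotypes are rejected with an instruction to phase.
Tag SNPs are expanded to panel variants within ±50 kb with r² > 0.9 and
MAF ≥ 0.01; the tag itself is always retained and per-disease-class
de-duplication keeps the highest r². Population pooling is the caller's
responsibility (the panel arrives pre-pooled).

SNPs inside any captured promoter region are excluded before linking. A
SNP links to a gene when its position falls in the 1 kb-extended distal
interval of a consensus interaction for that gene (linking deliberately
uses extended intervals to be inclusive; enrichment analyses use
fragment-level ones). SNP-to-gene distance is |SNP − promoter-region
midpoint|; same-TAD means both points sit in the same domain interval; the
skipped-TSS count is the number of distinct non-target genes with a TSS
strictly between the SNP and the nearest promoter edge.

## Permutation and resampling statistics

*eQTL–loop enrichment.* eQTLs are pre-filtered to promoter-distal
positions ≥10 kb from their gene's TSS. Observed: among eQTLs overlapping
at least one consensus distal interval, the fraction overlapping an
interval whose gene matches the eQTL's gene. Null: per chromosome, each
promoter's whole interaction set is re-assigned to a different promoter by
a uniform derangement (rejection-sampled; an "independent redraw" variant
is exposed as an option), placing each interval at the new TSS with its
signed, strand-aware offset preserved; intervals crossing a chromosome
edge are dropped, the denominator recomputed, and a permutation in which
no eQTL overlaps any interval contributes 0. Both a Z-based normal-tail p
and the empirical p (rank+1)/(n_perm+1) are reported; 1000 permutations by
default. At least two promoters per chromosome are required (no
derangement exists otherwise).

*Gene-set resampling.* The observed annotated fraction of a target gene
set is compared to draws of the same size, without replacement, from the
eligible pool (genes with at least one promoter-distal interaction);
1000 iterations, Z-test as above. Gene exclusion lists (e.g.
histone-cluster genes) are caller-supplied, never hard-coded.

*Ontology enrichment.* Gene annotations are propagated to all ancestor
terms of the DAG before counting; each term gets an upper-tail
hypergeometric p (P(X ≥ k) with X ~ Hypergeom(N, K, n)) and
Benjamini–Hochberg adjustment across tested terms; terms with zero set
hits are skipped.

## Synthetic data

The generator produces every input the pipeline consumes, with planted
parameters recorded in truth tables. Defaults are the study conditions
where those are stated — 422 bp mean fragment size, 10 kb minimum span,
three replicates, ≈55% of loops shared between the two cell types — and
field-plausible desk-scale choices elsewhere:

* genome: two chromosomes, 6 + 4 Mb, exponential cut spacing (mean 422 bp);
* 120 genes at ≥25 kb spacing; loops per promoter ~ Poisson(6);
* loop spans ~ d^(−α), α = 1, truncated to [13 kb, 1.5 Mb] — sampled 3 kb
  above the 10 kb filter so replicate jitter and promoter-midpoint offsets
  never push an observed span below the threshold (otherwise boundary loops
  would bias recovery-rate checks);
* distinct anchors of one gene are kept ≥5 kb apart so consensus clusters
  map one-to-one to planted loops;
* replicate observation: dropout q = 0.2 per replicate, 5% probability of
  reporting an adjacent fragment (exercising the 1 kb tolerance), noise
  loops at 10% of the true-loop count;
* peaks: anchor fragments carry a peak with π_peak = 0.3 and draw nothing
  from the background; other fragments carry background peaks at rate
  β = 0.1 on average, modulated ×1.6 in A and ×0.4 in B compartments so
  local peak density couples to expression;
* TADs: lognormal domain sizes (median 640 kb), 40 kb boundaries, occasional
  120 kb gaps that double as the unmappable regions excluded from
  background pools;
* compartments: ~500 kb alternating intervals with signed eigenvalues; the
  second cell type flips 15% of intervals;
* haplotypes: 100 haplotypes; per tag SNP a 50 kb LD block copied from two
  maximally distinct founders with 2% per-site mutation — giving a sharp
  high-r² block around each tag; 60% of tags are planted inside distal
  anchors of loops;
* eQTLs: 200 variants, a fraction π_eqtl = 0.5 placed inside an anchor of a
  loop of their own gene, the rest uniform, promoter-distal and ≥10 kb from
  the gene;
* expression: log2 TPM = base N(3, 2) + 1.5·1[A compartment] +
  0.25·log1p(peak density) + replicate noise (sd 0.25), with 15% structural
  zeros; three replicates per cell type.

What the generator does **not** emulate: promoter–promoter loops (anchors
are always promoter-distal, so the P-promoter category is exercised only by
unit fixtures), read-level noise and CHiCAGO score distributions (scores
are uniform placeholders), trans contacts, realistic LD decay within
blocks, population structure, and genome-scale gene counts. Passing tests
therefore demonstrate the correctness and calibration of the machinery on
structured data, not performance on real libraries.

Fold-recovery caveat: the background pool necessarily contains the anchor
fragments themselves, so the estimated fold converges to π_peak/β only as
anchors become a small share of the genome. The parameter-recovery check
runs at 5000 promoters on a 325 Mb genome (anchors ≈3% of fragments),
where the planted ratio 3 is recovered as ≈2.8–2.9.

## Numerical choices and degenerate inputs

Uniform derangements are rejection-sampled. Ties in bait-end ranking break
by (distance, fragment index, side). Empty expression bins, zero-spread
nulls and monomorphic variants yield warnings and NaN rather than errors;
empty link sets yield all-NA summaries. Every randomized API takes an
explicit seed and the pipeline derives all stage seeds from one run seed,
so identical inputs and seed give byte-identical outputs (the manifest's
wall-clock timings are the only varying field).

## Problem sizes used by the test suite

The suite runs at desk scale: the shared bundle uses the default 10 Mb
genome (~24k fragments, ~770 loops); the dropout-recovery check uses 300
genes and ~4200 planted loop observations; enrichment calibration uses 200
repeated runs on a 5 Mb scaffold; the fold-recovery check uses the 5000-
promoter genome above; the eQTL calibration runs 100 shuffled datasets at
200 permutations each. The full suite completes in well under a minute of
compute per heavy test file.
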
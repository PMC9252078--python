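# Methods

## The enhancer-calling model

The caller follows the standard reporter-assay counting model.  Fragment
intervals (already aligned and deduplicated upstream, or deduplicated by
`dedup_fragments` on exact `(chrom, start, end, strand)` tuples) are
assigned to non-overlapping 600 bp genome tiles by the midpoint
`floor((start + end) / 2)`; midpoint assignment rather than overlap keeps
per-window counts conservative (a ~600 bp fragment would otherwise be
counted in two or three windows, breaking count conservation).

Each window is scored with the fold change
`FC = (c / C) / (max(i, pseudo) / I)` and the exact binomial upper tail
`p = P(X ≥ c)`, `X ~ Binomial(C, max(i, pseudo) / I)`, where `c`/`i` are
the window's cDNA/input counts and `C`/`I` the library totals.  The
pseudo-count (default 1) substitutes for the input count only when it is
zero — enough to keep strength finite without inflating the null elsewhere.
The binomial tail is computed via the regularized incomplete beta function
(scipy), never a normal approximation, and is verified in the test suite
against direct log-space term summation to 1e-10 relative error.

Multiple testing uses Benjamini–Hochberg over windows with at least one
fragment in either library; empty windows carry no information and would
only dilute the step-up.  Windows passing `FC > 1.0` (strict), `p < 0.001`
and `q < 0.1` merge into calls when adjacent or overlapping.  In
sliding-window mode (optional, step 100 bp) a merged run of overlapping
significant windows is wider than the underlying element by construction,
so the call is reported at its summit — the maximum-strength constituent
window — as peak-calling tools conventionally do; tiled mode reports the
full merged span.

Replicate concordance is the Pearson correlation of `log2(FC + 0.01)`
across windows informative in at least one replicate; the log transform
stabilizes the heavy right tail of fold changes (a linear-scale option is
kept).  Consensus across replicates and cell lines pairs calls at strictly
greater than 50% reciprocal overlap and collapses each pair to its union
span; the non-redundant union merges all calls at any positive overlap.

## The synthetic study and why its defaults look the way they do

The generator is the package's benchmark instrument: every stage's claims
are demonstrated on its output, so its generative assumptions matter more
than its realism.

**Input library.**  Fragment midpoints are uniform over the genome; lengths
are Normal(600, 100) clipped to [200, 1200] bp, a stand-in for a sonicated
library with ~600 bp median fragments (the length distribution is exposed
in `SimConfig`).

**cDNA library — pool resampling.**  The cDNA library is a weighted
with-replacement resample of the realized input pool: every cDNA fragment
is one of the transfected molecules, drawn with probability proportional to
the activity of the planted enhancer containing its midpoint.  This is what
the assay physically does — transcripts can only arise from transfected
plasmids — and it has a decisive statistical consequence: conditional on
the input counts, the caller's binomial null is exact, so p-values are
calibrated and BH controls the false-call rate.  Had the two libraries been
sampled independently, the plug-in estimate of the input fraction would be
noisy and the binomial test anticonservative at any depth (its per-window
false-positive rate at `p < 1e-3` is then ~1.5–2% regardless of coverage,
because the test treats an estimated success probability as known).  The
expected cDNA/input count ratio in a planted window of activity `a` is
`a / (1 + Σ(a_e − 1)·L_e / G)`, verified by Monte-Carlo in the tests
(≈ 3.99 for a single 4× enhancer of 600 bp in 1 Mb).

**Scale.**  Defaults are 2 chromosomes × 2.5 Mb, 200 genes, 20 enhancers of
600 bp with activities uniform in [3, 6], and 1e5 fragments per library.
The genome size is chosen so that per-window input depth (~12 fragments
per 600 bp window) matches a ~45 M-fragment library on a ~2.5 Gb genome —
the regime the caller is meant for — under a ~1000× scale-down.  Doubling
the genome at fixed library size halves the depth and visibly costs
sensitivity at the weak end of the activity range.

**Enhancer placement.**  Planted elements are aligned to the 600 bp
analysis grid by default (`enhancer_grid`, settable to `None`), so each
corresponds to exactly one window.  This is deliberate benchmark design:
with tiled windows, a mid-window element splits its signal across two
windows, and a merged 1200 bp call has exactly 50% reciprocal overlap with
the 600 bp truth — which the strict > 50% matching rule rejects — so
recovery metrics would conflate detection failures with bookkeeping
artifacts.  Elements are kept at least two windows apart and placed in
repeat vs non-repeat windows by a mixing fraction (default 0.5).

**Genome annotation.**  Repeats are laid down as alternating exponential
gaps and lognormal element lengths to a target fraction (default 40%,
corrected to within ±2%); each element is a TE with probability 0.5, with
LINE-dominant class weights, otherwise a simple repeat.  Genes are
non-overlapping three-exon models with 5'UTR, first intron and 3'UTR.

**Tracks, expression, QTLs, Hi-C.**  ChIP/ATAC tracks are Gamma noise with
mean 1 in 100 bp bins; planted peaks multiply the signal by 4–8× over the
enhancer ± 300 bp wherever the per-enhancer mark flag is set, and
background peaks mimic genome-wide peak calls.  Expression is log-normal
FPKM with a silent fraction (default 0.4).  QTLs (50 kb–1.2 Mb) partly
cover planted enhancers, plus deliberately oversized records to exercise
the half-chromosome filter.  Hi-C matrices at 40 kb resolution follow
`E[contact] = C / (1 + d)` with Poisson counts, TAD blocks of 6–16 bins
with 1.5× intra-block contact, and 5× boosts for planted enhancer–gene
pairs.  TAD boundaries never split a planted pair, encoding the stylized
fact that enhancer–promoter contacts are preferentially intra-TAD; linked
genes are chosen at looping distance (80–400 kb) so a planted contact is
neither within-bin nor implausibly long-range.

All simulators are pure functions of `(config, seed)`; each draws from its
own RNG stream keyed by `(seed, operation)`, so adding a simulator never
perturbs the others and repeated runs are byte-identical.

What the generator does **not** model: sequence content (no FASTA, no GC
bias), PCR duplication (emitted fragments are unique molecules; a duplicate
rate can be layered on for testing `dedup_fragments`), mappability,
copy-number variation, replicate-level batch effects, or cell-line-specific
activity (both simulated cell lines share the planted truth).  Passing
benchmarks therefore demonstrate the statistical machinery under the
model's assumptions, not robustness to those real-data artifacts.

## Annotation and chromatin conventions

A single category per enhancer is assigned by priority: repetitive >
TSS-proximal > 5'UTR > 3'UTR > first intron > other intron > exon >
intergenic.  Repeat-first priority makes the categories mutually exclusive
in the way repeat-dominated genomes are usually summarized; the order is a
config list.  TSS-proximal means TSS ± 2 kb — a conventional promoter
window, config-exposed since no single value is canonical.  TE subclass is
the largest-overlap class, ties broken LINE > SINE > LTR > DNA.  Relative
enrichment divides the category fraction by the feature's genomic
background fraction, so abundance alone gives FC = 1.

Accessibility is binary ≥ 1 bp ATAC-peak overlap.  Chromatin-state classes
(active-only / repressive-only / both / neither) likewise use peak overlap
— subsets of enhancers are naturally reported as counts under a binary
rule; a signal-threshold alternative (fold ≥ 1.5) is provided.  Profiles
anchor at the call midpoint with 100 × 100 bp bins over ± 5 kb; midpoint
anchoring keeps variable-length calls comparable, and calls whose window
crosses a chromosome edge are dropped and counted.  Per-enhancer fold
enrichment is `(mean ChIP + 0.1) / (mean INPUT + 0.1)` over the call span
(mean, not max, config-exposed).  The Wilcoxon rank-sum test enumerates all
labelings exactly up to 12 observations (counting both tails at least as
extreme as observed) and uses the tie- and continuity-corrected normal
approximation above that.

## Trait linkage

QTLs longer than half their chromosome are dropped — such records carry no
positional information.  Non-redundant QTL regions are exact-coordinate
deduplicates (records sharing coordinates but differing in trait count once
as a region but contribute each trait); a merge-overlapping alternative
sits behind a flag, since "non-redundant" has no single canonical meaning.
Contact significance is a distance-stratified Poisson upper tail: expected
contact for a bin pair is the chromosome-wide mean at the same bin
distance, absorbing the power-law decay; this is the simplest defensible
expected model and is isolated behind the `contact_significance` surface
for replacement by e.g. a negative-binomial fit.  The gene anchor is the
TSS-containing bin — promoter contact is the claim being tested.  A
candidate link requires both TAD co-membership (one TAD containing both
midpoints) and contact `p < 0.05`.

## Numerical and reporting conventions

Coordinates are 0-based half-open everywhere internally; GTF and QTL tables
(1-based inclusive) convert at their readers.  Overlap operations ignore
strand.  "> 50% reciprocal overlap" is strict, matching the sharing rule's
wording; a non-strict mode exists.  Percentages round half-up to two
decimals.  Degenerate inputs fail loudly: empty intervals, inverted
coordinates, negative FPKM, overlapping TADs, unknown chromosomes and
out-of-range matrix bins all raise with the offending file and line where
applicable.

## Problem sizes used in tests and the acceptance script

Recovery and null-calibration benchmarks run the default desk-scale study
(2 × 2.5 Mb, 1e5 fragments/library) over 10 and 20 seeds respectively;
linkage end-to-end uses 5 seeds; unit tests use a further-shrunk study
(2 × 0.5 Mb, 2e4 fragments).  These sizes keep the full suite under a
minute while leaving per-window depth at the regime the caller targets.

## Known limitations

The binomial model conditions on the input counts and therefore assumes
the sequenced input library is the transfected pool; when the sequenced
input is a shallow sample of a much more complex pool, the input fraction
is an estimate and the test is anticonservative — deeper input sequencing,
not a smaller p threshold, is the remedy.  The distance-stratified Poisson
contact test ignores overdispersion of Hi-C counts and the TAD-level
elevation of contact frequency, so intra-TAD pairs are mildly
anticonservative when TAD structure is strong.  Consensus pairing is
pairwise between the first two replicates per cell line; designs with more
replicates reduce to the first two.
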
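# Methods

This note documents the models and numerical choices behind
`its2barcode`: what each stage computes, why the defaults are what they
are, and what the synthetic benchmark does and does not demonstrate.

## Amplicon annotation

The ITS2 amplicon produced by the universal primer pair spans three
regions: a partial 5.8S gene, the ITS2 spacer, and a partial 28S gene.
Because the flanking gene fragments are strongly conserved, their lengths
are constant across closely related taxa; annotation therefore uses a
**fixed-flank rule** — first 84 bp = partial 5.8S, last 141 bp = partial
28S, remainder = ITS2 — and requires at least 451 bp (84 + 226 + 141,
with 226 bp the shortest ITS2 the rule accepts). `annotate_regions` is
the single interface point for annotation, so a profile-HMM backend
against an rDNA model could be substituted without touching downstream
code. GC content excludes ambiguity codes from numerator and denominator,
making the statistic invariant to ambiguous base calls.

Primer excision is a minimum-Hamming sliding-window search (no indels
inside a primer; ties resolved leftmost for the forward, rightmost for
the reverse primer). Reverse primers are conventionally written either
5'→3' on the antisense strand or 3'→5' on the sense strand; both
interpretations are searched (reverse-complement and plain complement of
the printed string) and the better match wins, with the interpretation
logged.

## Alignment

Pairwise alignment is affine-gap global alignment (Gotoh): a gap of
length *g* costs `gap_open + (g-1)·gap_extend`. Defaults
(match 1, mismatch −1, open −4, extend −1) favor conservative gap
placement, appropriate for near-identical barcodes. The implementation
requires `gap_open ≤ gap_extend ≤ 0`, which licenses a running-maximum
scan for the horizontal gap state (re-opening a gap can never beat
extending one) and makes the row-vectorized dynamic program exact.
Traceback ties resolve diagonal > up > left, so alignments are
bit-reproducible. Identical symbols score as matches (including identical
ambiguity codes); any other pair is a mismatch.

The multiple alignment is progressive: identical sequences are grouped
first (they align trivially and barcoding datasets are haplotype-heavy),
a neighbor-joining guide tree is built from pairwise K2P distances
between unique sequences (p-distance fallback if a guide pair
saturates), and profiles are merged postorder by the same affine DP on
column-frequency profiles — "once a gap, always a gap". All tie-breaking
is lexicographic in sample ids. Row order follows the input. The MSA's
1-based columns are the coordinate system for every downstream site
report; column numbers are therefore alignment-dependent, as in any
column-based analysis.

## K2P distances

Distances use Kimura's two-parameter correction,
`d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`, with P the transition (A↔G, C↔T) and Q
the transversion proportion among compared sites. Columns where either
member of a pair carries a gap or ambiguity code are excluded for that
pair only (**pairwise deletion**, the default of the mainstream barcoding
toolchain); indels contribute nothing to the distance and are surfaced by
the variation module instead. Saturation (a non-positive logarithm
argument) raises a typed error by default; a configuration switch emits
`+inf` flags instead, for exploratory use. Species summaries are
unweighted arithmetic statistics over sample pairs: within-species pairs
for the intraspecific block (absent, not zero, for singleton species) and
all mixed pairs for the interspecific block.

## Variation and diagnostic sites

Columns are classified disjointly: gap present ⇒ *indel*; else ≥2
distinct bases ⇒ *substitution*; else *monomorphic* — so the three counts
partition the alignment width and "variable = substitution + indel"
arithmetic always adds up. Each substitution column contributes one count
to the bucket of its unordered base set, so 2-state and 3-state buckets
coexist. A multi-column gap counts one indel site per column by default;
an event-based view merging adjacent columns with an identical gap
pattern is available (`indel_events`) but is not the default, keeping the
site arithmetic simple. Ambiguity codes are treated as distinct symbols
that never match a base, and columns carrying them are flagged.

A site is **diagnostic** for a species when all its samples share one
symbol there (gap allowed) and no sample of any other species carries
that symbol — strict character-based diagnosis: a single such column
suffices to authenticate the species.

## Classification

*Nearest distance*: the query takes the species of its minimum-K2P
reference; distances are computed once on the full MSA and reused across
leave-one-out folds, which is exact because removing a row does not
change the remaining pairwise distances under pairwise deletion.
*BLAST1-style*: the query takes the species of its top-scoring
Smith–Waterman local alignment (match 2, mismatch −3, gap open −5,
extend −2 — megablast-like scoring). Reference sets in this setting are
tens of sequences, so the exact local alignment replaces heuristic seeded
search while preserving top-hit semantics. In both methods a cross-species
tie at the optimum yields `AMBIGUOUS`, which evaluation counts as a
failure; species with a single sample are evaluated (and necessarily
fail) by default, with a switch to exclude them, listed in the report.

## Neighbor joining and bootstrap

NJ joins the pair minimizing `Q(i,j) = (r−2)·d(i,j) − R_i − R_j`, with
the standard branch-length formulas, lexicographic tie-breaking on
cluster representatives, and negative branch-length estimates clamped to
zero (deficit logged). One deliberate refinement: **zero-distance taxa
are agglomerated first**. A set of identical sequences forms a star of
zero-length edges; every resolution of that star — including ones that
interleave an outside taxon among the identical samples — fits the
distances equally well, so leaving the choice to Q-value noise makes
species clades a lottery in bootstrap replicates. Joining
indistinguishable taxa first resolves the tie deterministically and
reduces to plain NJ whenever no off-diagonal zero exists (in particular
on the additive matrices used to verify exactness).

Bootstrap support resamples alignment columns with replacement (seeded),
rebuilds K2P + NJ per replicate, and reports the recovery percentage of
each internal bipartition of the full-data tree. Replicates whose
resampled distances saturate are dropped but still counted in the
denominator. Supports below the display threshold (default 50%) are kept
on the tree and suppressed only in rendered output. The tree is unrooted;
midpoint rooting is applied for display only.

Expected support is limited by character support: a clade separated from
its nearest neighbor by *k* substitution-visible columns (gap columns are
invisible to K2P distances) loses all of them in roughly `e^−k` of
replicates, so splits hinging on one or two columns cap near 63–86%
regardless of implementation. `min_haplotype_separation` measures *k*,
and the package calls a species split **central** when `k ≥ 3` — those
are the splits for which ≥90% support is a meaningful expectation.

## Synthetic data generator

The generator emulates the structure of a regional barcoding survey of
ten closely related species (74 vouchers with per-species sample counts
13, 6, 14, 6, 11, 5, 10, 4, 3, 2 by default):

1. ancestral sequence of 453 bp drawn i.i.d. at GC 0.55;
2. a Kingman-coalescent species tree, branch lengths rescaled so the
   expected pairwise leaf distance — tree path plus the planted
   diagnostics' contribution of `2k/L` per pair — equals the target
   interspecific mean (default 0.03 substitutions/site);
3. a continuous-time K2P substitution process down each branch,
   simulated exactly via per-site Poisson event counts; each event is a
   transition with probability κ/(κ+2) (default κ=4, i.e. a 2:1
   transition bias in events, matching the C/T-heavy tallies typical of
   ITS2);
4. one private diagnostic transition per species planted at sites still
   monomorphic across species;
5. at most one short indel (1–4 bp, probability 0.3) per terminal
   branch, placed between species haplotypes only and never erasing the
   species' own diagnostics — reproducing the few-bp length spread of
   real amplicons;
6. every sample an exact copy of its species haplotype: zero
   intraspecific variation, the empirical configuration this kind of
   survey reports. A knob (`intraspecific_mutations`) exists to break the
   barcoding gap deliberately.

All stochastic draws flow from one seeded generator, and every mutation
is recorded as an event; `GroundTruth.replay()` re-derives the emitted
haplotypes byte for byte, which the tests assert across 50 seeds.

What passing on this generator shows — and what it does not: the
synthetic data realizes the idealized barcoding-gap scenario (shared
haplotypes, well-separated species, diagnostic characters), so 100%
leave-one-out success and universal monophyly are the *correct* outputs
there, and the tests verify the pipeline reaches them. Real surveys add
length variation from sequencing quality, ambiguity codes, intragenomic
ITS2 paralogs and possible species non-monophyly; none of those failure
modes is claimed to be covered by the green suite, though the ambiguity
and singleton-species code paths are exercised separately.

## Problem sizes and numerical choices

The reference study conditions used by the test suite and the acceptance
script are the generator defaults above; trees use 100 bootstrap
replicates in tests (the CLI default remains 1000) and the calibration
check averages 50 seeds. Alignment-score traceback comparisons use a
relative tolerance of 1e−9; NJ exactness on additive matrices is asserted
at 1e−9; the K2P closed form is asserted at 1e−12. Degenerate inputs have
defined behavior throughout: empty alignments, all-gap columns,
singleton species, saturated pairs, sub-minimum amplicons and <3-taxon
trees each raise a typed error or produce a documented notice rather
than silently proceeding.

## Known limitations

* Only the K2P model is implemented; no rate heterogeneity or model
  selection.
* Fixed-flank annotation presumes the conserved flank lengths of the
  target group; divergent taxa would need an HMM backend.
* Progressive MSA has no iterative refinement; column coordinates from
  different parameter sets are not comparable.
* The BLAST1 surrogate computes exact local alignments and is quadratic
  per pair — appropriate for reference sets of tens to hundreds of
  sequences, not databases.
* Bootstrap counts bipartitions strictly; it does not collapse
  zero-length branches into polytomies before comparison.
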
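# Methods

## Scope and data model

`annoteval` evaluates predicted gene structures against reference
structures using genomic coordinates only: no sequence, no phase/frame
semantics, no UTRs. The unit of comparison is the gene → mRNA → CDS
hierarchy. Exons are the coding segments of a transcript; introns are
derived, not stored, as the gaps between consecutive CDS segments of one
transcript (a gap must be ≥ 1 nt to count as an intron — abutting segments
produce none; the minimum is configurable in `derive_introns`). A gene's
span runs from its minimum CDS start to its maximum CDS end over all
isoforms. Because reference annotations rarely state whether gene rows
include UTRs, using CDS extrema makes prediction and reference spans
commensurable by construction.

Coordinates are 1-based inclusive externally (GFF3); overlap arithmetic
uses the 0-based half-open `lo`/`hi` view of each interval so no `+1`
appears in the overlap math. Features on strand `.` cannot participate in
the strand-aware classifier and are rejected (or skipped with a warning in
lenient mode). CDS phase is parsed and round-tripped but never consulted.

## Gene outcome classification

Each reference gene receives exactly one outcome from {exact, inexact,
missing, merged, fragmented}. The defect rules interact, and the
classification is made a partition by giving them a fixed precedence, each
step consuming its participants:

1. **merged** — a prediction whose span covers ≥ 2 not-yet-consumed
   references, each by strictly more than `merged_ref_coverage` (default
   0.5) of the reference length. The denominator is the reference *span* by
   default; `merged_use_footprint` switches it to the CDS footprint for
   annotations with very long introns.
2. **fragmented** — a remaining reference overlapped by ≥ 2 remaining
   predictions, each with at least `fragment_pred_coverage` (default 0.5,
   non-strict) of *its own span* inside the reference span. "Separate
   portions" is enforced as pairwise fragment overlap ≤
   `fragment_mutual_overlap_max` of the shorter fragment (default 0 —
   disjoint). When candidates conflict, a maximal compatible subset is
   formed greedily left-to-right; fewer than two survivors means no
   fragmentation and the locus falls through to one-to-one matching, where
   the largest-overlap prediction wins and the rest go unassigned.
3. **one-to-one matching** — remaining overlapping prediction×reference
   pairs are resolved by maximum-weight assignment
   (`scipy.optimize.linear_sum_assignment`) on span overlap; zero-overlap
   pairs are never created. A pair is *exact* when both span boundaries
   coincide, else *inexact*. Structure-level exactness is reported at the
   exon/intron level instead, so a gene with perfect boundaries but wrong
   internal structure is an exact gene with imperfect exon tallies.
4. **leftovers** — references never consumed are *missing*; predictions
   never consumed are reported under a distinct `unassigned_prediction`
   outcome rather than as a gene-level false positive, so both the
   "genes have no FP class" and the "false positive gene predictions"
   presentations are derivable from one output.

Matching is restricted to identical (contig, strand): opposite-strand
overlap is never a match, since coding orientation defines the gene.
Overlapping genes within one input set are tolerated (and logged at info
level) — the assignment step resolves them.

Precedence merged → fragmented → match was chosen because each defect rule
is strictly more specific than the match rule, and merged before fragmented
makes the two mutually exclusive per locus; consumption guarantees that
outcome counts partition the reference set, which downstream partition laws
(agreement cells, per-1000 normalization) rely on.

## Transcript, exon, and intron tallies

Within each classified gene group (merged and fragmented groups pool all
participating genes), transcripts are matched one-to-one by maximizing the
total number of CDS nucleotides shared between paired transcripts —
an optimal assignment, since greedy matching is demonstrably suboptimal on
crossing overlap patterns. Overlap is computed on CDS footprints, not
spans, so long introns cannot fabricate overlap. Ties between equal-weight
assignments are broken toward coordinate-sorted (reference, prediction)
order by an integer bonus too small to trade against one nucleotide of real
weight. Unmatched reference transcripts count *missing*; surplus prediction
transcripts count *false positive*; all their exons and introns count
missing/false-positive wholesale.

Within each matched transcript pair, exons are matched one-to-one by
maximum overlap (for collinear non-overlapping segments this coincides with
greedy matching by position), introns likewise. Exon tallies carry a
breakdown by position class — initial (5′-most in transcription direction,
i.e. last by coordinate on the minus strand), internal, terminal, single —
with matched/missing classed by the reference segment and false positives
by the prediction segment. `exact_matched` counts the coordinate-identical
subset of matches, giving feature-level Sn/Pr at exact stringency.

## Accuracy statistics

`confusion_counts` supports four stringencies: *nucleotide* (per-base CDS
membership per strand, computed by merged-interval sweep and verified
against a literal per-base bitmap oracle in the tests), *exon* and *intron*
(exact-coordinate feature matches over distinct coordinates, so
isoform-shared features count once), and *transcript* (exact CDS-chain
matches). `sn_pr_f1` applies the 0/0 → 0 convention throughout: an empty
comparison scores zero rather than raising, and F1 = 0 iff TP = 0.

Per-gene F1 scores (the ECDF material) are computed at nucleotide
stringency between each reference gene and the prediction genes grouped
with it by the classifier; missing genes score 0. Reports label the
stringency used.

## The DTS two-sample test

The DTS statistic is the variance-weighted integrated absolute ECDF
difference: with pooled sorted values x₍₁₎…x₍ₙ₊ₘ₎, sample ECDFs F̂ and Ĝ
and pooled ECDF Ĥ,

DTS = Σₖ |F̂(x₍ₖ₎) − Ĝ(x₍ₖ₎)| · (x₍ₖ₊₁₎ − x₍ₖ₎) / √(Ĥ(x₍ₖ₎)(1 − Ĥ(x₍ₖ₎)))

Terms where Ĥ ∈ {0, 1} contribute nothing (the pooled minimum is reached
at k = 1 with Ĥ ≥ 1/(n+m) > 0; k = n+m is excluded). Tied pooled values
are handled implicitly: the spacing factor vanishes inside a tie run, so
cumulative counts by sorted position equal the ECDFs wherever a term
contributes. The statistic is symmetric, zero iff the multisets coincide,
shift-invariant, and exactly linear under joint positive rescaling — the
scaling law is asserted in tests. Published implementations may normalize
by a different constant; any constant cancels in the permutation p-value,
which is why the test, not the raw statistic, is the contract.

Significance comes from permutation: pooled values are re-split into groups
of the original sizes; the p-value uses the add-one estimator
(1 + #{permuted ≥ observed})/(B + 1), which cannot return 0 and keeps the
test level-valid. Permutations are vectorized (random subset masks over the
pooled sorted order, block-wise cumulative sums), so 500-trial calibration
experiments run in seconds. With B = 500 and α = 0.05 the achieved
rejection probability under the null is 25/501 ≈ 0.0499; the acceptance
check requires the empirical type-I error over 500 seeded null trials
(n = m = 30, standard normal) to fall inside the exact binomial 99 %
interval around 0.05.

The two-proportion z-test uses the pooled variance estimate, two-sided
normal p-values, no continuity correction; a degenerate pooled proportion
(0 or 1) has zero variance and returns (z = 0, p = 1) rather than NaN. The
implementation is the closed form; `statsmodels.proportions_ztest` serves
as an independent cross-check in the tests, as does a 50-digit `Decimal`
evaluation.

## Gold-standard extension from BUSCO

`parse_busco_table` reads the `full_table.tsv` dialect (comment lines,
busco id / status / sequence / score / length, trailing columns tolerated,
Missing rows without a sequence). The extension logic: genes split into
Swiss-Prot-curated and uncurated; the fragmented-to-complete proportion
(Fragmented / (Fragmented + complete-class)) is compared between groups
with the z-test; the gold standard is the union of curated genes and
uncurated genes with a complete-class status. "Complete-class" defaults to
{Complete, Duplicated} — a duplicated protein is individually complete — 
with a strict Complete-only mode. Curated genes are kept regardless of
their BUSCO status (curation is the higher evidence tier), one
complete-class record suffices when several share a sequence id, and the
reported percent increase is 100·|added|/|curated| (undefined and reported
as absent when no curated genes exist).

## Evidence concordance and agreement partitions

The 2-of-3 selector treats two gene models as concordant when their
(contig, strand, ordered CDS coordinate chain) signatures are identical —
exact structure agreement, not overlap. One representative per signature
supported by ≥ `min_agree` distinct sources is returned with provenance.

The agreement partition classifies each prediction set against the
reference independently and assigns every reference gene to the subset of
pipelines whose outcome for it is exact or inexact; cells are disjoint and,
with the matched-by-none remainder, sum to the reference total. Counts are
reported raw and per 1000 reference genes, and a parallel partition over
defective outcomes (merged/fragmented/missing) is emitted. Pipelines
lacking whole contigs contribute `missing` there, with a warning.

## Synthetic annotations

The generator emulates a compact eukaryotic genome annotation: genes placed
left-to-right per contig with intergenic gaps sampled uniformly in
[`min_intergenic_gap`, 2·`min_intergenic_gap`] (default 200 nt), 1–8 coding
exons of 50–300 nt, introns of 40–400 nt, strands i.i.d. at 0.5, optional
isoforms formed by skipping one internal exon. These defaults give mean
gene lengths around 1.5 kb and guarantee non-overlapping genes with known
separations. One seeded NumPy generator drives all sampling; outputs are
byte-identical per seed.

Defect injection assigns disjoint gene subsets in the fixed order merged,
fragmented, missing, inexact (the remainder exact), with integer values as
counts and floats < 1 as fractions of the gene count. Merges join adjacent
same-strand pairs into one model whose intergenic gap becomes an intron, so
each reference is covered at fraction 1.0 > 0.5; splits cut a multi-exon
gene at an intron into two disjoint predictions fully inside the reference
span (self-coverage 1.0 ≥ 0.5). Inexact jitter shifts both span boundaries
by at least 1 nt, capped at just under half the flanking intergenic gap
(so a jittered gene can only ever overlap its own reference) and at one
less than the boundary exon length (so no segment degenerates). This
bounding is deliberate: synthetic truth must be unambiguous under the
classifier's stated thresholds, which is what makes 100 % label recovery a
meaningful end-to-end contract rather than a tuning exercise.
Boundary-ambiguous layouts (partial coverage, overlapping fragments) are
exercised separately with hand-built fixtures.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: nucleotide sequence and splice-site signals,
UTRs, overlapping or nested real gene arrangements, biased intron length
distributions, assembly fragmentation, and annotation errors more subtle
than coordinate displacement. Recovery rates on synthetic data are a
correctness check of the classifier's logic, not an estimate of its
behaviour on any organism.

## Problem sizes and numerical choices

The acceptance computations use fifty 1000-gene genomes (two 3-Mb contigs
each; 100 merged pairs, 100 splits, 100 missing, 200 inexact per genome),
500 random transcript groups of ≤ 6 transcripts per side for the
enumeration oracle, 200 random ≤ 10-kb instances for the bitmap oracle,
1000 random configurations for the z-test precision check (tolerance
1e-10 against 50-digit decimal arithmetic), and 500 permutation-test null
trials at B = 500 — sizes chosen so the whole suite recomputes in well
under a minute on one CPU while keeping every count large enough for the
stated tolerances to bite.

Assignment weights are integer nucleotide counts, so optimality comparisons
are exact; tie-breaking bonuses are scaled integers, never floating
epsilons. GFF3 output orders rows by (contig, start, gene id), making
serialization canonical and the parse∘write∘parse identity testable as
structural equality.

## Known limitations

- GTF and attribute dialects other than ID/Parent GFF3 are not parsed.
- The classifier's merged test uses reference spans by default; annotations
  with enormous introns may prefer the footprint denominator.
- Exon/intron "exact" Sn/Pr treat features as coordinate sets (distinct
  coordinates), so features shared by many isoforms count once.
- `unassigned_prediction` conflates novel genes with pure false positives;
  distinguishing them needs evidence beyond the reference annotation.
- The DTS permutation test assumes exchangeability under the null, as any
  permutation test does; heavily tied score distributions reduce its
  resolution.
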
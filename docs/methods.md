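# Methods

`mirslice` implements a complete small-RNA analysis for a species that has
an assembled transcriptome but no reference genome: annotation of known
miRNAs by homology, validation of hairpin precursors, discovery of novel
miRNA candidates, and degradome-based target calling with slice-site
evidence categories.  Everything runs against transcript coordinates;
there is deliberately no genome-mapping stage.

## Read preprocessing

Reads are 3'-adapter-ligated single-end small-RNA reads.  Cleanup is:

1. **Adapter removal** — the leftmost occurrence of an exact >= 8-nt
   adapter prefix (anywhere in the read), or of the full adapter with
   one tolerated mismatch, and everything 3' of it are removed.
   Restricting mismatch tolerance to full-length matches is what makes
   trimming idempotent.  A read that is pure adapter is dropped.
2. **Quality trimming** — a 6-nt window slid from the 3' end; the read is
   cut so the retained prefix contains no window with mean Phred < 15.
   A remnant shorter than the window is held to the same mean rule, which
   makes trimming idempotent.  Defaults (15/6) are the usual small-RNA
   settings; both are parameters.
3. **Length selection** — 18–28 nt retained (the bound excludes reads of
   29 nt and longer); both bounds are parameters.

Identical clean reads are collapsed into one record per distinct sequence
with per-library counts; read-count totals are conserved exactly.  The
per-library profile reports redundant/non-redundant length histograms,
reads-per-million, and the **complexity index**: distinct sequences of a
length class divided by total reads of that class.  The index is 1.0 for
an all-unique class and approaches 0 for a redundant one; in real monocot
libraries the 21-nt class (dominated by abundant miRNAs) runs at roughly
half the complexity of the 24-nt class.  The term is used in the
literature without a formula; distinct/total is this package's
definition, chosen because it reproduces that reported relationship.

## Known-miRNA annotation

Each collapsed read is compared to a reference mature set (miRBase-style
FASTA; U/T normalised, all comparisons in DNA space) by ungapped sliding
alignment.  A hit requires overlap >= 18 nt and <= 2 substitutions —
equivalent to the ~90%-identity setting used by short-read aligners for
this task.  The best hit minimises mismatches, then maximises overlap,
then takes the lexicographically smallest reference name, making
annotation deterministic and order-independent.  The implementation is a
seed-and-verify scan (exact 6-mer seeds; the pigeonhole principle
guarantees any qualifying alignment contains one), verified in tests
against an exhaustive brute-force oracle.

Annotated sequences are retained only when expressed with **>= 5 reads in
>= 3 of the 4 libraries**.  The libraries are treated as biological
replicates, so multi-library support is the main false-positive control.
The 5-read rule is applied per library (not summed); both thresholds are
parameters.  Abundance is reported as TPM = reads per million clean
library reads, so TPM over all collapsed reads of a library sums to 1e6.

## Precursor validation

Potential pri-miRNA hosts are all full-length occurrences of a mature in
the transcriptome with <= 2 substitutions, searched on both strands
(assembled transcripts can be antisense).  Around each occurrence,
candidate windows of 60–300 nt (step 20, mature placed toward either end
with 10 nt of context) are folded with ViennaRNA and accepted when:

- (a) the mature lies on one arm (no paired mature base has its partner
  on the other side of the mature, i.e. it does not span the loop);
- (b) at most 4 mature bases are unpaired;
- (c) no bulge larger than 3 nt inside the mature:star duplex;
- (d) MFEI <= -0.85;
- (e) length <= 300 nt.

with AMFE = MFE/length x 100 and MFEI = AMFE / GC%.  The -0.85 MFEI bound
is the published empirical boundary separating miRNA hairpins from tRNA
(about -0.64), rRNA (about -0.59) and mRNA folds; all five rules are
parameters.  These criteria are a reconstruction of the conventions of
hairpin-validation tools, whose exact internal rules are not published in
citable form.  An accepted window is then **trimmed to the stem-loop that
actually contains the mature** (the span of the mature's outermost
partners, padded to the 60-nt floor), refolded and revalidated; this
makes reported precursor intervals coincide with the underlying hairpin
rather than an arbitrary window, which in turn makes cluster spacing
measurable.  Among accepted candidates the minimal-MFEI (then shortest)
one is reported.

The **star** strand is read off the dot-bracket pair table with 2-nt 3'
overhang geometry: the star's 3' end pairs mature position 3 and the
mature's 3' end pairs star position 3 (positions extrapolated along the
helix when an anchor base is unpaired).  Of the two duplex strands, the
one with the lower summed read count is labelled star; at equal counts
the 5' arm stays mature.  Precursors sharing a transcript form a
polycistronic cluster; the report gives the gap between consecutive
precursor intervals (negative and flagged when they overlap).

`FoldingEngine` is pluggable: `ViennaEngine` (thermodynamic MFE,
memoised) is the production engine; `PairMaxEngine` is a base-pair
maximisation folder with a -1 kcal/mol-per-pair proxy used only to test
structural plumbing — MFEI acceptance is only meaningful thermodynamically.

## Novel-candidate discovery

Reads not annotated by homology are screened against user-supplied
blacklist FASTAs (rRNA/tRNA/snoRNA, organellar genomes): any read
occurring within a blacklist sequence on either strand with <= 1
substitution is dropped.  This sequence-level screen replaces
covariance-model scanning; the blacklist content is the user's choice, so
Rfam-derived sets plug in directly.  Survivors are size-selected to
18–23 nt (the upper bound excludes 24-nt heterochromatic siRNAs and is
exclusive; it is configurable because long 23–24-nt miRNAs processed by
DCL3 do exist and a user may wish to keep them).  Reads then undergo
greedy longest-first clustering (the strategy of CD-HIT): sorted by
length, abundance, then sequence, each read joins the first cluster whose
representative shares a 5-mer and aligns ungapped over the shorter read
at >= 85% identity.  An abundance floor (total count >= 2, configurable)
is applied before clustering: singletons cannot contribute meaningfully
to the cluster-summed support rule and dominate the clustering cost.

A cluster whose summed counts pass the 3-library/5-read rule becomes a
candidate if its representative yields a valid precursor; candidates
resolving to the same precursor interval are merged.  A candidate whose
predicted star sequence is itself present among the collapsed reads (any
count) is tier "high-confidence" — star evidence is the strongest sign of
genuine Dicer processing under current plant-miRNA annotation criteria.
Star and isomiR reads of known loci can surface here; they resolve to the
same hairpins and are counted as true positives when scoring against the
generator's truth table.

## Degradome analysis

Degradome (PARE) reads capture the 5' ends of uncapped cleavage remnants.
Each read's first 20 nt (the read length is a parameter; real protocols
vary) is matched exactly against the transcriptome, sense strand;
multi-mapping prefixes increment every location (a unique-only flag
exists).  This yields a per-transcript position -> count profile and a
global mapping rate.

For a miRNA of length n, every transcript window of length n is scored by
an Allen-style penalty: per miRNA position, mismatch 1.0 and G:U wobble
0.5, doubled at positions 2–13; ungapped; cutoff 7.0.  The predicted
slice position is the target base pairing miRNA nucleotide 10 — the 5'
end of the downstream remnant.  A site is emitted only when the profile
has >= 1 read exactly there, so scanning profiled positions is exactly
equivalent to scanning all windows (tested against exhaustive
enumeration).  Default output keeps the single best site per
miRNA–transcript pair (lowest category, then highest count, then lowest
score); multi-site mode reports every supported site, which is how double
slice sites on one transcript surface.

Sites are ranked into five evidence categories based on the count c at
the slice position: c = 1 -> category 4; c > 1 and equal to the
transcript maximum -> 0 (unique maximum position) or 1 (tied maximum);
otherwise 2 if c is above the average depth and 3 if at or below it.  At
exact equality with the average the site is category 3, following the
verbatim category definitions.  Average depth is the mean over positions
with >= 1 read by default (an all-positions mean is available by flag).

The p-value is empirical: for each of 100 (seedable) mononucleotide
shuffles of the miRNA, the same transcriptome/profiles are re-scanned;
p = (1 + #shuffles yielding a site with category <= observed and score <=
observed) / (1 + 100).  The add-one estimator bounds p below by 1/101 ≈
0.0099.  The shuffle null is this package's construction — the cited
degradome pipelines do not document theirs — and no p cutoff is applied
to the output (reported targets in the field include p-values well above
0.05); filtering is left to the user.

## Catalogue statistics

Composition reports pool nucleotides across all positions of all mature
sequences (per-sequence averaging available by flag), with GC% and
positional distributions at positions 1, 10 and 11 (the 5' identity
relates to AGO sorting; 10/11 face the slice site).  Percentages are
given to 2 decimals using largest-remainder rounding so every table sums
to exactly 100.00.  Positional denominators count only sequences long
enough to have the position.  Precursor summaries report length min/max
and the mean rounded half-up to integer nt, plus MFE and MFEI ranges.

## The synthetic-data generator

The generator emulates the study design end-to-end so every stage is
testable without downloads: four treatment libraries ("C", "P", "Na",
"NaP") treated as replicates; a read-length profile peaking at 24 nt with
a 21-nt secondary peak and 66% of background mass in 20–24 nt; 200
transcripts (400–2500 nt, GC 0.45); 20 planted hairpins of which a
quarter are held out of the reference as novel, including one transcript
hosting two hairpins spaced exactly 94 nt apart (the polycistronic
cluster); rRNA/tRNA/chloroplast contaminants at 10% of each 50k-read
library; mature:star expression at 10:1 with mean 300 mature
reads/library (implied top TPM near 10^4); abundant non-hairpin decoy
reads as discovery negatives; and a 100k-read degradome in which 30% of
reads start exactly at planted slice positions.

Planted hairpins are perfect stems (mature + loop + reverse complement,
loop drawn from 18–150 nt so precursors span about 60–192 nt; G/C clamps
at the mature ends prevent terminal fraying) and are **verified with the
folding engine at generation time**: the embedded locus must validate as
a precursor in its transcript context, with redraws up to a retry cap.
Decoys are conversely verified *not* to validate, so truth labels are
correct by construction.  Library reads are drawn in a single multinomial
per library over channels (each mature/star, each decoy, a contaminant
channel, background), so per-class counts sum exactly to the requested
depth; reads are insert + adapter truncated to 50 nt at constant Phred 40
(an optional low-quality 3' tail exercises quality trimming).  Degradome
reads are exact 20-nt transcript subsequences; category-4 targets receive
exactly one peak read; an optional unmappable fraction of random reads
emulates the ~33% of real degradome reads that fail to map.  Fixed seeds
give byte-identical FASTA/FASTQ output.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: sequencing error and quality
noise; isomiR-generating imprecise Dicer processing (isomiRs arise only
as background fragments overlapping hairpins); locus-level redundancy of
24-nt siRNA classes (background fragments are uniform, so the 24-nt
complexity index sits near 1.0 rather than the ~0.65 of real libraries,
although the 21 ≈ half-of-24 relationship is preserved); imperfect
hairpins with natural bulges/wobbles; differential expression between
treatments (the analysis pools treatments, so none is simulated); and
antisense/genomic context, since no genome exists for the target species.

## Numerical and design choices

- Coordinates: 0-based half-open internally, 1-based inclusive in all
  reports and truth tables.
- Ties are broken deterministically everywhere (alignment: mismatches ->
  overlap -> name; precursor: MFEI -> length -> start; site: category ->
  count -> score -> position; star at equal counts: 5' arm mature).
- Degenerate inputs: empty libraries produce all-zero profiles; an empty
  blacklist passes through with a warning; zero-depth simulations yield
  empty FASTQs; empty reference or catalogue sets raise.
- The discovery size bound, support thresholds, duplex penalties, MFEI
  cutoff, shuffle count and degradome read length are all exposed as
  parameters with the defaults above.
- Problem sizes: the default configuration (200 transcripts, 4 x 50k
  reads, 100k degradome reads, 100 shuffles) is the scale at which the
  acceptance run and recovery tests operate; the unit-test fixture scales
  the same design down (40 transcripts, 4 x 5k reads) with expression
  reduced proportionally.

## Known limitations

- Precursor acceptance rules are a published-convention reconstruction,
  not a reimplementation of any specific tool's internals; borderline
  hairpins may be judged differently than by MIReNA or miRDeep-class
  tools.
- The homology stage reports isomiRs only as distinct collapsed
  sequences; there is no explicit isomiR enumeration.
- Degradome site search is ungapped and exact-match for mapping; bulged
  target sites and SNP-bearing transcripts are out of reach.
- The p-value null shuffles the miRNA, not the degradome; strongly
  structured target regions can make it conservative.
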
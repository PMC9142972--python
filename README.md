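# mirslice

Small-RNA miRNA annotation, hairpin precursor validation and
degradome-based target calling for species that have an assembled
transcriptome but **no reference genome** — the situation of most
non-model plants, including polyploid bioenergy grasses whose genomes
remain unassembled.

`mirslice` is a Python library for bioinformaticians who have:

- several small-RNA libraries (FASTQ),
- a de novo transcriptome assembly (FASTA),
- a reference set of mature miRNAs (miRBase-style FASTA),
- optionally a degradome/PARE library (FASTQ),

and want a catalogue of known miRNAs, validated pre-miRNA hairpins,
novel miRNA candidates with star evidence, and degradome-supported
target slice sites — all in transcript coordinates.  A synthetic-data
generator plants hairpins, a polycistronic cluster, contaminants and
degradome peaks with full ground truth, so the whole pipeline is
testable offline.

## The methods at the core

**Known-miRNA annotation.** Clean reads (adapter-trimmed, quality
window 15/6, 18–28 nt) are collapsed and aligned ungapped to reference
matures: overlap ≥ 18 nt, ≤ 2 substitutions.  A sequence is annotated
only if expressed with ≥ 5 reads in ≥ 3 of 4 libraries (libraries are
treated as biological replicates).  Abundance is TPM = reads per million
clean reads.

**Precursor validation.** Mature occurrences in the transcriptome
(≤ 2 mismatches, both strands) seed 60–300-nt candidate windows folded
with ViennaRNA.  A window is a valid pre-miRNA when the mature sits on
one arm of the stem-loop with ≤ 4 unpaired bases and no duplex bulge
> 3 nt, and

```
AMFE = MFE / L × 100          MFEI = AMFE / GC%          MFEI ≤ −0.85
```

which separates miRNA hairpins from tRNA (MFEI ≈ −0.64), rRNA (≈ −0.59)
and mRNA folds.  The star strand follows 2-nt 3′-overhang duplex
geometry, and the lower-abundance strand keeps the star label.

**Novel discovery.** Unannotated reads are screened against
rRNA/tRNA/snoRNA/chloroplast blacklists (≤ 1 mismatch, either strand),
size-selected (< 24 nt), clustered greedily (word size 5, 85% identity,
CD-HIT style), support-filtered and validated through the same precursor
machinery; candidates whose star sequence is itself sequenced are
"high-confidence".

**Degradome target calling.** Read 5′ ends are mapped exactly to the
transcriptome; each annotated miRNA is scanned with an Allen-style
penalty score (mismatch 1, G:U 0.5, doubled at positions 2–13, cutoff
7); the slice site is the base pairing miRNA nucleotide 10.  Sites are
ranked into categories 0–4 (0 = unique maximum peak on the transcript,
4 = single read) and given an empirical p-value from 100 mononucleotide
shuffles of the miRNA.

## Worked example

`examples/01_simulate_study.py` builds a small synthetic study and
prints the planted ground truth:

```
40 transcripts, 8 planted miRNAs (2 held out of the reference as novel)
polycistronic cluster on TR1: hairpins [61,180] and [275,381] -> spacer 94 nt
planted target: ado-miR150a-5p slices TR8 at position 616 (intended category 0)
```

`examples/04_precursor_validation.py` then locates one planted mature
and validates its hairpin:

```
mature ado-miR152a-5p located on TR2 [61,81] (+)
precursor [61,246] length 186 nt, arm 5p
MFE -76.1 kcal/mol | AMFE -40.9 | MFEI -0.86 | GC 47.3%
CGTGCAGGCGCCCCTTGCGTCC...GGGGCGCCTGCACG
(((((((((((((((((((((((.(((((((((...)))...)))))))))))))))))))
predicted star: TGGACGCAAGGGGCGCCTGCA
```

The MFEI of −0.86 clears the −0.85 hairpin bound (a tRNA control folds
near −0.64), the mature occupies the 5′ arm, and the predicted star is
the 2-nt-offset reverse complement of the mature — the signature of a
genuine Dicer substrate.  The other examples cover library profiles
(`02`), the known catalogue with TPM (`03`), degradome target tables
with t-plots (`05`) and novel-candidate discovery (`06`).

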
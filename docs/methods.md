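# Methods

## Engineering model

A gene model is a set of CDS isoforms on one strand, 0-based half-open
internally (GFF3 1-based closed at the I/O boundary), with the stop codon
included in the CDS. The tag site is the stop codon shared by the majority of
isoforms; on a tie the 3'-most stop with respect to the strand is taken and
flagged. The insertion point abuts the last sense codon, so the cassette is
fused in frame and the endogenous stop codon plus 3'UTR remain immediately
downstream.

Tagging is modelled as the two-step wet protocol:

1. **Pre-tag insertion** via 50-bp homology arms flanking the insertion
   point. Arm matching is exact string comparison against the fosmid with up
   to 2 substitutions tolerated per arm; the oligo's bases (including
   synthesis errors) are propagated into the construct — this is the step
   where arm-clustered clone mutations arise. Length-changing oligo defects
   abort the insertion.
2. **Cassette exchange** replaces the selectable pre-tag marker with the full
   tag cassette through their shared terminal flank epitopes; no new
   sequence is synthesised, so no new errors are introduced.
3. **Flip-out** excises the FRT-flanked selection operon between the two
   direct-orientation FRT sites, leaving a single in-frame 34-nt FRT scar.

`verify_frame` asserts: inserted length ≡ 0 (mod 3); no stop codon in the
insert read in coding frame; the endogenous stop codon immediately follows
the insert; all sequence downstream of the insertion point is byte-identical
to the input fosmid. Every construct carries an edit log that replays from
the base fosmid, and deleting the tag interval restores the input exactly.

The cassette registry shipped in `fostag/data/cassettes.yaml` is a synthetic
stand-in with the correct *structure* (flank epitopes shared with the
pre-tag, stop-free in-frame segments, FRT–marker–FRT operon, minimal 34-nt
FRT); it is not any particular published cassette sequence.

## Pooling and validation model

96-well plates are pooled into 8 row and 12 column barcoded pools; every
clone is sequenced in exactly two independent pools, and clone identity
within a pool is resolved by mapping location (each fosmid carries a unique
genomic insert). `deconvolve` returns the Cartesian intersection of positive
rows and columns; a single-positive row/column pair identifies the well
uniquely (verified exhaustively for all 96 wells).

Mapping is simplified seed-and-extend: a k-mer index (k = 21) proposes
(reference, diagonal) candidates; edlib infix alignment (edit distance ≤ 6
over a 2×100 bp pair's reads) extends them, keeping unique best hits. Because
the tag cassette is identical across clones, tag-internal reads multi-map by
construction; pairs are therefore resolved through the mate with fewer
candidate references (the clone-unique genomic mate), mirroring
concordant-only paired mapping. An anchor landing on the FRT–marker–FRT
sequence lets the genomic mate pick its clone instead.

Pair classes: **tag_anchored** (one mate overlaps the tag, outer distance in
the concordant window, reverse-forward orientation), **genomic_only**,
**unflipped_evidence** (one mate on the marker operon, span computed in
un-flipped-molecule coordinates), **discordant**, **unmapped**. PCR
duplicates are removed as identical placement of both mates. Variants are
pileup events in the tag region ± `roi_pad`; alignment paths through indels
are not unique, so non-match operations within 3 reference bases of an indel
are merged, trimmed to the minimal allele and left-aligned — truth mutations
are recorded left-aligned too, so truth and call keys compare exactly.

A candidate with support *s* at site depth *n* gets the phred-scaled binomial
tail score −10·log₁₀ P(X ≥ s | n, e) with assumed error e = 0.01, kept at
score ≥ 20. Confirmation requires the identical (position, kind, ref, alt)
with ≥ 3 supporting reads in both pools of the well. Verdict precedence:
`no_data` (no tag-anchored pair in either pool) → `unflipped` → `mutated`
(any confirmed variant) → `mutation_free_full` (every tag base covered by
anchored pairs from the two pools combined) → `mutation_free_partial`.
Percentages are reported over clones with data, rounded half-up to one
decimal.

## Parameter defaults and rationale

| parameter | default | rationale |
|---|---|---|
| arm length | 50 bp | standard recombineering oligo arm length |
| min flank | 2500 bp | clone must give the mate-pair insert room on both sides of the gene |
| insert window | 2200–3700 bp | explicit concordance bounds for a ~3000 ± 1000 bp library; the looser (2000, 4000) reading is selectable, and concordant pairs under the narrow window are a subset of the wide one |
| read length / orientation | 2×100 bp, RF | mate-pair libraries read outward; reverse-forward after standard processing |
| min anchor | 20 bp | a tag overlap shorter than the seed size carries no tag-specific information |
| assumed error | 0.01 | conservative upper bound for base-call error; inflating it only makes calling stricter |
| score cutoff | 20 | phred 20 ≡ P < 1% under the error null; a singleton error at 30× scores ≈ 5.9 and is rejected |
| min support per pool | 3 | cross-pool ∧ ≥3 makes a false confirmation require ≥3 identical random errors in *each* pool at the same site and allele |
| roi_pad | 1000 bp | covers the homology arms and the flank a 3 kb pair can anchor into |
| k-mer / max edits | 21 / 6 | 21-mers are effectively unique in random flanks; 6 edits tolerate 0.5–1% error over 100 bp with margin |
| duplicate rule | identical placement of both mates | with ~3 kb fragments and base-resolution starts, placement collisions between genuine fragments are rare at these depths; duplicates are exact placement copies by construction |

The un-flipped flag defaults to **cross-pool** (evidence pairs in both pools)
for symmetry with variant confirmation; a literal single-pool mode is
available (`--unflipped-mode single_pool`).

## What the simulator emulates — and does not

Emulated: per-clone defects drawn once before pooling (both pools sequence
the same molecule — the fact that makes cross-pool confirmation meaningful),
defect strata (arm substitutions, junction errors within 10 bp of the
insert edges, cassette-internal events, short indels ≤ 3 bp, un-excised
operon with its coordinate shift), fragment-length normal clipped to
[2·read_len, construct length], fragments restricted to those touching the
tag region of interest, uniform substitution sequencing error, exact-copy
PCR duplicates, per-pool barcodes, FASTQ output and full truth tables.

Not emulated: base-quality profiles (qualities are constant), indel
sequencing errors, chimeric/junction artefacts, GC or positional coverage
bias, barcode hopping, cross-well contamination, fragment-end biases, and
real ~40 kb fosmid backbones — synthetic fosmids are 8 kb so that desk-scale
runs stay in minutes while both flanks still exceed the 2.5 kb minimum.

## Numerical and reproducibility choices

- All randomness flows through `numpy` `SeedSequence` streams keyed by
  (seed, purpose label, pool, clone), so components are independently
  reproducible; duplicates come from their own stream layered on top of a
  fixed unique fragment set, which is why verdicts are exactly invariant
  when only `dup_rate` changes (verified at 0.2 → 0.5).
- Coverage uses difference arrays (O(1) per read, cumulative sum on demand).
- The binomial tail uses `scipy.stats.binom.sf`; scores are capped at
  phred 1000, and underflow to probability 0 maps to the cap.
- Percentages use decimal half-up rounding (`Decimal.quantize`), matching
  conventional report arithmetic, e.g. 9580/10995 → 87.1.

## Limitations

- The mapper is intentionally minimal (no affine gaps, no base-quality
  weighting, no proper MAPQ model); real-data use is expected to go through
  `ingest_sam` with an external aligner.
- Variant calling is frequency-free: a heterogeneous well (mixed culture) is
  not modelled — support is compared only against the error null.
- `mutation_free_full` requires 100% tag-base coverage by anchored pairs;
  there is no probabilistic coverage model behind the full/partial split.
- Un-flipped detection relies on reads mapping to the operon sequence and is
  quantified only as evidence-pair counts, not operon dosage.
- Single-plate scope: pool barcodes and deconvolution are per plate;
  cross-plate batch effects are out of scope.
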
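# Methods

## Scope and model

`varsim-lite` validates sequencing secondary analysis by construction: it
perturbs a reference genome with a known phased variant set, simulates reads
whose true origins are tracked exactly, and scores external aligner/caller
output against that truth. The package deliberately separates three layers —
variant model and normalization, diploid construction with an exact
coordinate map, and validation — so each is testable against an independent
oracle (naive string edits, brute-force enumeration, exhaustive matching).

## Coordinates and the variant model

VCF-facing positions are 1-based with the usual anchor-base convention for
indels and symbolic SVs; all internal arithmetic is 0-based half-open. A
record is one ALT on one sample; multi-allelic lines are decomposed on read.
`svlen` is signed: negative for deletions, the gained length for insertions
and duplications (for a duplication with c copies of a span s, the gain is
(c−1)·s; the on-disk SVLEN stores s, the conventional VCF meaning, with the
copy count in a DUPCOPIES INFO key). Inversions store the inverted span.
Records with genotype 0|0 are rejected: a truth set only contains carried
variants.

## Normalization

Many VCF spellings encode one edit, especially in short tandem repeats.
Canonical form here is: shared trailing bases trimmed, then shared leading
bases trimmed down to the single anchor base, with indels left-aligned by
the classic pull-in-the-previous-base loop. The procedure is idempotent and
sequence-preserving; the test suite verifies both against a string-edit
oracle, and verifies canonicity by brute-force enumerating every equivalent
encoding of several hundred repeat-context indels and checking they collapse
to one record. Symbolic inversions and duplications have a single spelling
and pass through; a symbolic insertion with no resolved sequence cannot be
left-aligned and also passes through until resolved. Block substitutions
other than same-length MNPs are rejected rather than guessed at.

## Sampling

Truth sets are drawn from a database uniformly without replacement: each
category (SNV, indel < 50 bp, and the four SV sub-types) is shuffled with
the seeded generator and accepted in order unless the candidate footprint
comes within `min_gap` (default 10 bp) of an accepted one. Shortfalls log a
warning rather than fail, since a small database is a legitimate input.
Heterozygous probability defaults to 0.6 — roughly the het/hom proportion of
a human genome against the reference — and het variants land on either
haplotype with probability ½. Uniform (rather than frequency-weighted)
sampling is a deliberate simplification; population allele frequencies are
out of scope.

## Diploid construction and the genome map

Each haplotype is built in a single left-to-right pass over its variants,
emitting map blocks as it goes: `SEQ` blocks for untouched (or
SNV/MNP-substituted) stretches, `INS_NOVEL` (zero reference width) for
insertions, `DEL_GAP` (zero host width) for deletions, `INV` (strand −) for
inversions, and `DUP_COPY` blocks — extra tandem copies whose reference
interval repeats that of the original span, placed immediately after it.
Blocks tile host space exactly; `SEQ` reference intervals are strictly
increasing. A substituted `SEQ` block carries its variant id so that
reconstruction can re-apply the substitution: rebuilding every haplotype
through `lift_interval` plus the recorded novel/substituted sequences is
byte-identical, which is the map's standing integrity check (run in tests
and in the acceptance script). Overlapping variants are a hard error —
sampling already guarantees separation, and silently resolving overlaps
would corrupt the truth.

The map is a function host→reference: a duplicated base lifts to its single
source location. The on-disk format is a versioned TSV, one block per line.

## Read simulation and truth metadata

Pairs are drawn uniformly over haplotypes (weighted by length): fragment
length ~ Normal(frag_mean=400, frag_sd=60) truncated to
[read_len, 2·frag_mean], mate 1 from the fragment's left end forward, mate 2
from the right end reverse-complemented. Pair count is
round(coverage · total_length / (2 · read_len)). The error model is
substitution-only at a flat rate with constant base qualities
Q = round(−10·log10(max(rate, 1e-4))); cycle-dependent profiles and indel
errors are the extension point of the adapter contract (`RawPair` /
`ReadSource`), through which the built-in simulator itself is routed.

Each pair's randomness comes from a generator seeded by (seed, pair_index).
This makes output bytes independent of the shard partition — a 1-shard and a
4-shard run concatenate identically — which is a stronger guarantee than a
per-shard stream and is what the sharding invariant actually demands.

True alignments: a mate's host interval is lifted; every resulting segment
that carries reference bases is an admissible anchor (that segment aligned
at its own reference start, the rest soft-clipped). When all segments are
plus-strand, reference-adjacent `SEQ`/`DUP_COPY` pieces, the read instead
has a single full-length alignment. A read wholly inside a novel insertion
is anchored at the insertion breakpoint. The record is packed as
zlib+base64url into the read name; names that would exceed the 254-character
SAM limit fall back to a sidecar TSV keyed by read id.

## Alignment validation

Primary records only; secondary/supplementary are counted separately.
A record is correct when its leftmost aligned base (soft clips excluded)
is within wiggle W (default 20 bp — tolerant of end-trimming, small enough
not to absorb misplacements) of any admissible anchor of either mate.
Checking both mates makes the verdict immune to mate-flag swapping, and
strand is not required to match, since a clipped anchor may be reported in
either orientation. Undecodable names count as unknown reads and leave the
denominator: validating a BAM that mixes in real reads should not tank the
score. MAPQ is recorded in the verdict stream but never consulted.

## Variant-call validation

Small variants (SNV/MNP, indels < 50 bp) match only on exact normalized
identity; genotype comparison is off by default (site-level reporting).
SVs match when the type agrees, breakpoint starts are within 100 bp and the
reciprocal size ratio is at least 0.8; insertion content is not compared,
as callers rarely report full inserted sequences. Matching is one-to-one:
candidate pairs are taken greedily in order of increasing breakpoint
distance (ties: larger size ratio, then truth position), then completed to
maximum cardinality by augmenting paths. Pure greedy matching can strand a
truth variant whose only compatible call was consumed by a closer, contested
pair; augmentation removes exactly that failure mode, and the suite checks
the result against an exhaustive optimal matcher on small fixtures whose
optimum is unique.

Degenerate cells: PPV with zero calls is null, TPR with zero truth is null;
F1 is 0.0 if either input is 0 and null if either is null — empty cells must
never read as perfect. Stratification bins truth-derived entries (TP/FN) by
truth size and FPs by call size, over bins
1, 2–5, 6–20, 21–50, 51–100, 101–200, 201–500, 501–1000, 1001–2000,
2001–5000, >5000 bp (configurable; SNVs to the unit bin).

## Tumor/normal workflow

One seed drives both passes, so the germline truth — and the normal genome —
is byte-identical between them; the test suite asserts this at the file
level. Somatic variants colliding with germline footprints are dropped and
reported. Contamination is modeled as a global read-mixture fraction α
(tumor purity): each emitted pair is tumor-origin with probability α,
sequentially without replacement within each pool, with origin recoverable
from the sample tag in the read id. Per-variant subclonal fractions are out
of scope — one α per run. Somatic scoring reuses the germline comparator and
additionally flags false positives that match a germline truth variant as
"germline leaks" (they remain false positives for precision).

## Synthetic fixtures

The generator emulates the *inputs* of a real study: an i.i.d. reference at
a target GC (default 0.5) with embedded short-tandem-repeat tracts, a
database of SNVs/indels/SVs valid against it, and a donor pool for insertion
sequences. A quarter of database indels sit at the right edge of repeat
tracts in a deliberately right-shifted encoding so normalization failures
surface immediately. What the fixtures do **not** model: realistic human
repeat and GC landscapes, mutation spectra, allele-frequency structure,
sequencing-error profiles. Passing tests therefore demonstrate correctness
of the bookkeeping (coordinates, truth, scoring) under controlled
conditions, not performance of any aligner or caller on real data.

Default problem sizes — a 100 kb contig with a 50 SNV + 20 indel + 5 SV
truth set at 50x for the germline end-to-end run, and a 50 kb contig at 22x
per sample for the tumor/normal pair (≥ 10,000 pairs per pool for mixing) —
keep the full pipeline fast enough to run routinely while leaving every
variant type represented.

## Known limitations

- Translocations, interspersed duplications and breakend notation are not
  modeled; duplications are tandem only.
- Single-sample VCFs; paired-end reads only.
- The alignment verdict is positional; CIGAR-level base accuracy and proper
  pairing are not judged.
- Haplotype-aware (allele-sequence) variant comparison is not implemented;
  matching is record-level after normalization.
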
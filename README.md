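# varsim-lite

Simulation-based validation for genome-sequencing secondary analysis.
`varsim-lite` synthesizes a phased diploid genome carrying known germline
(and optionally somatic) variants — SNVs, small indels and structural
variants (deletions, insertions, inversions, tandem duplications) — simulates
paired-end reads from it, and then scores any aligner's BAM and any caller's
VCF against that ground truth. It is aimed at developers and evaluators of
alignment and variant-calling pipelines who need a truth set with known
provenance rather than a consensus call set.

## How it works

**Simulation.** Variants are sampled from a database VCF (uniformly, without
replacement, with a minimum reference-space gap between accepted footprints)
and assigned phased genotypes: heterozygous with probability `het`, placed on
haplotype A or B with probability ½. Insertions without a known sequence draw
one from a donor pool. Applying the truth set to the reference yields two
haplotype FASTAs plus a **genome map**: an ordered list of blocks, each
mapping a host (perturbed-genome) interval to a reference interval with a
strand and a feature label (`SEQ`, `INS_NOVEL`, `DEL_GAP`, `INV`,
`DUP_COPY`). The map is an exact liftover: rebuilding every haplotype from
the reference through it is byte-identical, and haplotype lengths obey

    len(host) = len(ref) + Σ ins − Σ del + Σ (copies−1)·dup_span

Reads are simulated at a target mean depth with Normal(μ, σ) fragment
lengths and a flat per-base substitution-error rate. Each read's **true
reference alignments** are computed through the map and packed into its name
(`vs:<read_id>:<b64url payload>`). A read lifting to k reference segments
(for example one straddling an inversion edge) gets one admissible alignment
per anchorable segment, the others soft-clipped, so an aligner is scored
correct whichever side of the breakpoint it anchors.

**Validation.** Alignments: a primary record is correct if its leftmost
aligned base is within a wiggle tolerance W (default 20 bp) of any true
anchor; results are tallied overall and per region label. Variant calls are
first normalized to a canonical form (shared bases trimmed, indels
left-aligned), then matched one-to-one against the truth: small variants
exactly, SVs tolerantly (same type, breakpoint distance ≤ 100 bp, reciprocal
size ratio ≥ 0.8). Reports give TPR = TP/(TP+FN), PPV = TP/(TP+FP) and
F1 = 2·TPR·PPV/(TPR+PPV), stratified by variant type and size bin.

**Tumor/normal.** The germline workflow runs twice under one seed (so the
germline truth is byte-identical), the second pass adding a somatic variant
set. Reads from the two genomes are mixed at tumor purity α to model normal
contamination; somatic calls are validated against the somatic truth, with
false positives that match a germline variant flagged as germline leaks.

## Worked example

Everything below is synthetic — no downloads needed:

```sh
varsim-lite fixture --seed 1 --out-dir fx
varsim-lite sample --db fx/db.vcf --ref fx/ref.fa --pool fx/ins_pool.fa \
    --n-snv 50 --n-indel 20 --n-del 2 --n-ins 2 --n-dup 1 --n-inv 1 \
    --seed 1 --out truth.vcf
varsim-lite build --ref fx/ref.fa --truth truth.vcf --out-dir sim
varsim-lite reads --ref fx/ref.fa --truth truth.vcf \
    --coverage 4 --err 0 --seed 1 --out-prefix sim/reads
```

which prints

```
76 truth variants -> truth.vcf
diploid genome (201418 bp over 2 haplotype contigs) -> sim
4028 pairs (4.0x) -> sim/reads_1.fq, sim/reads_2.fq
```

76 variants — exactly the 50 + 20 + 6 requested — a ~201 kb diploid genome
over the 100 kb fixture contig, and 4,028 read pairs at the requested 4x. After aligning `sim/reads_*.fq` with any aligner:

```sh
varsim-lite val-align --bam aln.bam --sidecar sim/reads_truth.tsv --out align.json
varsim-lite val-vcf --truth truth.vcf --calls calls.vcf --ref fx/ref.fa --out vcf.json
```

Feeding back the truth-derived alignments and the truth VCF itself gives the
expected perfect score, e.g.

```
fraction_correct=1.0000 -> align.json
type          bin     tp     fn     fp      tpr      ppv       f1
...
SNV             1     50      0      0   1.0000   1.0000   1.0000
TOTAL                 76      0      0   1.0000   1.0000   1.0000
```

`fraction_correct` is the share of judgeable primary alignments within W of
a true anchor; each table row is one variant-type × size-bin cell.

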
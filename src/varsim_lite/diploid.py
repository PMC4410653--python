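"""Diploid genome construction and the perturbed<->reference coordinate map.

Applying a phased truth set to a reference yields two haplotype ("host")
sequences plus a :class:`GenomeMap`: an ordered, host-contiguous list of
blocks per host contig, each mapping a host interval to a reference interval
with a strand and a feature label. The map is the liftover backbone used to
compute true read alignments and is more expressive than a chain file: it
represents inversions (strand -), tandem duplications (several host blocks
sharing one reference interval) and novel insertions (zero reference width)
explicitly.

Feature semantics:

``SEQ``
    host_len == ref_len, strand +. May carry a variant_id when the block is
    an SNV/MNP substitution (host bases differ from the reference there).
``INS_NOVEL``
    ref_len == 0; ref_start records the insertion breakpoint.
``DEL_GAP``
    host_len == 0; host_start records the join point on the host.
``INV``
    host_len == ref_len, strand -.
``DUP_COPY``
    host_len == ref_len, strand +; an extra tandem copy whose reference
    interval duplicates that of the originating span.
"""
from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .reference import Reference, revcomp, write_fasta
from .variants import Variant, VarType, write_vcf

log = logging.getLogger(__name__)

MAP_FORMAT_VERSION = "1"

SEQ = "SEQ"
INS_NOVEL = "INS_NOVEL"
DEL_GAP = "DEL_GAP"
INV = "INV"
DUP_COPY = "DUP_COPY"
FEATURES = (SEQ, INS_NOVEL, DEL_GAP, INV, DUP_COPY)


class MapInvariantError(ValueError):
    """The genome map violates its well-formedness invariants."""


class OverlapError(ValueError):
    """Two variants occupy overlapping reference footprints."""


@dataclass(frozen=True)
class MapBlock:
    host_contig: str
    host_start: int  # 0-based
    host_len: int
    ref_contig: str
    ref_start: int  # 0-based
    ref_len: int
    strand: str  # '+' or '-'
    feature: str
    variant_id: str | None = None

    @property
    def host_end(self) -> int:
        return self.host_start + self.host_len

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_len


@dataclass(frozen=True)
class Segment:
    """One lifted piece of a host interval (host order preserved)."""

    ref_contig: str
    ref_start: int
    length: int  # host bases covered (0 for a DEL_GAP crossing)
    strand: str
    feature: str
    variant_id: str | None = None
    block_offset: int = 0  # offset of this piece within its block (host bases)


@dataclass(frozen=True)
class NovelInsertionPoint:
    """Lift result for a host base inside a novel insertion."""

    ref_contig: str
    breakpoint: int  # 0-based reference breakpoint


class GenomeMap:
    """Per-host-contig ordered block lists; supports exact point/interval lift."""

    def __init__(self, blocks: dict[str, list[MapBlock]]):
        self.blocks = blocks
        self.host_lengths = {
            c: (bl[-1].host_end if bl else 0) for c, bl in blocks.items()
        }
        # binary-search indexes over blocks with nonzero host width
        self._solid: dict[str, list[MapBlock]] = {}
        self._starts: dict[str, list[int]] = {}
        self._solid_idx: dict[str, list[int]] = {}
        for c, bl in blocks.items():
            idx = [i for i, b in enumerate(bl) if b.host_len > 0]
            self._solid_idx[c] = idx
            self._solid[c] = [bl[i] for i in idx]
            self._starts[c] = [bl[i].host_start for i in idx]

    # -- liftover -----------------------------------------------------------

    def lift_point(self, host_contig: str, host_pos: int):
        """Map one host base to (ref_contig, ref_pos, strand) or a
        :class:`NovelInsertionPoint`. The map is a function: exactly one
        result per position."""
        if not 0 <= host_pos < self.host_lengths[host_contig]:
            raise ValueError(f"{host_contig}:{host_pos} out of range")
        i = bisect.bisect_right(self._starts[host_contig], host_pos) - 1
        b = self._solid[host_contig][i]
        off = host_pos - b.host_start
        if b.feature == INS_NOVEL:
            return NovelInsertionPoint(b.ref_contig, b.ref_start)
        if b.feature == INV:
            return (b.ref_contig, b.ref_start + (b.host_len - 1 - off), "-")
        return (b.ref_contig, b.ref_start + off, "+")

    def lift_interval(self, host_contig: str, start: int, end: int) -> list[Segment]:
        """Split [start, end) at block boundaries and lift each piece.

        Zero-width DEL_GAP blocks strictly inside the interval are reported as
        zero-length segments so callers can see deletion crossings.
        """
        if not (0 <= start < end <= self.host_lengths[host_contig]):
            raise ValueError(f"{host_contig}:[{start},{end}) out of range")
        out: list[Segment] = []
        blocks = self.blocks[host_contig]
        i = bisect.bisect_right(self._starts[host_contig], start) - 1
        # walk the full (gap-inclusive) block list from the solid hit
        idx = self._solid_idx[host_contig][i]
        for b in blocks[idx:]:
            if b.host_start >= end and b.host_len > 0:
                break
            if b.host_len == 0:
                if start < b.host_start < end:
                    out.append(Segment(b.ref_contig, b.ref_start, 0, "+",
                                       DEL_GAP, b.variant_id))
                continue
            s = max(start, b.host_start)
            e = min(end, b.host_end)
            if s >= e:
                continue
            off = s - b.host_start
            ln = e - s
            if b.feature == INV:
                rs = b.ref_start + (b.host_end - e)
                out.append(Segment(b.ref_contig, rs, ln, "-", INV,
                                   b.variant_id, off))
            elif b.feature == INS_NOVEL:
                out.append(Segment(b.ref_contig, b.ref_start, ln, "+",
                                   INS_NOVEL, b.variant_id, off))
            else:
                out.append(Segment(b.ref_contig, b.ref_start + off, ln, "+",
                                   b.feature, b.variant_id, off))
        return out

    # -- integrity ----------------------------------------------------------

    def validate(self) -> None:
        for contig, bl in self.blocks.items():
            pos = 0
            prev_seq_end: dict[str, int] = {}
            for b in bl:
                if b.host_contig != contig:
                    raise MapInvariantError(f"{contig}: block names {b.host_contig}")
                if b.host_start != pos:
                    raise MapInvariantError(
                        f"{contig}: blocks do not tile host space at {pos}")
                pos += b.host_len
                if b.feature not in FEATURES:
                    raise MapInvariantError(f"{contig}: unknown feature {b.feature}")
                if b.feature in (SEQ, INV, DUP_COPY):
                    if b.host_len != b.ref_len or b.host_len <= 0:
                        raise MapInvariantError(f"{contig}: bad {b.feature} lengths")
                if b.feature == SEQ and b.strand != "+":
                    raise MapInvariantError(f"{contig}: SEQ must be strand +")
                if b.feature == INV and b.strand != "-":
                    raise MapInvariantError(f"{contig}: INV must be strand -")
                if b.feature == INS_NOVEL and (b.ref_len != 0 or b.host_len <= 0):
                    raise MapInvariantError(f"{contig}: bad INS_NOVEL lengths")
                if b.feature == DEL_GAP and (b.host_len != 0 or b.ref_len <= 0):
                    raise MapInvariantError(f"{contig}: bad DEL_GAP lengths")
                if b.feature == SEQ:
                    last = prev_seq_end.get(b.ref_contig, -1)
                    if b.ref_start < last:
                        raise MapInvariantError(
                            f"{contig}: SEQ reference intervals overlap/regress "
                            f"at {b.ref_contig}:{b.ref_start}")
                    prev_seq_end[b.ref_contig] = b.ref_end
            if pos != self.host_lengths[contig]:
                raise MapInvariantError(f"{contig}: tiling ends at {pos}")

    # -- serialization ------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#varsim-lite-map\tversion={MAP_FORMAT_VERSION}\n")
            fh.write("#host_contig\thost_start\thost_len\tref_contig\t"
                     "ref_start\tref_len\tstrand\tfeature\tvariant_id\n")
            for bl in self.blocks.values():
                for b in bl:
                    fh.write("\t".join([
                        b.host_contig, str(b.host_start), str(b.host_len),
                        b.ref_contig, str(b.ref_start), str(b.ref_len),
                        b.strand, b.feature, b.variant_id or ".",
                    ]) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenomeMap":
        blocks: dict[str, list[MapBlock]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#varsim-lite-map"):
                raise ValueError(f"{path}: not a varsim-lite map file")
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                b = MapBlock(f[0], int(f[1]), int(f[2]), f[3], int(f[4]),
                             int(f[5]), f[6], f[7],
                             None if f[8] == "." else f[8])
                blocks.setdefault(b.host_contig, []).append(b)
        gmap = cls(blocks)
        gmap.validate()
        return gmap


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_haplotype(ref_seq: str, ref_contig: str, host_contig: str,
                    variants: Sequence[Variant]) -> tuple[str, list[MapBlock]]:
    """Apply sorted, non-overlapping variants to one reference contig.

    Returns the host sequence and its map blocks. Variants must be normalized
    and sorted; overlapping footprints are a hard error (sampling guarantees
    separation upstream).
    """
    parts: list[str] = []
    blocks: list[MapBlock] = []
    r = 0  # reference cursor (0-based)
    h = 0  # host cursor
    prev: Variant | None = None

    def emit_seq(upto: int, variant_id: str | None = None) -> None:
        nonlocal r, h
        if upto > r:
            blocks.append(MapBlock(host_contig, h, upto - r, ref_contig, r,
                                   upto - r, "+", SEQ, variant_id))
            parts.append(ref_seq[r:upto])
            h += upto - r
            r = upto

    for v in sorted(variants, key=Variant.sort_key):
        if prev is not None and v.footprint[0] < prev.footprint[1]:
            raise OverlapError(
                f"variants {prev.id} and {v.id} overlap on {ref_contig} "
                f"({prev.footprint} vs {v.footprint})")
        prev = v
        if v.event_end0 > len(ref_seq):
            raise ValueError(f"{v.id}: extends past end of {ref_contig}")
        t = v.var_type
        if t in (VarType.SNV, VarType.MNP):
            emit_seq(v.pos - 1)
            ln = len(v.ref_allele)
            blocks.append(MapBlock(host_contig, h, ln, ref_contig, r, ln,
                                   "+", SEQ, v.id))
            parts.append(v.alt_allele)
            h += ln
            r += ln
        elif t is VarType.INS:
            if v.ins_seq is None:
                raise ValueError(f"{v.id}: insertion without resolved sequence")
            emit_seq(v.pos)  # through the anchor base
            ln = len(v.ins_seq)
            blocks.append(MapBlock(host_contig, h, ln, ref_contig, r, 0,
                                   "+", INS_NOVEL, v.id))
            parts.append(v.ins_seq)
            h += ln
        elif t is VarType.DEL:
            emit_seq(v.pos)
            span = abs(v.svlen)
            blocks.append(MapBlock(host_contig, h, 0, ref_contig, r, span,
                                   "+", DEL_GAP, v.id))
            r += span
        elif t is VarType.INV:
            emit_seq(v.pos)
            span = v.svlen
            blocks.append(MapBlock(host_contig, h, span, ref_contig, r, span,
                                   "-", INV, v.id))
            parts.append(revcomp(ref_seq[r:r + span]))
            h += span
            r += span
        elif t is VarType.DUP:
            span = v.dup_span
            emit_seq(v.pos + span)  # original copy stays inside SEQ
            for _ in range(v.dup_copies - 1):
                blocks.append(MapBlock(host_contig, h, span, ref_contig,
                                       r - span, span, "+", DUP_COPY, v.id))
                parts.append(ref_seq[r - span:r])
                h += span
        else:  # pragma: no cover
            raise ValueError(f"{v.id}: unsupported type {t}")

    emit_seq(len(ref_seq))
    return "".join(parts), blocks


@dataclass
class DiploidGenome:
    """Perturbed diploid genome: two haplotype sets plus the coordinate map."""

    reference: Reference
    haplotypes: dict[str, str]  # host contig -> sequence
    gmap: GenomeMap
    truth: list[Variant]  # full phased truth set
    hap_variants: dict[str, list[Variant]]  # host contig -> variants applied

    HAP_SUFFIX = ("_hapA", "_hapB")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.haplotypes.values())

    def novel_sequences(self) -> dict[str, str]:
        return {v.id: v.ins_seq for v in self.truth
                if v.var_type is VarType.INS and v.ins_seq is not None}

    def substitutions(self) -> dict[str, str]:
        return {v.id: v.alt_allele for v in self.truth
                if v.var_type in (VarType.SNV, VarType.MNP)}

    def check_length_equation(self) -> None:
        """len(host) == len(ref) + sum(gains) - sum(losses), per haplotype."""
        for host, vs in self.hap_variants.items():
            ref_contig = _ref_contig_of(host)
            expect = self.reference.length(ref_contig)
            for v in vs:
                if v.var_type in (VarType.INS, VarType.DUP):
                    expect += v.svlen
                elif v.var_type is VarType.DEL:
                    expect += v.svlen  # negative
            got = len(self.haplotypes[host])
            if got != expect:
                raise AssertionError(
                    f"{host}: length {got} != expected {expect}")


def _ref_contig_of(host_contig: str) -> str:
    for suf in DiploidGenome.HAP_SUFFIX:
        if host_contig.endswith(suf):
            return host_contig[: -len(suf)]
    raise ValueError(f"not a haplotype contig name: {host_contig}")


def build_diploid(reference: Reference, truth: Sequence[Variant]) -> DiploidGenome:
    """Apply a phased truth set to every contig of the reference.

    Haplotype 0 carries variants with genotype[0] == 1 ("hapA"), haplotype 1
    those with genotype[1] == 1 ("hapB"); homozygous variants appear in both.
    """
    haps: dict[str, str] = {}
    blocks: dict[str, list[MapBlock]] = {}
    hap_variants: dict[str, list[Variant]] = {}
    for contig in reference.contigs:
        seq = reference.sequence(contig)
        for hap in (0, 1):
            host = contig + DiploidGenome.HAP_SUFFIX[hap]
            vs = sorted((v for v in truth
                         if v.chrom == contig and v.genotype[hap] == 1),
                        key=Variant.sort_key)
            hseq, hblocks = build_haplotype(seq, contig, host, vs)
            haps[host] = hseq
            blocks[host] = hblocks
            hap_variants[host] = vs
    gmap = GenomeMap(blocks)
    gmap.validate()
    genome = DiploidGenome(reference, haps, gmap,
                           sorted(truth, key=Variant.sort_key), hap_variants)
    genome.check_length_equation()
    return genome


def reconstruct_contig(genome_or_map, host_contig: str, reference: Reference,
                       novel_seqs: dict[str, str],
                       substitutions: dict[str, str]) -> str:
    """Rebuild a host contig purely through `lift_interval`.

    Fetches every lifted piece from the reference (reverse-complemented on
    strand -), re-applies recorded SNV/MNP substitutions and splices recorded
    novel insertion sequences. Byte-for-byte equality with the stored host
    sequence is the map's keystone integrity property.
    """
    gmap = genome_or_map.gmap if isinstance(genome_or_map, DiploidGenome) else genome_or_map
    n = gmap.host_lengths[host_contig]
    parts = []
    for seg in gmap.lift_interval(host_contig, 0, n):
        if seg.length == 0:
            continue
        if seg.feature == INS_NOVEL:
            seq = novel_seqs[seg.variant_id][seg.block_offset:
                                             seg.block_offset + seg.length]
        elif seg.feature == INV:
            seq = revcomp(reference.fetch(seg.ref_contig, seg.ref_start,
                                          seg.ref_start + seg.length))
        else:
            seq = reference.fetch(seg.ref_contig, seg.ref_start,
                                  seg.ref_start + seg.length)
            if seg.variant_id is not None and seg.variant_id in substitutions:
                alt = substitutions[seg.variant_id]
                seq = alt[seg.block_offset:seg.block_offset + seg.length]
        parts.append(seq)
    return "".join(parts)


# ---------------------------------------------------------------------------
# On-disk simulation directory
# ---------------------------------------------------------------------------

def write_sim_dir(genome: DiploidGenome, out_dir: str | Path) -> dict[str, Path]:
    """Write haplotype FASTAs, the map TSV and truth VCFs to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hapA": out / "hapA.fa",
        "hapB": out / "hapB.fa",
        "map": out / "map.tsv",
        "truth": out / "truth.vcf",
        "truth_hapA": out / "truth_hapA.vcf",
        "truth_hapB": out / "truth_hapB.vcf",
    }
    for hap, key in ((0, "hapA"), (1, "hapB")):
        seqs = {h: s for h, s in genome.haplotypes.items()
                if h.endswith(DiploidGenome.HAP_SUFFIX[hap])}
        write_fasta(seqs, paths[key])
    genome.gmap.write_tsv(paths["map"])
    contigs = genome.reference.lengths
    write_vcf(genome.truth, paths["truth"], contigs)
    for hap, key in ((0, "truth_hapA"), (1, "truth_hapB")):
        vs = sorted((v for v in genome.truth if v.genotype[hap] == 1),
                    key=Variant.sort_key)
        write_vcf(vs, paths[key], contigs)
    return paths
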
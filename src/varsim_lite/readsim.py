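"""Paired-end read simulation with per-read true-alignment metadata.

Reads are drawn from the perturbed diploid genome; their true reference
alignments are computed through the genome map and packed into the read name
(``vs:<read_id>:<b64url payload>``), so any aligner's output can be scored
without auxiliary lookups. Names that would exceed the SAM query-name limit
fall back to a sidecar TSV keyed by read_id.

Alternative true locations: a read lifting to k reference segments yields one
alternative per anchorable segment (that segment aligned at its own reference
start, the rest soft-clipped). When all segments are plus-strand SEQ/DUP_COPY
pieces that are adjacent in reference space, the read has a single full-length
alternative instead. Bases inside a novel insertion carry no reference anchor;
a read entirely inside one is anchored at the insertion breakpoint.

Determinism: each pair draws from its own RNG seeded by (seed, pair_index),
so output is reproducible and independent of how pairs are partitioned into
shards — concatenated shard outputs are byte-identical to a one-shard run.
"""
from __future__ import annotations

import base64
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Protocol, Sequence

import numpy as np

from .diploid import (DEL_GAP, DUP_COPY, INS_NOVEL, INV, SEQ, DiploidGenome,
                      GenomeMap, Segment)
from .reference import revcomp

log = logging.getLogger(__name__)

QNAME_MAX = 254
_FEAT_CODE = {SEQ: "S", INS_NOVEL: "I", DEL_GAP: "D", INV: "V", DUP_COPY: "U"}
_CODE_FEAT = {v: k for k, v in _FEAT_CODE.items()}


class TruthNameError(ValueError):
    pass


class NotSimulatedRead(TruthNameError):
    """The query name does not carry varsim-lite truth metadata."""


class CorruptPayload(TruthNameError):
    """The name claims to carry truth metadata but the payload is unreadable."""


@dataclass(frozen=True)
class ReadSimParams:
    coverage: float = 30.0
    read_len: int = 100
    frag_mean: int = 400
    frag_sd: int = 60
    sub_error_rate: float = 0.001
    seed: int = 0
    shards: int = 1

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.frag_mean < self.read_len:
            raise ValueError("frag_mean must be >= read_len")
        if not 0.0 <= self.sub_error_rate < 1.0:
            raise ValueError("sub_error_rate must be in [0, 1)")
        if self.shards < 1:
            raise ValueError("shards must be >= 1")

    @property
    def base_quality(self) -> int:
        return round(-10.0 * math.log10(max(self.sub_error_rate, 1e-4)))


@dataclass(frozen=True)
class AlnSegment:
    """One lifted piece of a read: read bases covered + reference anchor."""

    ref_contig: str
    ref_start: int  # 0-based
    length: int  # read bases (0 for a deletion crossing)
    strand: str
    feature: str


@dataclass(frozen=True)
class Alternative:
    """One admissible true alignment: the anchored segment's own ref_start is
    the position an aligner should report (remaining segments soft-clipped)."""

    segments: tuple[AlnSegment, ...]
    anchor_index: int
    full_length: bool

    @property
    def anchor(self) -> AlnSegment:
        return self.segments[self.anchor_index]


@dataclass(frozen=True)
class MateTruth:
    segments: tuple[AlnSegment, ...]

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(s.feature for s in self.segments)

    @property
    def alternatives(self) -> tuple[Alternative, ...]:
        return _alternatives_from_segments(self.segments)


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    haplotype: str  # originating host contig
    mates: tuple[MateTruth, MateTruth]

    @property
    def labels(self) -> frozenset[str]:
        return self.mates[0].labels | self.mates[1].labels


def _alternatives_from_segments(segs: tuple[AlnSegment, ...]) -> tuple[Alternative, ...]:
    solid = [(i, s) for i, s in enumerate(segs) if s.length > 0]
    anchorable = [(i, s) for i, s in solid if s.feature != INS_NOVEL]
    if not anchorable:
        # read entirely within a novel insertion: anchored at the breakpoint
        i = solid[0][0]
        return (Alternative(segs, i, False),)
    if len(anchorable) == len(solid) == len(segs):
        colinear = all(s.feature in (SEQ, DUP_COPY) and s.strand == "+"
                       for _, s in solid)
        if colinear:
            for (_, a), (_, b) in zip(solid, solid[1:]):
                if (b.ref_contig != a.ref_contig
                        or b.ref_start != a.ref_start + a.length):
                    colinear = False
                    break
        if colinear:
            return (Alternative(segs, solid[0][0], True),)
    return tuple(Alternative(segs, i, False) for i, _ in anchorable)


def true_alignments(gmap: GenomeMap, host_contig: str, start: int,
                    length: int) -> MateTruth:
    """True reference alignment metadata for a read at host [start, start+length)."""
    segs = tuple(
        AlnSegment(s.ref_contig, s.ref_start, s.length, s.strand, s.feature)
        for s in gmap.lift_interval(host_contig, start, start + length)
    )
    return MateTruth(segs)


# ---------------------------------------------------------------------------
# Name encoding
# ---------------------------------------------------------------------------

def _pack(rec: TruthRecord) -> str:
    def mate(m: MateTruth) -> str:
        return ",".join(
            f"{s.ref_contig}~{s.ref_start}~{s.length}~{s.strand}~{_FEAT_CODE[s.feature]}"
            for s in m.segments)

    payload = ";".join([rec.haplotype, mate(rec.mates[0]), mate(rec.mates[1])])
    return base64.urlsafe_b64encode(zlib.compress(payload.encode(), 9)).decode()


def _unpack(read_id: str, b64: str) -> TruthRecord:
    try:
        payload = zlib.decompress(base64.urlsafe_b64decode(b64.encode())).decode()
        hap, m1, m2 = payload.split(";")

        def mate(s: str) -> MateTruth:
            segs = []
            for part in s.split(","):
                c, rs, ln, st, fc = part.split("~")
                segs.append(AlnSegment(c, int(rs), int(ln), st, _CODE_FEAT[fc]))
            return MateTruth(tuple(segs))

        return TruthRecord(read_id, hap, (mate(m1), mate(m2)))
    except Exception as exc:
        raise CorruptPayload(f"read {read_id}: corrupt truth payload: {exc}")


def encode_truth(rec: TruthRecord) -> tuple[str, str | None]:
    """Pack a TruthRecord into a SAM-legal read name.

    Returns (name, overflow_payload): overflow_payload is None unless the
    packed name would exceed the SAM query-name limit, in which case the name
    carries the sidecar sentinel and the payload must go to the sidecar.
    """
    b64 = _pack(rec)
    name = f"vs:{rec.read_id}:{b64}"
    if len(name) <= QNAME_MAX:
        return name, None
    return f"vs:{rec.read_id}:S", b64


def decode_truth(name: str, sidecar: dict[str, str] | None = None) -> TruthRecord:
    """Invert :func:`encode_truth`; raises :class:`NotSimulatedRead` or
    :class:`CorruptPayload`."""
    parts = name.split(":", 2)
    if len(parts) != 3 or parts[0] != "vs":
        raise NotSimulatedRead(f"not a varsim-lite read name: {name!r}")
    read_id, body = parts[1], parts[2]
    if body == "S":
        if sidecar is None or read_id not in sidecar:
            raise CorruptPayload(f"read {read_id}: payload in sidecar but "
                                 "sidecar missing or incomplete")
        body = sidecar[read_id]
    return _unpack(read_id, body)


def read_sidecar(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rid, payload = line.rstrip("\n").split("\t")
            out[rid] = payload
    return out


# ---------------------------------------------------------------------------
# Simulator + adapter contract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawPair:
    """Adapter contract unit: a simulated read pair in host coordinates.

    Any external read simulator can be plugged in by yielding RawPairs:
    mate 1 is the fragment's left end on the forward host strand, mate 2 the
    right end reverse-complemented. Truth (host_contig + intervals) is
    mandatory; :func:`annotate_and_write` turns it into reference-space truth.
    """

    pair_id: str
    host_contig: str | None
    m1_start: int | None
    m2_start: int | None
    read_len: int
    seq1: str
    seq2: str
    qual1: str
    qual2: str


class ReadSource(Protocol):
    def reads(self) -> Iterator[RawPair]: ...


@dataclass
class SimResult:
    n_pairs: int
    n_bases: int
    realized_coverage: float
    fastq1: Path
    fastq2: Path
    sidecar: Path
    n_overflow: int


class BuiltinSimulator:
    """Uniform-coverage paired-end simulator with a flat substitution-error
    model; the reference adapter for the :class:`ReadSource` contract."""

    def __init__(self, genome: DiploidGenome, params: ReadSimParams,
                 sample_tag: str = "s", shard: int = 0):
        self.genome = genome
        self.params = params
        self.sample_tag = sample_tag
        self.shard = shard
        usable, skipped = [], []
        for name, seq in genome.haplotypes.items():
            (usable if len(seq) >= params.frag_mean else skipped).append(name)
        for name in skipped:
            log.warning("haplotype %s shorter than frag_mean, skipped", name)
        self.contigs = [(n, genome.haplotypes[n]) for n in usable]
        self.total_len = sum(len(s) for _, s in self.contigs)
        self.n_pairs = round(params.coverage * self.total_len
                             / (2 * params.read_len))
        self._cum = np.cumsum([len(s) for _, s in self.contigs])

    def pair_range(self) -> tuple[int, int]:
        per = self.n_pairs // self.params.shards
        rem = self.n_pairs % self.params.shards
        lo = self.shard * per + min(self.shard, rem)
        hi = lo + per + (1 if self.shard < rem else 0)
        return lo, hi

    def reads(self) -> Iterator[RawPair]:
        p = self.params
        lo, hi = self.pair_range()
        for i in range(lo, hi):
            rng = np.random.default_rng((p.seed, i))
            u = rng.random() * self.total_len
            ci = int(np.searchsorted(self._cum, u, side="right"))
            name, seq = self.contigs[ci]
            clen = len(seq)
            while True:
                frag = int(round(rng.normal(p.frag_mean, p.frag_sd)))
                if p.read_len <= frag <= 2 * p.frag_mean:
                    break
            frag = min(frag, clen)
            start = int(rng.integers(0, clen - frag + 1))
            s1 = seq[start:start + p.read_len]
            s2 = revcomp(seq[start + frag - p.read_len:start + frag])
            if p.sub_error_rate > 0:
                s1 = _apply_errors(s1, p.sub_error_rate, rng)
                s2 = _apply_errors(s2, p.sub_error_rate, rng)
            q = chr(p.base_quality + 33) * p.read_len
            yield RawPair(f"{self.sample_tag}{i}", name, start,
                          start + frag - p.read_len, p.read_len, s1, s2, q, q)


_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGTN"}
_OTHER["N"] = list("ACGT")


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for p in sorted(int(x) for x in pos):
        out[p] = _OTHER[out[p]][int(rng.integers(3))]
    return "".join(out)


def annotate_and_write(source: ReadSource, gmap: GenomeMap,
                       fq1, fq2, sidecar_fh) -> tuple[int, int, int]:
    """Apply truth lifting + name encoding to any adapter's reads and write
    FASTQ. Returns (n_pairs, n_bases, n_overflow)."""
    n_pairs = n_bases = n_overflow = 0
    for rp in source.reads():
        if rp.host_contig is None or rp.m1_start is None or rp.m2_start is None:
            raise ValueError(f"adapter omitted truth for pair {rp.pair_id}")
        clen = gmap.host_lengths.get(rp.host_contig)
        if clen is None:
            raise ValueError(f"pair {rp.pair_id}: unknown host contig "
                             f"{rp.host_contig}")
        for s in (rp.m1_start, rp.m2_start):
            if not 0 <= s <= clen - rp.read_len:
                raise ValueError(f"pair {rp.pair_id}: host coordinates out of "
                                 f"range ({s} on {rp.host_contig})")
        m1 = true_alignments(gmap, rp.host_contig, rp.m1_start, rp.read_len)
        m2 = true_alignments(gmap, rp.host_contig, rp.m2_start, rp.read_len)
        rec = TruthRecord(rp.pair_id, rp.host_contig, (m1, m2))
        name, overflow = encode_truth(rec)
        if overflow is not None:
            sidecar_fh.write(f"{rp.pair_id}\t{overflow}\n")
            n_overflow += 1
        fq1.write(f"@{name}\n{rp.seq1}\n+\n{rp.qual1}\n")
        fq2.write(f"@{name}\n{rp.seq2}\n+\n{rp.qual2}\n")
        n_pairs += 1
        n_bases += len(rp.seq1) + len(rp.seq2)
    return n_pairs, n_bases, n_overflow


def simulate_reads(genome: DiploidGenome, params: ReadSimParams,
                   out_prefix: str | Path, sample_tag: str = "s") -> SimResult:
    """Simulate paired-end reads to ``<prefix>_1.fq`` / ``<prefix>_2.fq`` plus
    a truth sidecar, sharded internally per ``params.shards``."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fq1_path = prefix.parent / (prefix.name + "_1.fq")
    fq2_path = prefix.parent / (prefix.name + "_2.fq")
    sc_path = prefix.parent / (prefix.name + "_truth.tsv")
    n_pairs = n_bases = n_overflow = 0
    total_len = 0
    with open(fq1_path, "w") as fq1, open(fq2_path, "w") as fq2, \
            open(sc_path, "w") as sc:
        sc.write("#read_id\tpayload\n")
        for shard in range(params.shards):
            sim = BuiltinSimulator(genome, params, sample_tag, shard)
            total_len = sim.total_len
            p, b, o = annotate_and_write(sim, genome.gmap, fq1, fq2, sc)
            n_pairs += p
            n_bases += b
            n_overflow += o
    cov = n_bases / total_len if total_len else 0.0
    return SimResult(n_pairs, n_bases, cov, fq1_path, fq2_path, sc_path,
                     n_overflow)


# ---------------------------------------------------------------------------
# Truth-derived perfect alignments (keystone self-validation input)
# ---------------------------------------------------------------------------

def iter_fastq_names(path: str | Path) -> Iterator[str]:
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 0:
                yield line.rstrip("\n")[1:]


def write_truth_sam(fastq1: str | Path, sidecar_path: str | Path,
                    contig_lengths: dict[str, int], out_sam: str | Path) -> int:
    """Convert each read's first true alternative into a SAM record.

    Feeding this SAM back to alignment validation must score 100% correct in
    every category — the pipeline's end-to-end self-check.
    """
    sidecar = read_sidecar(sidecar_path)
    n = 0
    with open(out_sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for name in iter_fastq_names(fastq1):
            rec = decode_truth(name, sidecar)
            for mate_i, mate in enumerate(rec.mates):
                alt = mate.alternatives[0]
                anchor = alt.anchor
                flag = 0x1 | (0x40 if mate_i == 0 else 0x80)
                if anchor.strand == "-":
                    flag |= 0x10
                read_len = sum(s.length for s in mate.segments)
                lead = sum(s.length for s in mate.segments[:alt.anchor_index])
                pos0 = anchor.ref_start
                if anchor.feature == INS_NOVEL:
                    # breakpoint anchor: keep the record within the contig
                    pos0 = min(pos0, contig_lengths[anchor.ref_contig] - 1)
                    matched = 1
                else:
                    matched = anchor.length
                trail = read_len - lead - matched
                cigar = (f"{lead}S" if lead else "") + f"{matched}M" + \
                        (f"{trail}S" if trail > 0 else "")
                fh.write("\t".join([
                    name, str(flag), anchor.ref_contig, str(pos0 + 1),
                    "60", cigar, "*", "0", "0", "*", "*",
                ]) + "\n")
                n += 1
    return n
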
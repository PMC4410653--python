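"""Variant data model, VCF I/O and canonical normalization.

A :class:`Variant` is a single-ALT, phased record. Multi-allelic VCF lines are
decomposed into one Variant per ALT at read time. Positions follow the VCF
convention: ``pos`` is 1-based and, for indels and symbolic SVs, names the
anchor base *before* the affected span; for SNV/MNP it names the first changed
base. All internal arithmetic converts to 0-based half-open intervals.

Normalization canonicalizes the many equivalent VCF spellings of one edit:
shared bases are trimmed (keeping the single anchor base for indels) and
indels are left-aligned to the smallest position that yields an identical
edited sequence. Normalization is idempotent and sequence-preserving; both
properties are exercised by the test suite against a naive string-edit oracle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)


class VariantError(ValueError):
    """A record violates the Variant invariants."""


class IdentityVariantError(VariantError):
    """REF and ALT describe the same sequence (no edit)."""


class VcfParseError(ValueError):
    """A VCF line could not be parsed."""


class VarType(str, Enum):
    SNV = "SNV"
    MNP = "MNP"
    INS = "INS"
    DEL = "DEL"
    INV = "INV"
    DUP = "DUP"


SYMBOLIC_ALT = {
    VarType.DEL: "<DEL>",
    VarType.INS: "<INS>",
    VarType.INV: "<INV>",
    VarType.DUP: "<DUP:TANDEM>",
}
_SYMBOL_TO_TYPE = {
    "DEL": VarType.DEL,
    "INS": VarType.INS,
    "INV": VarType.INV,
    "DUP": VarType.DUP,
    "DUP:TANDEM": VarType.DUP,
}


@dataclass(frozen=True)
class Variant:
    """One normalized variant on one sample.

    svlen sign convention: 0 for SNV/MNP, +gained bp for INS and DUP
    (for DUP the gain is ``(copies-1) * span``), -lost bp for DEL, and the
    inverted span length for INV.
    """

    chrom: str
    pos: int  # 1-based (VCF convention; anchor base for indels/SVs)
    ref_allele: str
    alt_allele: str
    var_type: VarType
    svlen: int = 0
    ins_seq: str | None = None
    dup_copies: int | None = None
    genotype: tuple[int, int] = (1, 1)
    id: str = "."

    # -- derived geometry (0-based half-open on the reference) --------------

    @property
    def dup_span(self) -> int:
        """Reference span of one duplicated unit."""
        assert self.var_type is VarType.DUP and self.dup_copies
        return self.svlen // (self.dup_copies - 1)

    @property
    def event_start0(self) -> int:
        """0-based first reference base actually affected by the edit."""
        if self.var_type in (VarType.SNV, VarType.MNP):
            return self.pos - 1
        return self.pos  # base after the anchor

    @property
    def event_end0(self) -> int:
        t = self.var_type
        if t in (VarType.SNV, VarType.MNP):
            return self.pos - 1 + len(self.ref_allele)
        if t is VarType.INS:
            return self.pos
        if t is VarType.DEL:
            return self.pos + abs(self.svlen)
        if t is VarType.INV:
            return self.pos + self.svlen
        return self.pos + self.dup_span  # DUP

    @property
    def footprint(self) -> tuple[int, int]:
        """0-based half-open reference interval occupied (anchor included)."""
        if self.var_type in (VarType.SNV, VarType.MNP):
            return (self.pos - 1, self.event_end0)
        return (self.pos - 1, self.event_end0)

    @property
    def end(self) -> int:
        """1-based inclusive END (VCF convention)."""
        return self.event_end0

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.var_type.value, self.alt_allele, self.svlen)


def validate_variant(v: Variant, reference) -> None:
    """Raise :class:`VariantError` if `v` violates the model invariants."""
    if v.pos < 1:
        raise VariantError(f"{v.id}: pos must be >= 1, got {v.pos}")
    if v.chrom not in reference:
        raise VariantError(f"{v.id}: unknown contig {v.chrom}")
    if v.event_end0 > reference.length(v.chrom):
        raise VariantError(f"{v.id}: variant extends past end of {v.chrom}")
    if v.genotype == (0, 0):
        raise VariantError(f"{v.id}: genotype 0|0 carries no variant")
    t = v.var_type
    if t is VarType.SNV:
        if len(v.ref_allele) != 1 or len(v.alt_allele) != 1 or v.ref_allele == v.alt_allele:
            raise VariantError(f"{v.id}: malformed SNV alleles")
    if t is VarType.DEL and v.svlen >= 0:
        raise VariantError(f"{v.id}: DEL requires svlen < 0")
    if t in (VarType.INS, VarType.DUP, VarType.INV) and v.svlen <= 0:
        raise VariantError(f"{v.id}: {t.value} requires svlen > 0")
    if t is VarType.DUP:
        if not v.dup_copies or v.dup_copies < 2:
            raise VariantError(f"{v.id}: DUP requires dup_copies >= 2")
        if v.svlen % (v.dup_copies - 1) != 0:
            raise VariantError(f"{v.id}: DUP gain not divisible by copies-1")
    if not v.alt_allele.startswith("<"):
        expect = reference.fetch(v.chrom, v.pos - 1, v.pos - 1 + len(v.ref_allele))
        if v.ref_allele != expect:
            raise VariantError(
                f"{v.id}: REF {v.ref_allele!r} does not match reference {expect!r} "
                f"at {v.chrom}:{v.pos}"
            )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _trim_and_left_align(chrom: str, pos: int, r: str, a: str, reference):
    # Right-trim shared suffix bases; when an allele would empty, pull in the
    # preceding reference base (classic left-alignment of indels).
    while len(r) > 1 or len(a) > 1:
        if not r or not a or r[-1] != a[-1]:
            break
        r2, a2 = r[:-1], a[:-1]
        if not r2 or not a2:
            if pos == 1:
                break  # cannot extend left past the contig start
            prev = reference.fetch(chrom, pos - 2, pos - 1)
            r, a, pos = prev + r2, prev + a2, pos - 1
        else:
            r, a = r2, a2
    # Trim shared leading bases, keeping one anchor base for indels.
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        r, a, pos = r[1:], a[1:], pos + 1
    return pos, r, a


def normalize(v: Variant, reference) -> Variant:
    """Return the canonical (trimmed, left-aligned) form of `v`.

    Symbolic INV/DUP records (and symbolic INS without a resolved sequence)
    have a single spelling already and pass through after validation.
    """
    validate_variant(v, reference)
    if v.var_type in (VarType.INV, VarType.DUP):
        anchor = reference.fetch(v.chrom, v.pos - 1, v.pos)
        return replace(v, ref_allele=anchor, alt_allele=SYMBOLIC_ALT[v.var_type])

    if v.alt_allele.startswith("<"):
        if v.var_type is VarType.DEL:
            r = reference.fetch(v.chrom, v.pos - 1, v.pos + abs(v.svlen))
            a = r[0]
        elif v.var_type is VarType.INS:
            if v.ins_seq is None:
                return v  # unresolved symbolic insertion: nothing to align
            a0 = reference.fetch(v.chrom, v.pos - 1, v.pos)
            r, a = a0, a0 + v.ins_seq
        else:  # pragma: no cover - symbolic SNV/MNP impossible
            raise VariantError(f"{v.id}: unexpected symbolic ALT {v.alt_allele}")
    else:
        r, a = v.ref_allele, v.alt_allele

    if r == a:
        raise IdentityVariantError(f"{v.id}: REF == ALT at {v.chrom}:{v.pos}")
    pos, r, a = _trim_and_left_align(v.chrom, v.pos, r, a, reference)
    if r == a:
        raise IdentityVariantError(f"{v.id}: identity record after trimming")

    if len(r) == len(a):
        vt = VarType.SNV if len(r) == 1 else VarType.MNP
        svlen, ins_seq = 0, None
    elif len(a) > len(r) and len(r) == 1 and a[0] == r[0]:
        vt, svlen, ins_seq = VarType.INS, len(a) - 1, a[1:]
    elif len(r) > len(a) and len(a) == 1 and r[0] == a[0]:
        vt, svlen, ins_seq = VarType.DEL, -(len(r) - 1), None
    else:
        raise VariantError(
            f"{v.id}: complex substitution {r!r}->{a!r} is not representable "
            "(block substitutions beyond MNPs are unsupported)"
        )
    return Variant(
        chrom=v.chrom,
        pos=pos,
        ref_allele=r,
        alt_allele=a,
        var_type=vt,
        svlen=svlen,
        ins_seq=ins_seq,
        dup_copies=None,
        genotype=v.genotype,
        id=v.id,
    )


# ---------------------------------------------------------------------------
# Size bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SizeBin:
    label: str
    lo: int  # bp, inclusive
    hi: int | None  # bp, inclusive; None = unbounded


DEFAULT_BINS: tuple[SizeBin, ...] = (
    SizeBin("1", 1, 1),
    SizeBin("2-5", 2, 5),
    SizeBin("6-20", 6, 20),
    SizeBin("21-50", 21, 50),
    SizeBin("51-100", 51, 100),
    SizeBin("101-200", 101, 200),
    SizeBin("201-500", 201, 500),
    SizeBin("501-1000", 501, 1000),
    SizeBin("1001-2000", 1001, 2000),
    SizeBin("2001-5000", 2001, 5000),
    SizeBin(">5000", 5001, None),
)


def validate_bins(bins: Sequence[SizeBin]) -> None:
    """Bins must be disjoint, ordered and cover [1, inf)."""
    if not bins or bins[0].lo != 1:
        raise ValueError("size bins must start at 1")
    for prev, cur in zip(bins, bins[1:]):
        if prev.hi is None or cur.lo != prev.hi + 1:
            raise ValueError(f"size bins not contiguous at {prev.label}/{cur.label}")
    if bins[-1].hi is not None:
        raise ValueError("last size bin must be unbounded")


def variant_size(v: Variant) -> int:
    """Size used for binning: 1 for SNV, allele length for MNP, |svlen| else."""
    if v.var_type is VarType.SNV:
        return 1
    if v.var_type is VarType.MNP:
        return len(v.ref_allele)
    return abs(v.svlen)


def assign_bin(v: Variant, bins: Sequence[SizeBin] = DEFAULT_BINS) -> SizeBin:
    size = variant_size(v)
    for b in bins:
        if b.lo <= size and (b.hi is None or size <= b.hi):
            return b
    raise AssertionError("bins do not cover size %d" % size)  # unreachable


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _info_scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0]
    return value


def read_vcf(path: str | Path, reference, strict: bool = False) -> list[Variant]:
    """Read a single-sample VCF into normalized :class:`Variant` records.

    Multi-allelic lines are decomposed per ALT. Records on unknown contigs or
    with genotype 0|0 (for that ALT) are skipped with a warning. In lenient
    mode (default) malformed records are skipped with a warning; in strict
    mode they abort with :class:`VcfParseError`.
    """
    import pysam

    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        rec_no = 0
        it = iter(vcf)
        while True:
            rec_no += 1
            try:
                rec = next(it)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                raise VcfParseError(f"{path}: malformed VCF around record {rec_no}: {exc}")
            try:
                out.extend(_variants_from_record(rec, reference, strict, rec_no))
            except VariantError as exc:
                if strict:
                    raise VcfParseError(f"{path}: record {rec_no}: {exc}")
                log.warning("skipping record %d: %s", rec_no, exc)
    out.sort(key=Variant.sort_key)
    return out


def _genotype_for_alt(rec, alt_index: int) -> tuple[int, int] | None:
    if len(rec.samples) == 0:
        return (1, 1)  # site-only database VCF: treat as homozygous carrier
    try:
        gt = rec.samples[0]["GT"]
    except KeyError:
        gt = None
    if gt is None or all(g is None for g in gt):
        return (1, 1)
    calls = [0 if g is None else g for g in gt]
    if len(calls) == 1:
        calls = calls * 2
    return (1 if calls[0] == alt_index else 0, 1 if calls[1] == alt_index else 0)


def _variants_from_record(rec, reference, strict: bool, rec_no: int) -> list[Variant]:
    if rec.chrom not in reference:
        log.warning("record %d: unknown contig %s, skipped", rec_no, rec.chrom)
        return []
    if not rec.alts:
        return []
    out = []
    vid = rec.id or "."
    for ai, alt in enumerate(rec.alts, start=1):
        gt = _genotype_for_alt(rec, ai)
        if gt == (0, 0):
            log.warning("record %d alt %d: genotype 0|0, skipped", rec_no, ai)
            continue
        raw = _build_variant(rec, alt, reference, vid, gt)
        try:
            out.append(normalize(raw, reference))
        except IdentityVariantError as exc:
            if strict:
                raise
            log.warning("record %d: %s", rec_no, exc)
    return out


def _build_variant(rec, alt: str, reference, vid: str, gt) -> Variant:
    pos = rec.pos  # 1-based
    if alt.startswith("<"):
        key = alt.strip("<>")
        vt = _SYMBOL_TO_TYPE.get(key)
        if vt is None:
            raise VariantError(f"{vid}: unsupported symbolic ALT {alt}")
        svlen_info = _info_scalar(rec.info.get("SVLEN"))
        span = rec.stop - rec.start - 1  # bases beyond the anchor, from END
        if span <= 0 and svlen_info is not None:
            span = abs(int(svlen_info))
        anchor = reference.fetch(rec.chrom, pos - 1, pos)
        if vt is VarType.DEL:
            if span <= 0:
                raise VariantError(f"{vid}: <DEL> without resolvable END/SVLEN")
            return Variant(rec.chrom, pos, anchor, alt, vt, svlen=-span, genotype=gt, id=vid)
        if vt is VarType.INS:
            if svlen_info is None:
                raise VariantError(f"{vid}: <INS> without SVLEN")
            return Variant(rec.chrom, pos, anchor, alt, vt, svlen=abs(int(svlen_info)),
                           genotype=gt, id=vid)
        if vt is VarType.INV:
            if span <= 0:
                raise VariantError(f"{vid}: <INV> without resolvable END/SVLEN")
            return Variant(rec.chrom, pos, anchor, alt, vt, svlen=span, genotype=gt, id=vid)
        # DUP: SVLEN/END give the duplicated span (VCF convention); the
        # internal svlen is the *gain*, (copies-1) * span
        copies = int(_info_scalar(rec.info.get("DUPCOPIES")) or 2)
        if svlen_info is not None:
            span = abs(int(svlen_info))
        if span <= 0:
            raise VariantError(f"{vid}: <DUP> without resolvable END/SVLEN")
        return Variant(rec.chrom, pos, anchor, alt, vt, svlen=(copies - 1) * span,
                       dup_copies=copies, genotype=gt, id=vid)

    r, a = rec.ref, alt
    if len(r) == len(a):
        vt = VarType.SNV if len(r) == 1 else VarType.MNP
        return Variant(rec.chrom, pos, r, a, vt, genotype=gt, id=vid)
    if len(a) > len(r):
        return Variant(rec.chrom, pos, r, a, VarType.INS, svlen=len(a) - len(r),
                       ins_seq=None, genotype=gt, id=vid)
    return Variant(rec.chrom, pos, r, a, VarType.DEL, svlen=-(len(r) - len(a)),
                   genotype=gt, id=vid)


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

_SV_EXPLICIT_MAX = 49  # indels up to this size are written with explicit alleles


def write_vcf(variants: Sequence[Variant], path: str | Path,
              contigs: dict[str, int], sample: str = "SAMPLE") -> None:
    """Write variants as a single-sample VCF 4.2 with phased GT.

    Input must be position-sorted. Indels below the SV size threshold are
    written with explicit alleles; larger events use symbolic ALTs with
    SVTYPE/END/SVLEN (and DUPCOPIES for duplications).
    """
    keys = [v.sort_key() for v in variants]
    if keys != sorted(keys):
        raise ValueError("write_vcf requires variants sorted by (chrom, pos)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varsim-lite\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=INS,Description="Insertion">\n')
        fh.write('##ALT=<ID=INV,Description="Inversion">\n')
        fh.write('##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length gain">\n')
        fh.write('##INFO=<ID=DUPCOPIES,Number=1,Type=Integer,'
                 'Description="Total tandem copy count">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for v in variants:
            fh.write(_vcf_line(v) + "\n")


def _vcf_line(v: Variant) -> str:
    gt = f"{v.genotype[0]}|{v.genotype[1]}"
    t = v.var_type
    info = "."
    if t in (VarType.SNV, VarType.MNP):
        ref, alt = v.ref_allele, v.alt_allele
    elif t is VarType.INS:
        if v.ins_seq is not None:
            ref, alt = v.ref_allele, v.ref_allele + v.ins_seq
        else:
            ref, alt = v.ref_allele, SYMBOLIC_ALT[t]
            info = f"SVTYPE=INS;END={v.pos};SVLEN={v.svlen}"
    elif t is VarType.DEL:
        if abs(v.svlen) <= _SV_EXPLICIT_MAX and not v.alt_allele.startswith("<"):
            ref, alt = v.ref_allele, v.alt_allele
        else:
            ref, alt = v.ref_allele[0], SYMBOLIC_ALT[t]
            info = f"SVTYPE=DEL;END={v.end};SVLEN={v.svlen}"
    elif t is VarType.INV:
        ref, alt = v.ref_allele, SYMBOLIC_ALT[t]
        info = f"SVTYPE=INV;END={v.end};SVLEN={v.svlen}"
    else:  # DUP: SVLEN is the span of one duplicated unit (VCF convention)
        ref, alt = v.ref_allele, SYMBOLIC_ALT[t]
        info = (f"SVTYPE=DUP;END={v.end};SVLEN={v.dup_span};"
                f"DUPCOPIES={v.dup_copies}")
    return "\t".join([v.chrom, str(v.pos), v.id, ref, alt, ".", "PASS", info, "GT", gt])
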
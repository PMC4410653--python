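"""Truth-set construction: sample variants from a database, assign phased
genotypes, and resolve novel insertion sequences from a donor pool.

Sampling is uniform without replacement (a seeded shuffle followed by
rejection of records whose reference footprints come within ``min_gap`` bp of
an already-accepted record), deterministic given the seed. Heterozygous
variants are assigned to haplotype A or B with probability 1/2 each.
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .variants import Variant, VarType

log = logging.getLogger(__name__)

SV_SIZE_MIN = 50  # conventional indel/SV boundary, bp


@dataclass(frozen=True)
class SamplingSpec:
    """Requested truth-set composition.

    Counts are per category: SNV (incl. MNP), small indel (< 50 bp), and the
    four SV sub-types. ``het_fraction`` is the probability that an accepted
    variant is heterozygous; ``min_gap`` the minimum reference-space
    separation (bp) between accepted footprints.
    """

    n_snv: int = 0
    n_indel: int = 0
    n_del: int = 0
    n_ins: int = 0
    n_dup: int = 0
    n_inv: int = 0
    het_fraction: float = 0.6
    indel_size: tuple[int, int] = (1, SV_SIZE_MIN - 1)
    sv_size: tuple[int, int] = (SV_SIZE_MIN, 1_000_000)
    seed: int = 0
    min_gap: int = 10

    def __post_init__(self):
        for n in (self.n_snv, self.n_indel, self.n_del, self.n_ins,
                  self.n_dup, self.n_inv):
            if n < 0:
                raise ValueError("requested counts must be >= 0")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must be in [0, 1]")
        if self.min_gap < 1:
            raise ValueError("min_gap must be >= 1")


@dataclass(frozen=True)
class InsertionPool:
    """Donor sequences standing in for known insertion-sequence databases."""

    sequences: tuple[str, ...]

    def __post_init__(self):
        for s in self.sequences:
            if not s or set(s) - set("ACGTN"):
                raise ValueError("pool sequences must be non-empty ACGTN strings")


class FootprintTracker:
    """Sorted per-contig interval sets with a minimum-gap acceptance test."""

    def __init__(self, min_gap: int):
        self.min_gap = min_gap
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def accepts(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom, [])
        ends = self._ends.get(chrom, [])
        i = bisect.bisect_left(starts, start)
        if i > 0 and start - ends[i - 1] < self.min_gap:
            return False
        if i < len(starts) and starts[i] - end < self.min_gap:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def _category(v: Variant) -> str | None:
    t = v.var_type
    if t in (VarType.SNV, VarType.MNP):
        return "snv"
    size = abs(v.svlen)
    if t in (VarType.INS, VarType.DEL):
        return "indel" if size < SV_SIZE_MIN else ("sv_ins" if t is VarType.INS
                                                   else "sv_del")
    return "sv_dup" if t is VarType.DUP else "sv_inv"


def _size_ok(v: Variant, spec: SamplingSpec) -> bool:
    cat = _category(v)
    if cat == "snv":
        return True
    size = abs(v.svlen)
    lo, hi = spec.indel_size if cat == "indel" else spec.sv_size
    return lo <= size <= hi


def sample_variants(db: Sequence[Variant], spec: SamplingSpec,
                    reference) -> list[Variant]:
    """Draw a phased truth set from a normalized variant database.

    Returns position-sorted variants with assigned genotypes. If a category
    has fewer eligible records than requested, all eligible records are taken
    and a shortfall is logged (not fatal).
    """
    rng = np.random.default_rng(spec.seed)
    requested = {"snv": spec.n_snv, "indel": spec.n_indel,
                 "sv_del": spec.n_del, "sv_ins": spec.n_ins,
                 "sv_dup": spec.n_dup, "sv_inv": spec.n_inv}
    groups: dict[str, list[Variant]] = {k: [] for k in requested}
    for v in db:
        cat = _category(v)
        if cat in groups and _size_ok(v, spec):
            groups[cat].append(v)

    tracker = FootprintTracker(spec.min_gap)
    accepted: list[Variant] = []
    for cat in sorted(requested):  # deterministic category order
        want = requested[cat]
        if want == 0:
            continue
        pool = groups[cat]
        order = rng.permutation(len(pool))
        taken = 0
        for i in order:
            if taken == want:
                break
            v = pool[i]
            s, e = v.footprint
            if tracker.accepts(v.chrom, s, e):
                tracker.add(v.chrom, s, e)
                accepted.append(v)
                taken += 1
        if taken < want:
            log.warning("category %s: requested %d, only %d eligible "
                        "non-colliding records", cat, want, taken)

    accepted.sort(key=Variant.sort_key)
    out = []
    for i, v in enumerate(accepted):
        if rng.random() < spec.het_fraction:
            gt = (1, 0) if rng.integers(2) == 0 else (0, 1)
        else:
            gt = (1, 1)
        vid = v.id if v.id != "." else f"v{i}"
        out.append(replace(v, genotype=gt, id=vid))
    return out


def make_insertion_sequence(length: int, pool: InsertionPool | None,
                            rng: np.random.Generator) -> str:
    """Draw an insertion sequence of exactly `length` bp.

    A uniformly chosen substring of a uniformly chosen eligible donor when the
    pool has one long enough; otherwise i.i.d. uniform ACGT.
    """
    if length < 1:
        raise ValueError("insertion length must be >= 1")
    donors = [s for s in (pool.sequences if pool else ()) if len(s) >= length]
    if donors:
        donor = donors[int(rng.integers(len(donors)))]
        start = int(rng.integers(0, len(donor) - length + 1))
        return donor[start:start + length]
    return "".join(rng.choice(list("ACGT"), size=length))


def resolve_truth(sampled: Sequence[Variant], pool: InsertionPool | None,
                  rng: np.random.Generator, reference=None) -> list[Variant]:
    """Give every insertion a concrete sequence; the result is the final truth.

    A resolved sequence can accidentally extend a reference repeat, so newly
    filled insertions are re-normalized when a reference is supplied.
    """
    from .variants import normalize

    out = []
    for v in sorted(sampled, key=Variant.sort_key):
        if v.var_type is VarType.INS and v.ins_seq is None:
            seq = make_insertion_sequence(v.svlen, pool, rng)
            filled = replace(v, ins_seq=seq, alt_allele=v.ref_allele + seq)
            out.append(normalize(filled, reference) if reference is not None
                       else filled)
        else:
            out.append(v)
    return sorted(out, key=Variant.sort_key)
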